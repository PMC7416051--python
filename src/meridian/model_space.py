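"""The constrained 72-model modulation space, RFX-BMS, families, and BMA.

Candidate models differ only in which connections invalid trials modulate
(the shared support of B^1 and B^3).  A structure is defined by

* laterality: modulations in the left, right, or both hemispheres
  (bilateral structures mirror the hemispheric pattern);
* the TPJ<->IPS and TPJ<->FEF pattern within a modulated hemisphere, each
  one of {none, TPJ->dorsal, dorsal->TPJ} with at least one of the two
  pairs modulated and no bidirectional modulation within a pair;
* the inter-hemispheric IPS modulation: left->right, right->left, or
  bidirectional.

That yields (3 x 3 - 1) x 3 x 3 = 72 admissible structures.

Group-level inference uses random-effects Bayesian model selection: a
variational Dirichlet scheme over model frequencies, with exceedance
probabilities estimated by Monte-Carlo sampling of the Dirichlet posterior.
Family comparisons place a uniform prior over families by down-weighting
each model's prior concentration by its family size and sample the exact
posterior by Gibbs (the mean-field update is biased for non-uniform
priors).  Within the winning family, per-participant parameters are
combined by fixed-effects Bayesian model averaging with softmax(free
energy) weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.special import digamma

from .constants import NODE_INDEX, NODES

LATERALITIES = ("left", "right", "bilateral")
PAIR_PATTERNS = ("none", "tpj_to_dorsal", "dorsal_to_tpj")
IPS_DIRECTIONS = ("l_to_r", "r_to_l", "bidirectional")


@dataclass(frozen=True)
class ModulationStructure:
    """One admissible support pattern for the invalid-trial modulations."""

    laterality: str
    tpj_ips: str
    tpj_fef: str
    ips_direction: str
    index: int = -1

    def __post_init__(self) -> None:
        if self.laterality not in LATERALITIES:
            raise ValueError(f"unknown laterality {self.laterality!r}")
        if self.tpj_ips not in PAIR_PATTERNS or self.tpj_fef not in PAIR_PATTERNS:
            raise ValueError("unknown TPJ-dorsal pattern")
        if self.ips_direction not in IPS_DIRECTIONS:
            raise ValueError(f"unknown IPS direction {self.ips_direction!r}")
        if self.tpj_ips == "none" and self.tpj_fef == "none":
            raise ValueError(
                "at least one modulation between the dorsal and ventral network "
                "must be present"
            )

    def support_mask(self) -> np.ndarray:
        """(6, 6) boolean mask of modulated connections (row = target node)."""
        mask = np.zeros((len(NODES), len(NODES)), dtype=bool)
        hemis = {"left": ("L",), "right": ("R",), "bilateral": ("L", "R")}[self.laterality]
        for h in hemis:
            tpj = NODE_INDEX[f"TPJ_{h}"]
            for pattern, dorsal_name in ((self.tpj_ips, f"IPS_{h}"), (self.tpj_fef, f"FEF_{h}")):
                dorsal = NODE_INDEX[dorsal_name]
                if pattern == "tpj_to_dorsal":
                    mask[dorsal, tpj] = True
                elif pattern == "dorsal_to_tpj":
                    mask[tpj, dorsal] = True
        ips_l, ips_r = NODE_INDEX["IPS_L"], NODE_INDEX["IPS_R"]
        if self.ips_direction in ("l_to_r", "bidirectional"):
            mask[ips_r, ips_l] = True
        if self.ips_direction in ("r_to_l", "bidirectional"):
            mask[ips_l, ips_r] = True
        return mask

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "laterality": self.laterality,
            "tpj_ips": self.tpj_ips,
            "tpj_fef": self.tpj_fef,
            "ips_direction": self.ips_direction,
            "support_mask": self.support_mask().astype(int).tolist(),
        }


def enumerate_models() -> list[ModulationStructure]:
    """Enumerate the 72 admissible structures in a stable order.

    Order: laterality (left, right, bilateral) x IPS direction
    (l_to_r, r_to_l, bidirectional) x the 8 admissible TPJ-dorsal patterns.
    """
    models = []
    for lat, ips, (t_ips, t_fef) in product(
        LATERALITIES, IPS_DIRECTIONS, product(PAIR_PATTERNS, PAIR_PATTERNS)
    ):
        if t_ips == "none" and t_fef == "none":
            continue
        models.append(
            ModulationStructure(
                laterality=lat,
                tpj_ips=t_ips,
                tpj_fef=t_fef,
                ips_direction=ips,
                index=len(models),
            )
        )
    return models


# --------------------------------------------------------------------------
# Family partitions
# --------------------------------------------------------------------------


@dataclass
class FamilyPartition:
    """A disjoint, exhaustive partition of model indices into named families."""

    families: dict[str, list[int]]
    n_models: int

    def __post_init__(self) -> None:
        seen: list[int] = []
        for members in self.families.values():
            seen.extend(members)
        if sorted(seen) != list(range(self.n_models)):
            raise ValueError("families must be disjoint and exhaustive")


def laterality_partition(models: list[ModulationStructure]) -> FamilyPartition:
    """Level-1 families: left / right / bilateral modulations."""
    fams = {lat: [m.index for m in models if m.laterality == lat] for lat in LATERALITIES}
    fams = {k: v for k, v in fams.items() if v}
    return FamilyPartition(families=fams, n_models=len(models))


def ips_direction_partition(models: list[ModulationStructure]) -> FamilyPartition:
    """Level-2 families: direction of the inter-hemispheric IPS modulation.

    Indices refer to positions within ``models`` (use on a family subset).
    """
    fams = {
        d: [i for i, m in enumerate(models) if m.ips_direction == d] for d in IPS_DIRECTIONS
    }
    fams = {k: v for k, v in fams.items() if v}
    return FamilyPartition(families=fams, n_models=len(models))


# --------------------------------------------------------------------------
# Random-effects BMS
# --------------------------------------------------------------------------


@dataclass
class BMSResult:
    """Posterior over model (or family) frequencies from RFX-BMS."""

    alpha: np.ndarray
    expected_p: np.ndarray
    exceedance_p: np.ndarray
    names: tuple[str, ...]
    n_samples: int
    assignments: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "alpha": self.alpha.tolist(),
            "expected_p": self.expected_p.tolist(),
            "exceedance_p": self.exceedance_p.tolist(),
            "n_samples": self.n_samples,
        }


def _dirichlet_vb(log_evidences: np.ndarray, alpha0: np.ndarray, tol=1e-8, max_iter=500):
    """Variational posterior over model frequencies (Dirichlet update)."""
    lme = np.asarray(log_evidences, dtype=float)
    if not np.all(np.isfinite(lme)):
        bad = np.argwhere(~np.isfinite(lme))
        raise ValueError(f"non-finite log evidences at (participant, model) cells {bad.tolist()}")
    n, k = lme.shape
    alpha = alpha0.astype(float).copy()
    for _ in range(max_iter):
        logu = lme + digamma(alpha)[None, :] - digamma(alpha.sum())
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        new_alpha = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    return alpha, u


def _exceedance(alpha: np.ndarray, n_samples: int, seed: int, groups=None) -> np.ndarray:
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    if groups is not None:
        draws = np.stack([draws[:, g].sum(axis=1) for g in groups], axis=1)
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=draws.shape[1]) / n_samples


def rfx_bms(
    log_evidences: np.ndarray,
    alpha0: float | np.ndarray = 1.0,
    n_samples: int = 100_000,
    seed: int = 0,
    names: tuple[str, ...] | None = None,
) -> BMSResult:
    """Random-effects BMS over a participants x models evidence matrix."""
    lme = np.asarray(log_evidences, dtype=float)
    n, k = lme.shape
    alpha0 = np.broadcast_to(np.asarray(alpha0, dtype=float), (k,)).copy()
    alpha, u = _dirichlet_vb(lme, alpha0)
    ep = _exceedance(alpha, n_samples, seed)
    return BMSResult(
        alpha=alpha,
        expected_p=alpha / alpha.sum(),
        exceedance_p=ep,
        names=names if names is not None else tuple(f"m{i}" for i in range(k)),
        n_samples=n_samples,
        assignments=u,
    )


def _gibbs_frequencies(
    lme: np.ndarray,
    alpha0: np.ndarray,
    n_samples: int,
    seed: int,
    burn_in: int = 500,
    thin: int = 2,
) -> np.ndarray:
    """Gibbs samples of the population model frequencies r.

    Alternates sampling each participant's model assignment from
    Cat(softmax(lme_n + log r)) and r from the Dirichlet conditional.
    Unlike the mean-field variational update, the exact sampler keeps
    aggregated (family) frequencies unbiased for non-uniform priors.
    """
    rng = np.random.default_rng(seed)
    n, k = lme.shape
    lme_c = lme - lme.max(axis=1, keepdims=True)
    r = rng.dirichlet(np.maximum(alpha0, 1e-3))
    out = np.empty((n_samples, k))
    kept = 0
    total = burn_in + n_samples * thin
    for it in range(total):
        logp = lme_c + np.log(np.maximum(r, 1e-300))[None, :]
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=1, keepdims=True)
        # vectorized categorical draws per participant
        picks = (p.cumsum(axis=1) > rng.random((n, 1))).argmax(axis=1)
        counts = np.bincount(picks, minlength=k)
        r = rng.dirichlet(alpha0 + counts)
        if it >= burn_in and (it - burn_in) % thin == 0:
            out[kept] = r
            kept += 1
    return out[:kept]


def family_bms(
    log_evidences: np.ndarray,
    partition: FamilyPartition,
    n_samples: int = 20_000,
    seed: int = 0,
) -> BMSResult:
    """Family-level random-effects BMS with a uniform prior over families.

    Each model's prior concentration is 1 / (family size), so every family
    carries total prior concentration 1 regardless of how many models it
    holds.  Posterior frequencies are obtained by Gibbs sampling (the
    mean-field variational update is biased for non-uniform priors);
    family quantities are sums over member models of the sampled
    frequencies, and the exceedance probability is the fraction of samples
    in which a family's frequency tops the rest.
    """
    lme = np.asarray(log_evidences, dtype=float)
    if not np.all(np.isfinite(lme)):
        bad = np.argwhere(~np.isfinite(lme))
        raise ValueError(f"non-finite log evidences at (participant, model) cells {bad.tolist()}")
    n, k = lme.shape
    if partition.n_models != k:
        raise ValueError("partition does not match the number of models")
    names = tuple(partition.families.keys())
    alpha0 = np.zeros(k)
    for members in partition.families.values():
        alpha0[members] = 1.0 / len(members)
    draws = _gibbs_frequencies(lme, alpha0, n_samples, seed)
    groups = [partition.families[f] for f in names]
    fam_draws = np.stack([draws[:, g].sum(axis=1) for g in groups], axis=1)
    winners = np.argmax(fam_draws, axis=1)
    ep = np.bincount(winners, minlength=len(names)) / len(fam_draws)
    fam_alpha0 = np.array([alpha0[g].sum() for g in groups])
    return BMSResult(
        # posterior concentration proxy: prior + expected participant counts
        alpha=fam_alpha0 + n * fam_draws.mean(axis=0),
        expected_p=fam_draws.mean(axis=0),
        exceedance_p=ep,
        names=names,
        n_samples=len(fam_draws),
    )


def hierarchical_family_selection(
    log_evidences: np.ndarray,
    models: list[ModulationStructure],
    n_samples: int = 100_000,
    seed: int = 0,
) -> dict:
    """Two-level family selection: laterality, then IPS direction.

    Level 1 compares left/right/bilateral families over the full space;
    level 2 partitions the winning family's models by inter-hemispheric IPS
    modulation direction.  Returns the two BMS results, the winning labels,
    and the winning family's model indices (into the full space).
    """
    lme = np.asarray(log_evidences, dtype=float)
    level1 = family_bms(lme, laterality_partition(models), n_samples=n_samples, seed=seed)
    lat_winner = level1.names[int(np.argmax(level1.exceedance_p))]
    sub_models = [m for m in models if m.laterality == lat_winner]
    sub_idx = [m.index for m in sub_models]
    sub_lme = lme[:, sub_idx]
    part2 = ips_direction_partition(sub_models)
    level2 = family_bms(sub_lme, part2, n_samples=n_samples, seed=seed + 1)
    ips_winner = level2.names[int(np.argmax(level2.exceedance_p))]
    winning = [sub_idx[i] for i in part2.families[ips_winner]]
    return {
        "level1": level1,
        "level2": level2,
        "laterality_winner": lat_winner,
        "ips_winner": ips_winner,
        "winning_family_models": winning,
    }


# --------------------------------------------------------------------------
# Bayesian model averaging
# --------------------------------------------------------------------------


def bma(posterior_means: list[dict], free_energies: np.ndarray) -> dict:
    """Fixed-effects BMA of per-model posterior means for one participant.

    ``posterior_means`` maps parameter name -> posterior mean for each
    model; parameters absent from a model's support contribute zero to its
    term.  Weights are softmax(F - max F), invariant to adding a constant
    to all free energies.
    """
    f = np.asarray(free_energies, dtype=float)
    if len(posterior_means) != len(f):
        raise ValueError("need one free energy per model")
    w = np.exp(f - f.max())
    w /= w.sum()
    names: list[str] = []
    for means in posterior_means:
        for k in means:
            if k not in names:
                names.append(k)
    return {
        name: float(sum(wi * means.get(name, 0.0) for wi, means in zip(w, posterior_means)))
        for name in names
    }
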