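"""Synthetic Posner-cueing designs, behavior, and node-level BOLD.

The generator reproduces the statistical structure of a two-run spatial
cueing experiment: each run has 5 blocks of 32 valid + 8 invalid trials
(80% cue validity), targets appear on the horizontal meridian (left/right)
in one run and on the vertical meridian (down/up) in the other, cue-target
SOA is 400 or 600 ms, and inter-trial intervals are drawn from
{2.0, 2.7, 3.2, 3.9, 4.5} s.  Behavioral responses follow a shifted
lognormal reaction-time model with an additive invalidity cost and an
optional (default zero) direction effect.  Node-level BOLD is generated
from a known ground-truth bilinear DCM plus low-frequency cosine drift and
white observation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from . import dcm
from .constants import HORIZONTAL, NODES, POSITIONS, RUNS, VERTICAL

# --------------------------------------------------------------------------
# Design
# --------------------------------------------------------------------------


@dataclass
class DesignSpec:
    """Timing and counterbalancing parameters of one experimental run."""

    tr_seconds: float = 2.2
    volumes_per_run: int = 552  # 557 acquired minus 5 discarded
    blocks_per_run: int = 5
    valid_per_block: int = 32
    invalid_per_block: int = 8
    soa_ms: tuple[int, ...] = (400, 600)
    iti_seconds: tuple[float, ...] = (2.0, 2.7, 3.2, 3.9, 4.5)
    alerting_duration_ms: float = 500.0
    alert_to_cue_ms: float = 1000.0
    cue_duration_ms: float = 200.0
    target_duration_ms: float = 250.0
    break_seconds_range: tuple[float, float] = (10.0, 13.0)
    run_order: tuple[str, str] = (HORIZONTAL, VERTICAL)
    response_mapping: int = 0  # 0 or 1; which finger maps to which orientation
    seed: int = 0

    def __post_init__(self) -> None:
        n_block = self.valid_per_block + self.invalid_per_block
        n_cells = 2 * 2 * len(self.soa_ms)  # position x finger x SOA
        if n_block % n_cells != 0:
            raise ValueError(
                f"trials per block ({n_block}) must be a multiple of the "
                f"{n_cells} target-property cells"
            )
        if self.invalid_per_block < 0 or self.valid_per_block < 0:
            raise ValueError("trial counts must be non-negative")

    @property
    def trials_per_block(self) -> int:
        return self.valid_per_block + self.invalid_per_block

    @property
    def trials_per_run(self) -> int:
        return self.trials_per_block * self.blocks_per_run

    @property
    def validity_fraction(self) -> float:
        return self.valid_per_block / self.trials_per_block

    @property
    def run_duration(self) -> float:
        return self.volumes_per_run * self.tr_seconds


#: Reduced-scale spec for quick simulations: a single block of 32 valid +
#: 8 invalid trials in a 110-volume run.  Same timing grid, cell balance
#: and 80% validity as the default.
DESK_SPEC = DesignSpec(
    volumes_per_run=110, blocks_per_run=1, valid_per_block=32, invalid_per_block=8
)


def generate_design(spec: DesignSpec, direction: str, seed: int | None = None) -> pd.DataFrame:
    """Generate one run's randomized trial sequence.

    Within each block the eight target-property cells (2 positions x 2
    response fingers x 2 SOAs) occur equally often and exactly
    ``invalid_per_block`` trials are invalidly cued; trial order is fully
    randomized.  Returns a trial table with onsets in seconds from run
    start (columns ``onset_alert``, ``onset_cue``, ``onset`` for the target)
    plus condition labels.

    Raises ``ValueError`` if the trials cannot fit into the run.
    """
    if direction not in RUNS:
        raise ValueError(f"direction must be one of {RUNS}, got {direction!r}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    positions = POSITIONS[direction]
    n_cells = 2 * 2 * len(spec.soa_ms)
    reps = spec.trials_per_block // n_cells
    rows = []
    t = 0.0
    for block in range(spec.blocks_per_run):
        cells = list(product(positions, (0, 1), spec.soa_ms)) * reps
        order = rng.permutation(len(cells))
        invalid_idx = set(rng.choice(len(cells), size=spec.invalid_per_block, replace=False))
        for k, idx in enumerate(order):
            pos, finger, soa = cells[idx]
            cueing = "invalid" if k in invalid_idx else "valid"
            onset_alert = t
            onset_cue = onset_alert + spec.alert_to_cue_ms / 1000.0
            onset_target = onset_cue + soa / 1000.0
            iti = float(rng.choice(spec.iti_seconds))
            rows.append(
                {
                    "run": direction,
                    "block": block,
                    "onset_alert": onset_alert,
                    "onset_cue": onset_cue,
                    "onset": onset_target,
                    "duration": 0.0,
                    "cueing": cueing,
                    "position": pos,
                    "trial_type": f"{cueing[0]}{pos}",
                    "soa_ms": soa,
                    "iti_s": iti,
                    "finger": finger,
                }
            )
            t = onset_target + spec.target_duration_ms / 1000.0 + iti
        if block < spec.blocks_per_run - 1:
            t += rng.uniform(*spec.break_seconds_range)
    seq = pd.DataFrame(rows)
    if len(seq):
        last_end = seq["onset"].iloc[-1] + spec.target_duration_ms / 1000.0 + seq["iti_s"].iloc[-1]
        if last_end > spec.run_duration:
            raise ValueError(
                f"infeasible timing: trials end at {last_end:.1f} s but the run "
                f"lasts only {spec.run_duration:.1f} s "
                f"({spec.volumes_per_run} volumes x {spec.tr_seconds} s)"
            )
    return seq


def generate_design_pair(
    spec: DesignSpec, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the horizontal and vertical runs with independent streams."""
    base = spec.seed if seed is None else seed
    seqs = {
        run: generate_design(spec, run, seed=base + i)
        for i, run in enumerate(spec.run_order)
    }
    return seqs[HORIZONTAL], seqs[VERTICAL]


# --------------------------------------------------------------------------
# Behavior
# --------------------------------------------------------------------------


@dataclass
class BehaviorParams:
    """Shifted-lognormal reaction-time model with Bernoulli lapses.

    RT = exp(N(log_location, log_scale)) + invalidity_cost * [invalid]
         + direction_effect * [vertical run], in milliseconds.

    The lognormal median is exp(log_location), so condition effects move the
    cell medians additively (the oracle used in tests).  Error and miss
    probabilities may be scalars or {'valid': p, 'invalid': p} mappings.
    """

    log_location: float = float(np.log(650.0))
    log_scale: float = 0.18
    invalidity_cost_ms: float = 50.0
    direction_effect_ms: float = 0.0
    error_prob: float | dict = field(default_factory=lambda: {"valid": 0.033, "invalid": 0.05})
    miss_prob: float | dict = 0.005
    seed: int = 0

    def _prob(self, which: str, cueing: str) -> float:
        p = getattr(self, which)
        p = p.get(cueing) if isinstance(p, dict) else p
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{which} must lie in [0, 1], got {p}")
        return float(p)


def generate_behavior(seq: pd.DataFrame, params: BehaviorParams) -> pd.DataFrame:
    """Attach reaction times, responses and correctness flags to a design.

    Returns a copy of ``seq`` (one or both runs) with columns ``rt_ms``,
    ``response``, ``correct`` and ``missed``.  Missed trials carry NaN RTs.
    """
    if len(seq) == 0:
        raise ValueError("trial sequence is empty")
    rng = np.random.default_rng(params.seed)
    out = seq.reset_index(drop=True).copy()
    n = len(out)
    rt = np.exp(rng.normal(params.log_location, params.log_scale, size=n))
    invalid = (out["cueing"] == "invalid").to_numpy()
    vertical = (out["run"] == VERTICAL).to_numpy()
    rt = rt + params.invalidity_cost_ms * invalid + params.direction_effect_ms * vertical
    p_err = np.array([params._prob("error_prob", c) for c in out["cueing"]])
    p_miss = np.array([params._prob("miss_prob", c) for c in out["cueing"]])
    missed = rng.random(n) < p_miss
    error = (rng.random(n) < p_err) & ~missed
    correct_finger = out["finger"].to_numpy()
    response = np.where(error, 1 - correct_finger, correct_finger).astype(float)
    response[missed] = np.nan
    rt[missed] = np.nan
    out["rt_ms"] = rt
    out["response"] = response
    out["correct"] = ~error & ~missed
    out["missed"] = missed
    return out


# --------------------------------------------------------------------------
# Ground-truth network and BOLD
# --------------------------------------------------------------------------


@dataclass
class GroundTruthNetwork:
    """A known DCM plus the nuisance structure of real recordings.

    noise_sd : white observation noise SD per node (scalar or (6,) array);
        ignored when ``snr`` is given, in which case the noise SD per node is
        set to (noiseless signal SD) / snr.
    drift_amplitude : SD of a low-frequency cosine drift mixture added per
        node and run (same units as the BOLD signal); 0 disables drift.
    voxels_per_node : optional voxel expansion for eigenvariate testing;
        each node then yields ``voxels_per_node`` voxel series sharing the
        node signal plus independent noise of SD ``voxel_noise_sd``.
    """

    model: dcm.DCMModel
    noise_sd: float | np.ndarray = 0.0
    snr: float | None = None
    drift_amplitude: float = 0.0
    drift_components: int = 3
    drift_period_s: float = 128.0
    voxels_per_node: int | None = None
    voxel_noise_sd: float = 1.0
    sampling_offset: int = 18

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise_sd must be non-negative")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive")


def default_ground_truth(
    b_strength: float = 0.4,
    support_mask: np.ndarray | None = None,
    b3_strength: float | None = None,
    snr: float | None = 1.0,
    noise_sd: float | np.ndarray = 0.0,
    drift_amplitude: float = 0.0,
    self_coupling: float = -0.5,
    lateral_coupling: float = 0.10,
    homologous_coupling: float = 0.08,
    driving_weight: float = 0.10,
) -> GroundTruthNetwork:
    """A plausible, stable six-node ground truth.

    The fixed coupling A is fully connected within each hemisphere and
    between homologous regions, with weak positive couplings and
    self-inhibition of -0.5 Hz.  Invalid-trial modulations B^1 (horizontal)
    and B^3 (vertical) share ``support_mask`` (default: the bilateral
    TPJ->IPS, TPJ->FEF pattern with right->left IPS modulation) and strength
    ``b_strength`` (B^3 defaults to the same values as B^1, i.e. no
    direction effect).  All nodes receive all driving inputs.
    """
    n = len(NODES)
    a = np.zeros((n, n))
    hemis = {"L": [0, 2, 4], "R": [1, 3, 5]}  # IPS, FEF, TPJ per hemisphere
    for nodes in hemis.values():
        for i in nodes:
            for j in nodes:
                if i != j:
                    a[i, j] = lateral_coupling
    for i, j in ((0, 1), (2, 3), (4, 5)):
        a[i, j] = a[j, i] = homologous_coupling
    np.fill_diagonal(a, self_coupling)
    if support_mask is None:
        from .model_space import ModulationStructure

        support_mask = ModulationStructure(
            laterality="bilateral",
            tpj_ips="tpj_to_dorsal",
            tpj_fef="tpj_to_dorsal",
            ips_direction="r_to_l",
        ).support_mask()
    b = np.zeros((4, n, n))
    b[0] = b_strength * support_mask
    b[2] = (b_strength if b3_strength is None else b3_strength) * support_mask
    c = np.full((n, 4), driving_weight)
    model = dcm.DCMModel(a=a, b=b, c=c)
    model.assert_stable()
    return GroundTruthNetwork(
        model=model, snr=snr, noise_sd=noise_sd, drift_amplitude=drift_amplitude
    )


def _cosine_drift(n_vol: int, tr: float, n_components: int, period_s: float, rng) -> np.ndarray:
    """Random low-frequency cosine mixture, unit SD, one node column."""
    t = np.arange(n_vol) * tr
    drift = np.zeros(n_vol)
    duration = n_vol * tr
    for k in range(1, n_components + 1):
        freq = k / (2.0 * max(duration, period_s))
        drift += rng.normal() * np.cos(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    sd = drift.std()
    return drift / sd if sd > 0 else drift


def generate_bold(
    seq_pair: Sequence[pd.DataFrame],
    truth: GroundTruthNetwork,
    spec: DesignSpec | None = None,
    seed: int = 0,
    return_voxels: bool = False,
):
    """Generate node-level BOLD for the two runs from a known DCM.

    Returns ``(bold, inputs)`` where ``bold`` is a DataFrame of shape
    (total volumes, 6) with node-name columns (both runs concatenated) and
    ``inputs`` is the :class:`meridian.dcm.InputSet` used.  With
    ``return_voxels=True`` a third element maps node name -> (voxels, time)
    array of the voxel expansion.
    """
    spec = spec if spec is not None else DesignSpec()
    events = pd.concat(list(seq_pair), ignore_index=True)
    inputs = dcm.build_inputs(
        events,
        tr=spec.tr_seconds,
        volumes_per_run=[spec.volumes_per_run] * len(seq_pair),
    )
    truth.model.assert_stable()
    clean = dcm.simulate_bold(truth.model, inputs, sampling_offset=truth.sampling_offset)
    rng = np.random.default_rng(seed)
    n_vol, n_nodes = clean.shape
    if truth.snr is not None:
        sd_signal = clean.std(axis=0)
        noise_sd = sd_signal / truth.snr
    else:
        noise_sd = np.broadcast_to(np.asarray(truth.noise_sd, dtype=float), (n_nodes,))
    noisy = clean + rng.normal(size=clean.shape) * noise_sd
    if truth.drift_amplitude > 0:
        per_run = n_vol // len(seq_pair)
        for r in range(len(seq_pair)):
            sl = slice(r * per_run, (r + 1) * per_run)
            for node in range(n_nodes):
                noisy[sl, node] += truth.drift_amplitude * _cosine_drift(
                    per_run, spec.tr_seconds, truth.drift_components, truth.drift_period_s, rng
                )
    bold = pd.DataFrame(noisy, columns=list(NODES))
    if not return_voxels:
        return bold, inputs
    voxels = {}
    if truth.voxels_per_node:
        for i, node in enumerate(NODES):
            base = noisy[:, i]
            vox = base[None, :] + rng.normal(
                size=(truth.voxels_per_node, n_vol)
            ) * truth.voxel_noise_sd
            voxels[node] = vox
    return bold, inputs, voxels


# --------------------------------------------------------------------------
# File formats
# --------------------------------------------------------------------------


def write_events(seq: pd.DataFrame, path) -> None:
    """Write a trial table as a BIDS-style events TSV."""
    cols = [c for c in (
        "onset", "duration", "trial_type", "run", "block", "cueing", "position",
        "soa_ms", "iti_s", "finger", "rt_ms", "response", "correct", "missed",
        "onset_alert", "onset_cue",
    ) if c in seq.columns]
    seq[cols].to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_timeseries(bold: pd.DataFrame, path) -> None:
    """Write node time series as TSV with a node-name header row."""
    bold.to_csv(path, sep="\t", index=False)


def read_timeseries(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [n for n in NODES if n not in df.columns]
    if missing:
        raise ValueError(f"time-series file lacks node columns: {missing}")
    return df[list(NODES)]
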