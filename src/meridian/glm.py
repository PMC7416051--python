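"""Node-level event-related GLM: design matrices, OLS, contrasts, helpers.

Both runs are modeled in one design matrix: eight condition regressors
(iL, iR, vL, vR, iD, iU, vD, vU; stick functions at target onsets convolved
with the canonical double-gamma HRF), optional per-run error/post-error and
outlier-trial regressors, per-run nuisance columns (six motion parameters
plus frame-wise displacement when provided), a per-run orthonormal cosine
drift set (128 s cutoff) and per-run intercepts.  Convolution and drift
construction are delegated to nilearn's first-level machinery; the fit is
ordinary least squares per node.

The planned contrasts over the eight condition betas:

(a) main_cueing     (iL + iR + iD + iU) - (vL + vR + vD + vU)
(b) horiz_reorient  (iL + iR) - (vL + vR)
(c) vert_reorient   (iD + iU) - (vD + vU)
(d) main_direction  (iL + iR + vL + vR) - (iD + iU + vD + vU)
(e) interaction     (iL + iR - vL - vR) - (iD + iU - vD - vU)
plus the visual-field contrasts vL>vR, vR>vL, vD>vU, vU>vD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from nilearn.glm.first_level import make_first_level_design_matrix

from .constants import CONDITIONS, NODES

logger = logging.getLogger(__name__)

DRIFT_CUTOFF_S = 128.0

CONTRASTS: dict[str, dict[str, float]] = {
    "main_cueing": {"iL": 1, "iR": 1, "iD": 1, "iU": 1, "vL": -1, "vR": -1, "vD": -1, "vU": -1},
    "horiz_reorient": {"iL": 1, "iR": 1, "vL": -1, "vR": -1},
    "vert_reorient": {"iD": 1, "iU": 1, "vD": -1, "vU": -1},
    "main_direction": {"iL": 1, "iR": 1, "vL": 1, "vR": 1, "iD": -1, "iU": -1, "vD": -1, "vU": -1},
    "interaction": {"iL": 1, "iR": 1, "vL": -1, "vR": -1, "iD": -1, "iU": -1, "vD": 1, "vU": 1},
    "vL>vR": {"vL": 1, "vR": -1},
    "vR>vL": {"vR": 1, "vL": -1},
    "vD>vU": {"vD": 1, "vU": -1},
    "vU>vD": {"vU": 1, "vD": -1},
}


@dataclass
class DesignMatrix:
    """A two-run design matrix with a frozen column registry."""

    frame: pd.DataFrame
    condition_columns: list[str]
    run_columns: dict[str, list[str]]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


def build_design_matrix(
    events: pd.DataFrame,
    confounds: dict[str, pd.DataFrame] | None = None,
    n_volumes: int = 552,
    tr: float = 2.2,
    exclusion_events: pd.DataFrame | None = None,
    drift_cutoff_s: float = DRIFT_CUTOFF_S,
) -> DesignMatrix:
    """Build the concatenated two-run design matrix.

    ``events`` carries both runs (columns ``run``, ``onset``, ``trial_type``);
    ``confounds`` optionally maps run label -> (n_volumes, q) nuisance frame
    (e.g. motion + frame-wise displacement); ``exclusion_events`` optionally
    carries error/post-error and outlier trials (column ``trial_type`` in
    {'error_posterror', 'outlier'}) modeled as per-run stick regressors.

    Events beyond the scan end raise with the offending onsets listed.
    """
    runs = [r for r in ("horizontal", "vertical") if r in set(events["run"])]
    if not runs:
        runs = sorted(set(events["run"]))
    frame_times = np.arange(n_volumes) * tr
    frames = []
    run_columns: dict[str, list[str]] = {}
    for run in runs:
        sub = events[events["run"] == run]
        late = sub[sub["onset"] > n_volumes * tr]
        if len(late):
            raise ValueError(
                f"events beyond the end of the {run} run: {late['onset'].tolist()}"
            )
        ev = sub[["onset", "trial_type"]].copy()
        ev["duration"] = 0.0
        if exclusion_events is not None:
            ex = exclusion_events[exclusion_events["run"] == run]
            if len(ex):
                exf = ex[["onset", "trial_type"]].copy()
                exf["duration"] = 0.0
                ev = pd.concat([ev, exf], ignore_index=True)
        add_regs = None
        if confounds is not None and run in confounds and confounds[run] is not None:
            add_regs = pd.DataFrame(confounds[run]).reset_index(drop=True)
            add_regs.columns = [f"{c}_{run[0]}" for c in add_regs.columns]
            add_regs.index = frame_times
        with warnings.catch_warnings():
            # zero-duration sticks are the intended event-related model
            warnings.filterwarnings("ignore", message=".*null duration.*")
            dm = make_first_level_design_matrix(
                frame_times,
                events=ev,
                hrf_model="spm",
                drift_model="cosine",
                high_pass=1.0 / drift_cutoff_s,
                add_regs=add_regs,
            )
        rename = {}
        for col in dm.columns:
            if col in CONDITIONS:
                continue
            if col in ("constant",) or col.startswith("drift_") or col in (
                "error_posterror", "outlier",
            ):
                rename[col] = f"{col}_{run[0]}"
        dm = dm.rename(columns=rename)
        run_columns[run] = [c for c in dm.columns if c not in CONDITIONS]
        frames.append(dm.reset_index(drop=True))
    full = pd.concat(frames, axis=0, ignore_index=True).fillna(0.0)
    cond_cols = [c for c in CONDITIONS if c in full.columns]
    dropped = []
    for c in cond_cols:
        if np.allclose(full[c], 0.0):
            dropped.append(c)
    if dropped:
        logger.warning("dropping all-zero condition columns: %s", dropped)
        full = full.drop(columns=dropped)
        cond_cols = [c for c in cond_cols if c not in dropped]
    other = [c for c in full.columns if c not in cond_cols]
    full = full[cond_cols + other]
    return DesignMatrix(frame=full, condition_columns=cond_cols, run_columns=run_columns)


@dataclass
class GLMResult:
    """OLS betas (node x design column) and residuals (time x node)."""

    betas: pd.DataFrame
    residuals: np.ndarray
    rank_deficient: bool


def fit_glm(ts, design: DesignMatrix) -> GLMResult:
    """Ordinary least squares of each node's series on the design matrix."""
    Y = ts[list(NODES)].to_numpy(dtype=float) if isinstance(ts, pd.DataFrame) else np.asarray(ts, dtype=float)
    X = design.values
    if Y.shape[0] != X.shape[0]:
        raise ValueError(f"time series has {Y.shape[0]} rows but design has {X.shape[0]}")
    rank = np.linalg.matrix_rank(X)
    rank_deficient = rank < X.shape[1]
    if rank_deficient:
        logger.warning("design matrix is rank deficient (rank %d < %d columns); "
                       "using the pseudoinverse", rank, X.shape[1])
    beta = np.linalg.pinv(X) @ Y
    resid = Y - X @ beta
    names = list(ts.columns) if isinstance(ts, pd.DataFrame) else list(NODES)[: Y.shape[1]]
    betas = pd.DataFrame(beta.T, index=names, columns=design.columns)
    return GLMResult(betas=betas, residuals=resid, rank_deficient=rank_deficient)


def apply_contrast(betas: pd.DataFrame, name_or_weights) -> pd.Series:
    """Evaluate a planned contrast; returns one scalar per node."""
    weights = CONTRASTS[name_or_weights] if isinstance(name_or_weights, str) else name_or_weights
    missing = [c for c in weights if c not in betas.columns]
    if missing:
        raise ValueError(f"betas lack condition columns {missing}")
    out = sum(w * betas[c] for c, w in weights.items())
    out.name = name_or_weights if isinstance(name_or_weights, str) else "contrast"
    return out


COLLAPSED = {
    "invalid_horizontal": ("iL", "iR"),
    "valid_horizontal": ("vL", "vR"),
    "invalid_vertical": ("iD", "iU"),
    "valid_vertical": ("vD", "vU"),
}


def collapse_betas(betas: pd.DataFrame) -> pd.DataFrame:
    """Average condition betas over visual fields (direction-collapsed).

    Idempotent: a frame already carrying the collapsed columns is returned
    unchanged (copy).
    """
    if all(c in betas.columns for c in COLLAPSED):
        return betas[list(COLLAPSED)].copy()
    out = {}
    for name, (c1, c2) in COLLAPSED.items():
        if c1 in betas.columns and c2 in betas.columns:
            out[name] = (betas[c1] + betas[c2]) / 2.0
    return pd.DataFrame(out)


def eigenvariate(roi: np.ndarray) -> np.ndarray:
    """Summary time course of a voxels x time matrix.

    First principal component over time, sign-aligned so the mean voxel
    loading is positive, and rescaled to the mean SD of the voxel series.
    """
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2:
        raise ValueError("roi must be a voxels x time matrix")
    centered = roi - roi.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    comp = vt[0]
    if u[:, 0].mean() < 0:
        comp = -comp
    sd = comp.std()
    scale = roi.std(axis=1).mean()
    return comp / sd * scale if sd > 0 else comp


def signflip_ttest(group_values, n_permutations: int = 25_000, seed: int = 0) -> float:
    """Two-sided one-sample sign-flip permutation test on the group mean.

    Uses full enumeration of the 2^n sign patterns when that is no larger
    than ``n_permutations`` (exact p = count / 2^n, the identity flip
    included); otherwise Monte-Carlo sign flips with add-one smoothing
    p = (1 + #{|perm| >= |observed|}) / (n_permutations + 1).
    """
    v = np.asarray(group_values, dtype=float)
    n = len(v)
    if n == 0:
        raise ValueError("empty group")
    obs = abs(v.mean())
    if 2**n <= n_permutations:
        signs = np.array(
            [[1 if (k >> i) & 1 else -1 for i in range(n)] for k in range(2**n)]
        )
        stats = np.abs(signs @ v) / n
        return float(np.mean(stats >= obs - 1e-12))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    stats = np.abs(signs @ v) / n
    return float((1 + np.sum(stats >= obs - 1e-12)) / (n_permutations + 1))


def beta_table(
    glm_results: dict[int, GLMResult], condition_columns=CONDITIONS
) -> pd.DataFrame:
    """Cohort beta table: rows participant x node, condition columns."""
    rows = []
    for pid, res in glm_results.items():
        for node in res.betas.index:
            row = {"participant": pid, "node": node}
            for c in condition_columns:
                if c in res.betas.columns:
                    row[c] = res.betas.loc[node, c]
            rows.append(row)
    return pd.DataFrame(rows)


def write_beta_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_beta_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
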