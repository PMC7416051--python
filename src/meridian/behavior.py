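"""Reaction-time cleaning and condition summaries.

Trials are excluded, per participant, in a fixed rule order (the first
matching rule claims the trial in the exclusion ledger):

1. ``error``       -- incorrect (non-missed) response;
2. ``post_error``  -- the trial immediately following an error, to account
   for post-error slowing (no cascading: a correct post-error trial does
   not itself trigger further exclusion);
3. ``miss``        -- no response recorded;
4. ``fast``        -- reaction time below 200 ms;
5. ``iqr_outlier`` -- reaction time above Q3 + 1.5 * IQR, with quartiles
   (linear-interpolation / type-7 estimator) computed per cueing x position
   cell over the trials surviving rules 1-4.  Cells with fewer than 4
   surviving trials skip the rule with a logged warning.

Error rates are computed on the raw record (mean of the incorrect-or-missed
indicator per cueing x direction cell, before any RT cleaning); median RTs
are computed on the cleaned trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RT_FLOOR_MS = 200.0
IQR_FACTOR = 1.5
MIN_CELL_FOR_IQR = 4

EXCLUSION_REASONS = ("error", "post_error", "miss", "fast", "iqr_outlier")


@dataclass
class CleanedTrials:
    """Retained trials plus a per-cell exclusion ledger."""

    retained: pd.DataFrame
    ledger: pd.DataFrame  # rows: cueing x position cells; columns: reasons
    n_total: int

    @property
    def n_excluded(self) -> int:
        return int(self.ledger[list(EXCLUSION_REASONS)].to_numpy().sum())

    def check(self) -> None:
        if len(self.retained) + self.n_excluded != self.n_total:
            raise AssertionError("exclusion ledger does not add up")


def clean_rts(record: pd.DataFrame) -> CleanedTrials:
    """Apply the exclusion rules to one participant's behavioral record.

    ``record`` needs columns ``rt_ms``, ``correct``, ``missed``, ``cueing``,
    ``position`` and ``run``; trial order within each run is the
    presentation order (used for the post-error rule).
    """
    rec = record.reset_index(drop=True).copy()
    reason = np.full(len(rec), "", dtype=object)
    error = (~rec["correct"].to_numpy(dtype=bool)) & (~rec["missed"].to_numpy(dtype=bool))
    missed = rec["missed"].to_numpy(dtype=bool)
    # post-error: the next trial within the same run follows an error
    post_error = np.zeros(len(rec), dtype=bool)
    for _, idx in rec.groupby("run", sort=False).indices.items():
        idx = np.sort(idx)
        prev_err = error[idx[:-1]]
        post_error[idx[1:]] = prev_err
    rt = rec["rt_ms"].to_numpy(dtype=float)
    reason[error] = "error"
    free = reason == ""
    reason[free & post_error] = "post_error"
    free = reason == ""
    reason[free & missed] = "miss"
    free = reason == ""
    reason[free & (rt < RT_FLOOR_MS)] = "fast"
    # IQR rule per cueing x position cell on survivors
    free = reason == ""
    for (cueing, pos), idx in rec.groupby(["cueing", "position"], sort=False).indices.items():
        idx = np.asarray(idx)
        surv = idx[free[idx]]
        if len(surv) < MIN_CELL_FOR_IQR:
            logger.warning(
                "cell (%s, %s): only %d surviving trials, IQR rule skipped",
                cueing, pos, len(surv),
            )
            continue
        vals = rt[surv]
        q1, q3 = np.quantile(vals, [0.25, 0.75])  # linear interpolation (type 7)
        bound = q3 + IQR_FACTOR * (q3 - q1)
        reason[surv[vals > bound]] = "iqr_outlier"
    rec["exclusion_reason"] = reason
    retained = rec[reason == ""].drop(columns="exclusion_reason")
    ledger = (
        pd.crosstab([rec["cueing"], rec["position"]], rec["exclusion_reason"])
        .reindex(columns=list(EXCLUSION_REASONS), fill_value=0)
        .astype(int)
    )
    out = CleanedTrials(retained=retained, ledger=ledger, n_total=len(rec))
    out.check()
    return out


def summarize(cleaned: CleanedTrials, record: pd.DataFrame) -> pd.DataFrame:
    """Per-condition medians and error rates for one participant.

    Returns a tidy frame with one row per cueing x direction cell and
    columns ``median_rt_ms`` (cleaned trials; NaN for empty cells) and
    ``error_rate`` (raw record: mean of incorrect-or-missed).
    """
    raw = record.copy()
    raw["direction"] = raw["run"]
    raw["err"] = (~raw["correct"].astype(bool)) | raw["missed"].astype(bool)
    error_rates = raw.groupby(["cueing", "direction"])["err"].mean()
    ret = cleaned.retained.copy()
    ret["direction"] = ret["run"]
    medians = ret.groupby(["cueing", "direction"])["rt_ms"].median()
    rows = []
    for cueing in ("invalid", "valid"):
        for direction in sorted(raw["direction"].unique()):
            rows.append(
                {
                    "cueing": cueing,
                    "direction": direction,
                    "median_rt_ms": medians.get((cueing, direction), np.nan),
                    "error_rate": error_rates.get((cueing, direction), np.nan),
                }
            )
    return pd.DataFrame(rows)


def summarize_cohort(records: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Clean and summarize every participant; returns the tidy cohort table
    (participant, cueing, direction, median_rt_ms, error_rate)."""
    frames = []
    for pid, rec in records.items():
        summary = summarize(clean_rts(rec), rec)
        summary.insert(0, "participant", pid)
        frames.append(summary)
    return pd.concat(frames, ignore_index=True)
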