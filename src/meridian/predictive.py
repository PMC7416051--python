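"""Cross-run decoding of the cueing condition from VOI betas.

Each observation is one condition regressor of one participant in one run
(four per run: two invalid, two valid), with the six VOI betas as features
and the cueing condition as the label.  Within-run performance uses nested
five-fold cross-validation (the inner loop selects the L2 regularization
parameter C over a decade grid; ties go to the strongest regularization);
cross-run generalization selects C by five-fold cross-validation within the
training run, refits on that whole run and scores on the untouched other
run.  Features are standardized with training-split statistics only.
Significance comes from label permutations that re-run the entire selection
pipeline, with p = (1 + #{perm >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .constants import CONDITIONS, HORIZONTAL, NODES

DEFAULT_C_GRID = tuple(10.0**k for k in range(-4, 5))


@dataclass
class DecodeDataset:
    """Feature matrix (observations x 6 VOIs) with cueing labels."""

    X: np.ndarray
    y: np.ndarray  # 1 = invalid, 0 = valid
    run: str
    participants: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y disagree on the number of observations")

    def shuffled_labels(self, rng) -> "DecodeDataset":
        """Permute labels for the permutation null.

        When participant tags are present, labels shuffle within each
        participant -- the exchangeable unit under participant random
        effects, and the scheme that keeps the within-participant label
        balance of the design.  Without tags, labels shuffle globally.
        """
        y = self.y.copy()
        if self.participants is not None:
            for pid in np.unique(self.participants):
                idx = np.nonzero(self.participants == pid)[0]
                y[idx] = y[idx[rng.permutation(len(idx))]]
        else:
            y = rng.permutation(y)
        return DecodeDataset(
            X=self.X, y=y, run=self.run, participants=self.participants
        )


def decode_dataset_from_betas(beta_table: pd.DataFrame, run: str) -> DecodeDataset:
    """Build the decoding dataset of one run from a cohort beta table.

    ``beta_table`` is tidy (participant, node, 8 condition columns); the
    run's four condition regressors become observations with the six VOI
    betas as features.  Labels are balanced by construction (two invalid
    and two valid regressors per participant).
    """
    conds = [c for c in CONDITIONS if (c[1] in "LR") == (run == HORIZONTAL)]
    wide = beta_table.pivot(index="participant", columns="node")
    rows, labels, pids = [], [], []
    for pid in wide.index:
        for cond in conds:
            rows.append([wide.loc[pid, (cond, node)] for node in NODES])
            labels.append(1 if cond.startswith("i") else 0)
            pids.append(pid)
    return DecodeDataset(
        X=np.asarray(rows), y=np.asarray(labels), run=run, participants=np.asarray(pids)
    )


def _make_clf(c: float):
    return make_pipeline(
        StandardScaler(), LogisticRegression(C=c, solver="liblinear")
    )


def _select_c(X, y, c_grid, seed: int, n_folds: int = 5) -> float:
    """Pick C by stratified k-fold accuracy; ties -> strongest regularization."""
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    best_c, best_acc = None, -np.inf
    for c in sorted(c_grid):  # ascending: first best = smallest C
        accs = []
        for tr, te in cv.split(X, y):
            clf = _make_clf(c).fit(X[tr], y[tr])
            accs.append(clf.score(X[te], y[te]))
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:
            best_acc, best_c = acc, c
    return best_c


def nested_cv_accuracy(
    ds: DecodeDataset, c_grid=DEFAULT_C_GRID, seed: int = 0, n_folds: int = 5
) -> float:
    """Within-run accuracy from nested stratified five-fold CV."""
    X, y = ds.X, ds.y
    if min(np.bincount(y.astype(int))) < n_folds:
        raise ValueError("too few observations per class for stratified folds")
    outer = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for k, (tr, te) in enumerate(outer.split(X, y)):
        c = _select_c(X[tr], y[tr], c_grid, seed=seed + 1 + k)
        clf = _make_clf(c).fit(X[tr], y[tr])
        accs.append(clf.score(X[te], y[te]))
    return float(np.mean(accs))


def cross_run_generalization(
    train: DecodeDataset, test: DecodeDataset, c_grid=DEFAULT_C_GRID, seed: int = 0
) -> tuple[float, float]:
    """Accuracy on the untouched other run; C selected within the training
    run only.  Returns (accuracy, chosen_C)."""
    c = _select_c(train.X, train.y, c_grid, seed=seed)
    clf = _make_clf(c).fit(train.X, train.y)
    return float(clf.score(test.X, test.y)), float(c)


@dataclass
class PermutationResult:
    observed: float
    p_value: float
    n_permutations: int
    null_distribution: np.ndarray = field(repr=False, default=None)


def permutation_p_nested(
    ds: DecodeDataset, n_perm: int = 1000, c_grid=DEFAULT_C_GRID, seed: int = 0
) -> PermutationResult:
    """Label-permutation test of the within-run nested-CV accuracy.

    The whole pipeline, including C re-selection, is rerun per permutation.
    """
    observed = nested_cv_accuracy(ds, c_grid=c_grid, seed=seed)
    rng = np.random.default_rng(seed)
    null = np.array(
        [
            nested_cv_accuracy(ds.shuffled_labels(rng), c_grid=c_grid, seed=seed)
            for _ in range(n_perm)
        ]
    )
    p = (1 + np.sum(null >= observed - 1e-12)) / (n_perm + 1)
    return PermutationResult(observed, float(p), n_perm, null)


def permutation_p_cross(
    train: DecodeDataset,
    test: DecodeDataset,
    n_perm: int = 1000,
    c_grid=DEFAULT_C_GRID,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation test of the cross-run generalization accuracy.

    Labels are shuffled within each run and the full selection pipeline
    (including C re-selection on the permuted training run) reruns.
    """
    observed, _ = cross_run_generalization(train, test, c_grid=c_grid, seed=seed)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        acc, _ = cross_run_generalization(
            train.shuffled_labels(rng), test.shuffled_labels(rng), c_grid=c_grid, seed=seed
        )
        null[i] = acc
    p = (1 + np.sum(null >= observed - 1e-12)) / (n_perm + 1)
    return PermutationResult(observed, float(p), n_perm, null)
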