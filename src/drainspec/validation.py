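"""Five-fold optimism correction of in-sample performance.

The scheme: split the samples into k (default 5) near-equal folds.  For
each fold, refit the whole modelling procedure on the remaining 80%, record
the metric on the training data (inner-sample) and on the left-out fold
(out-of-sample), and take the difference (out - inner).  Fit once more on
all data for the global inner-sample metric, then

    corrected = global + mean(out - inner)

which shifts the optimistic in-sample value by the average generalization
gap.  The same signed formula serves losses (MSE, lower better: corrected
ends up above global) and scores (AUC/BAC, higher better: corrected ends up
below global) because the sign of the mean difference flips with the
metric's direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


@dataclass
class FoldReport:
    k: int
    inner: np.ndarray
    outer: np.ndarray
    global_metric: float
    fold_diffs: np.ndarray = field(init=False)
    mean_diff: float = field(init=False)
    sd_diff: float = field(init=False)
    corrected: float = field(init=False)
    failures: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.inner = np.asarray(self.inner, dtype=float)
        self.outer = np.asarray(self.outer, dtype=float)
        self.fold_diffs = self.outer - self.inner
        self.mean_diff = float(self.fold_diffs.mean())
        self.sd_diff = float(self.fold_diffs.std(ddof=1)) if self.k > 1 else 0.0
        self.corrected = apply_correction(self.global_metric, self.fold_diffs)

    @property
    def var_diff(self) -> float:
        return self.sd_diff**2


def apply_correction(global_metric: float, fold_diffs) -> float:
    """The correction formula itself: global + mean(out-of-sample - inner-sample).

    Exposed separately so printed fold-difference tables can be pushed
    through the exact same arithmetic as live cross-validation runs.
    """
    return float(global_metric + np.mean(np.asarray(fold_diffs, dtype=float)))


def make_folds(
    sample_ids: Sequence, k: int = 5, seed: int = 0, groups: Sequence | None = None
) -> np.ndarray:
    """Deterministic fold assignment (array of fold indices 0..k-1).

    Without ``groups``, samples are permuted and dealt round-robin, so fold
    sizes differ by at most one.  With ``groups`` (patient ids), whole
    patients are assigned to folds greedily by size so no patient is split
    -- the statistically safer option for repeated samples, off by default
    in the pipeline.
    """
    n = len(sample_ids)
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if groups is None:
        perm = rng.permutation(n)
        for pos, idx in enumerate(perm):
            assignment[idx] = pos % k
        return assignment
    groups = np.asarray(groups)
    uniq = list(dict.fromkeys(groups.tolist()))  # stable order
    order = rng.permutation(len(uniq))
    sizes = {g: int((groups == g).sum()) for g in uniq}
    shuffled = sorted((uniq[i] for i in order), key=lambda g: -sizes[g])
    fold_load = np.zeros(k, dtype=int)
    fold_of_group = {}
    for g in shuffled:
        f = int(np.argmin(fold_load))
        fold_of_group[g] = f
        fold_load[f] += sizes[g]
    for i, g in enumerate(groups):
        assignment[i] = fold_of_group[g]
    return assignment


def corrected_metric(
    fit_predict: Callable[[np.ndarray], Callable[[np.ndarray], np.ndarray]],
    metric: Callable[[np.ndarray, np.ndarray], float],
    y: np.ndarray,
    folds: np.ndarray,
) -> FoldReport:
    """Run the fold-difference correction for an arbitrary refittable procedure.

    ``fit_predict(train_idx)`` refits the full procedure on the given rows
    and returns a ``predict(idx) -> predictions`` callable;
    ``metric(predictions, y_subset)`` scores them.  Any fold whose fit
    raises is recorded in ``failures`` and contributes NaN.
    """
    y = np.asarray(y, dtype=float)
    folds = np.asarray(folds, dtype=int)
    ks = np.unique(folds)
    inner, outer, failures = [], [], []
    for f in ks:
        train = np.nonzero(folds != f)[0]
        test = np.nonzero(folds == f)[0]
        try:
            predict = fit_predict(train)
            inner.append(metric(predict(train), y[train]))
            outer.append(metric(predict(test), y[test]))
        except Exception as exc:  # noqa: BLE001 - fold failures must be visible, not fatal
            failures.append((int(f), repr(exc)))
            inner.append(np.nan)
            outer.append(np.nan)
    all_idx = np.arange(y.size)
    predict_all = fit_predict(all_idx)
    global_metric = metric(predict_all(all_idx), y)
    return FoldReport(
        k=len(ks),
        inner=np.array(inner),
        outer=np.array(outer),
        global_metric=float(global_metric),
        failures=failures,
    )
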