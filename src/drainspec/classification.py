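"""Cut-off binarization and logistic classification of drain-fluid samples.

Each analyte value is coded 0 (non-pathological) or 1 (pathological) against
its clinical cut-off; by default a value strictly greater than the cut-off
is pathological (a drop of hemoglobin in drain fluid already signals
bleeding, hence its cut-off of 0), with the direction configurable per
analyte.  SNV intensities at the screened wavelengths serve as covariates
in a logistic regression fitted with (glmer-style) or without (glm-style) a
per-patient random intercept; the random intercept is integrated out by
Gauss-Hermite quadrature.  Discrimination is summarized by the AUC
(Mann-Whitney probability of correct ranking) and the balanced accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import optimize
from scipy.special import expit, log_expit, logsumexp, roots_hermitenorm
from scipy.stats import rankdata

from .spectra import CutoffTable, LabPanel


@dataclass
class BinaryLabelSet:
    analyte: str
    labels: dict[str, int]  # sample_id -> 0/1
    cutoff: float
    direction: str

    def vector(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Labels aligned to a sample order; missing samples become NaN."""
        return np.array(
            [self.labels.get(sid, np.nan) for sid in sample_ids], dtype=float
        )


def binarize(
    panels: Iterable[LabPanel], cutoffs: CutoffTable, analyte: str
) -> BinaryLabelSet:
    """0/1 pathological coding of one analyte; missing values are excluded."""
    cut = cutoffs[analyte]
    labels: dict[str, int] = {}
    for panel in panels:
        value = panel.get(analyte)
        if value is None:
            continue
        if cut.direction == "above":
            labels[panel.sample_id] = int(value > cut.value)
        else:
            labels[panel.sample_id] = int(value < cut.value)
    return BinaryLabelSet(analyte, labels, cut.value, cut.direction)


# ---------------------------------------------------------------------------
# logistic models


@dataclass
class LogisticFit:
    feature_names: list[str]
    beta: np.ndarray  # intercept first
    tau: float  # random-intercept SD; 0.0 for the plain glm
    loglik: float
    converged: bool
    random_intercept: bool
    separation_suspected: bool = False
    se: np.ndarray | None = None
    message: str = ""

    @property
    def tau2(self) -> float:
        return self.tau**2

    def predict_proba(self, X) -> np.ndarray:
        """Population-level probability (random effect at its mean, 0).

        New patients carry no estimated effect, so out-of-fold prediction
        uses the population intercept.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        Xd = np.column_stack([np.ones(X.shape[0]), X])
        return expit(Xd @ self.beta)


def _negll_glmer(params, Xd, y, group_idx, n_groups, nodes, log_w):
    beta, tau = params[:-1], params[-1]
    eta = Xd @ beta
    # (n_obs, n_nodes): log Bernoulli likelihood at each shifted linear predictor
    shifted = eta[:, None] + tau * nodes[None, :]
    ll_obs = np.where(y[:, None] == 1, log_expit(shifted), log_expit(-shifted))
    group_ll = np.zeros((n_groups, nodes.size))
    np.add.at(group_ll, group_idx, ll_obs)
    return -logsumexp(group_ll + log_w[None, :], axis=1).sum()


def fit_logistic(
    X,
    y,
    random_intercept: bool = False,
    groups=None,
    feature_names: list[str] | None = None,
    gh_nodes: int = 25,
    tau_max: float = 5.0,
) -> LogisticFit:
    """Maximum-likelihood logistic regression, optionally with a per-patient
    random intercept.

    The plain model is fitted via statsmodels; the mixed model maximizes the
    Gauss-Hermite-integrated likelihood directly.  Perfect separation is
    flagged on the fit rather than raised.

    ``tau_max`` bounds the random-intercept SD on the logit scale: under
    patient-level quasi-separation (every patient all-pathological or
    all-normal, common for rare outcomes) the unbounded MLE runs to
    infinity and destroys the fixed effects; an SD of 5 logits already
    saturates the per-patient probabilities, so the bound only bites in
    that degenerate regime, and a fit sitting on it is flagged.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("labels must be coded 0/1")
    if classes.size < 2:
        raise ValueError("both classes must be present")
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(p)]
    Xd = sm.add_constant(X, has_constant="add")

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            glm = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
            beta = np.asarray(glm.params, dtype=float)
            se = np.asarray(glm.bse, dtype=float)
            loglik = float(glm.llf)
            converged = bool(glm.mle_retvals.get("converged", True))
        except Exception as exc:  # perfect separation can abort the fit outright
            separation = True
            beta = np.zeros(p + 1)
            se = np.full(p + 1, np.nan)
            loglik = float("nan")
            converged = False
            warnings.warn(f"logistic fit failed: {exc}", stacklevel=2)
        for w in caught:
            if issubclass(w.category, PerfectSeparationWarning):
                separation = True
    if np.any(np.abs(beta) > 1e3):
        separation = True

    if not random_intercept:
        return LogisticFit(
            feature_names=list(feature_names),
            beta=beta,
            tau=0.0,
            loglik=loglik,
            converged=converged,
            random_intercept=False,
            separation_suspected=separation,
            se=se,
        )

    if groups is None:
        raise ValueError("random_intercept requires groups")
    uniq, codes = np.unique(np.asarray(groups), return_inverse=True)
    nodes, w = roots_hermitenorm(gh_nodes)
    log_w = np.log(w / w.sum())
    start = np.concatenate([beta if np.all(np.isfinite(beta)) else np.zeros(p + 1), [0.5]])
    res = optimize.minimize(
        _negll_glmer,
        start,
        args=(Xd, y, codes, len(uniq), nodes, log_w),
        method="L-BFGS-B",
        bounds=[(None, None)] * (p + 1) + [(0.0, tau_max)],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    beta_re = res.x[:-1]
    if np.any(np.abs(beta_re) > 1e3) or res.x[-1] >= tau_max - 1e-6:
        separation = True
    return LogisticFit(
        feature_names=list(feature_names),
        beta=beta_re,
        tau=float(res.x[-1]),
        loglik=-float(res.fun),
        converged=bool(res.success),
        random_intercept=True,
        separation_suspected=separation,
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# discrimination metrics


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """AUC as the Mann-Whitney probability of correct ranking (ties count 1/2),
    plus the ROC polyline as an array of (false positive rate, true positive
    rate) points."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError("scores/labels length mismatch")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties -> 1/2 credit
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    # collapse tied thresholds to the last index of each tie block
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], sorted_scores.size - 1]
    points = np.column_stack(
        [np.r_[0.0, fps[distinct] / n0], np.r_[0.0, tps[distinct] / n1]]
    )
    return float(auc), points


def balanced_accuracy(probabilities, labels, threshold: float = 0.5) -> float:
    """(sensitivity + specificity) / 2 at a probability threshold (default 0.5)."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present in the truth")
    predicted = probabilities >= threshold
    sensitivity = float(predicted[pos].mean())
    specificity = float((~predicted[neg]).mean())
    return 0.5 * (sensitivity + specificity)
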