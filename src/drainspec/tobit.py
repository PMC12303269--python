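"""Censored (Tobit) regression with an optional per-patient random intercept.

Laboratory concentrations cannot fall below the assay floor, so the response
is modelled as a latent Gaussian linear model observed only above a
censoring bound L (left-censoring, default L = 0):

    y*_ij = x_ij' beta + b_i + eps_ij,   eps_ij ~ N(0, sigma^2)
    y_ij  = max(y*_ij, L)

with an optional patient-level intercept b_i ~ N(0, tau^2) capturing the
correlation among repeated samples of the same patient.  Uncensored
observations contribute a Gaussian density term, censored ones the
probability mass below the bound:

    ll = sum_unc log[ phi((y - xb)/sigma) / sigma ] + sum_cens log Phi((L - xb)/sigma)

The random intercept is integrated out of the likelihood by Gauss-Hermite
quadrature (node count configurable); maximization uses L-BFGS-B with an
analytic gradient in the fixed-effects case.  Wald standard errors come from
the numerically differentiated Hessian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import log_ndtr, logsumexp, roots_hermitenorm

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _as_design(X, add_intercept: bool):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    return X


def tobit_loglik(beta, sigma, X, y, censor_bound: float = 0.0) -> float:
    """Log-likelihood of the fixed-effects left-censored Gaussian model.

    With no censored observations this reduces exactly to the ordinary
    Gaussian (OLS) log-likelihood.
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if np.any(y < censor_bound - 1e-12):
        raise ValueError("responses below the censoring bound are impossible")
    mu = X @ beta
    censored = y <= censor_bound
    z = (y[~censored] - mu[~censored]) / sigma
    ll = np.sum(-np.log(sigma) - 0.5 * z * z - _LOG_SQRT_2PI)
    if censored.any():
        ll += np.sum(log_ndtr((censor_bound - mu[censored]) / sigma))
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite Tobit log-likelihood")
    return float(ll)


def tobit_mixed_loglik(
    beta, sigma, tau, X, y, groups, censor_bound: float = 0.0, gh_nodes: int = 25
) -> float:
    """Log-likelihood with the per-group random intercept integrated out by
    Gauss-Hermite quadrature (the quantity :func:`fit_tobit` maximizes)."""
    X = _as_design(X, add_intercept=False)
    Xd = np.column_stack([np.ones(X.shape[0]), X])
    y = np.asarray(y, dtype=float)
    censored = y <= censor_bound
    codes, uniq = _encode_groups(groups)
    nodes, w = roots_hermitenorm(gh_nodes)
    w = w / w.sum()
    params = np.concatenate([np.atleast_1d(beta), [np.log(sigma)], [tau]])
    return -float(
        _negll_random(params, Xd, y, censored, censor_bound, codes, len(uniq), nodes, w)
    )


def _loglik_terms(params, X, y, censored, L):
    """Per-observation log-likelihood and gradient pieces; params = (beta, log sigma)."""
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    mu = X @ beta
    ll = np.empty_like(y)
    dmu = np.empty_like(y)  # d ll_i / d mu_i
    dls = np.empty_like(y)  # d ll_i / d log sigma
    z = (y[~censored] - mu[~censored]) / sigma
    ll[~censored] = -log_sigma - 0.5 * z * z - _LOG_SQRT_2PI
    dmu[~censored] = z / sigma
    dls[~censored] = z * z - 1.0
    if censored.any():
        a = (L - mu[censored]) / sigma
        log_phi = -0.5 * a * a - _LOG_SQRT_2PI
        ratio = np.exp(log_phi - log_ndtr(a))  # phi(a)/Phi(a), stable
        ll[censored] = log_ndtr(a)
        dmu[censored] = -ratio / sigma
        dls[censored] = -a * ratio
    return ll, dmu, dls


def _negll_fixed(params, X, y, censored, L):
    ll, dmu, dls = _loglik_terms(params, X, y, censored, L)
    grad = np.concatenate([X.T @ dmu, [dls.sum()]])
    return -ll.sum(), -grad


def _negll_random(params, X, y, censored, L, group_idx, n_groups, nodes, weights):
    """-log-likelihood with a random intercept integrated by Gauss-Hermite.

    params = (beta, log sigma, tau);  per group i:
        L_i = sum_k w_k prod_j f(y_ij | mu_ij + tau * z_k)
    evaluated in log space via logsumexp.
    """
    beta, log_sigma, tau = params[:-2], params[-2], params[-1]
    sigma = np.exp(log_sigma)
    mu = X @ beta
    # (n_obs, n_nodes) matrix of shifted means
    shifted = mu[:, None] + tau * nodes[None, :]
    ll_obs = np.empty_like(shifted)
    unc = ~censored
    z = (y[unc, None] - shifted[unc]) / sigma
    ll_obs[unc] = -log_sigma - 0.5 * z * z - _LOG_SQRT_2PI
    if censored.any():
        a = (L - shifted[censored]) / sigma
        ll_obs[censored] = log_ndtr(a)
    # sum over observations within each group, per node
    group_ll = np.zeros((n_groups, nodes.size))
    np.add.at(group_ll, group_idx, ll_obs)
    total = logsumexp(group_ll + np.log(weights)[None, :], axis=1).sum()
    return -total


@dataclass
class TobitFit:
    """A fitted (possibly mixed) Tobit model."""

    feature_names: list[str]
    beta: np.ndarray  # intercept first
    sigma: float
    tau: float  # random-intercept SD; 0.0 when absent
    censor_bound: float
    loglik: float
    converged: bool
    random_intercept: bool
    n_obs: int
    n_censored: int
    se: np.ndarray | None = None  # for (beta, log sigma[, tau])
    pvalues: dict = field(default_factory=dict)  # Wald p per feature (not intercept)
    message: str = ""

    @property
    def tau2(self) -> float:
        return self.tau**2

    def linear_predictor(self, X) -> np.ndarray:
        X = _as_design(X, add_intercept=True)
        return X @ self.beta

    def predict(self, X, kind: str = "expected") -> np.ndarray:
        """Predicted response for new samples (random effect at its mean, 0).

        ``kind="latent"`` returns x'beta; ``kind="expected"`` returns
        E[max(y*, L)], the mean of the censored response, which is what the
        observed laboratory value estimates.
        """
        from scipy.stats import norm

        mu = self.linear_predictor(X)
        if kind == "latent":
            return mu
        if kind != "expected":
            raise ValueError("kind must be 'latent' or 'expected'")
        # marginal latent SD includes the random-intercept variance
        s = float(np.hypot(self.sigma, self.tau))
        d = (mu - self.censor_bound) / s
        return (
            self.censor_bound * norm.cdf(-d)
            + mu * norm.cdf(d)
            + s * norm.pdf(d)
        )


def _numerical_hessian(fun, x0, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    x0 = np.asarray(x0, dtype=float)
    k = x0.size
    H = np.empty((k, k))
    steps = eps * np.maximum(1.0, np.abs(x0))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = steps[i]
            ej[j] = steps[j]
            f_pp = fun(x0 + ei + ej)
            f_pm = fun(x0 + ei - ej)
            f_mp = fun(x0 - ei + ej)
            f_mm = fun(x0 - ei - ej)
            H[i, j] = H[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4 * steps[i] * steps[j])
    return H


def fit_tobit(
    X,
    y,
    censor_bound: float = 0.0,
    random_intercept: bool = False,
    groups=None,
    feature_names: list[str] | None = None,
    gh_nodes: int = 25,
    compute_se: bool = True,
    warn_per_coef: int = 10,
) -> TobitFit:
    """Maximum-likelihood Tobit fit; design matrix gains an intercept column.

    ``groups`` (required with ``random_intercept``) is the patient id per
    observation.  Non-convergence is flagged on the returned fit, never
    silent.
    """
    import warnings

    X = _as_design(X, add_intercept=False)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(p)]
    if len(feature_names) != p:
        raise ValueError("feature_names length mismatch")
    if n < warn_per_coef * (p + 1):
        warnings.warn(
            f"only {n} observations for {p + 1} coefficients "
            f"(< {warn_per_coef} per coefficient)",
            stacklevel=2,
        )
    # standardize columns (location + scale) for optimizer conditioning;
    # coefficients and SEs are mapped back to the raw scale afterwards
    col_mean = X.mean(axis=0) if p else np.empty(0)
    col_scale = X.std(axis=0) if p else np.empty(0)
    col_scale = np.where(col_scale > 0, col_scale, 1.0)
    Xs = (X - col_mean) / col_scale
    Xd = np.column_stack([np.ones(n), Xs])
    censored = y <= censor_bound
    if censored.all():
        raise ValueError("all observations censored; model unidentifiable")

    # start at OLS on all data (censoring shrinks toward the bound; good enough)
    beta0, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta0
    sigma0 = max(float(resid.std(ddof=1)), 1e-3)
    start = np.concatenate([beta0, [np.log(sigma0)]])

    res = optimize.minimize(
        _negll_fixed,
        start,
        args=(Xd, y, censored, censor_bound),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    params = res.x
    converged = bool(res.success)
    message = res.message if isinstance(res.message, str) else str(res.message)

    tau = 0.0
    if random_intercept:
        if groups is None:
            raise ValueError("random_intercept requires groups")
        codes, uniq = _encode_groups(groups)
        z_nodes, w = roots_hermitenorm(gh_nodes)
        w = w / w.sum()
        start_re = np.concatenate([params, [0.5 * np.exp(params[-1])]])
        res_re = optimize.minimize(
            _negll_random,
            start_re,
            args=(Xd, y, censored, censor_bound, codes, len(uniq), z_nodes, w),
            method="L-BFGS-B",
            bounds=[(None, None)] * (p + 1) + [(None, None), (0.0, None)],
            options={"maxiter": 500, "ftol": 1e-12},
        )
        params = res_re.x
        tau = float(params[-1])
        converged = bool(res_re.success)
        message = str(res_re.message)
        loglik = -float(res_re.fun)
        negll = lambda q: _negll_random(  # noqa: E731
            q, Xd, y, censored, censor_bound, codes, len(uniq), z_nodes, w
        )
        free = params[:-1] if tau < 1e-8 else params  # tau at boundary: drop from Hessian
    else:
        loglik = -float(res.fun)
        negll = lambda q: _negll_fixed(q, Xd, y, censored, censor_bound)[0]  # noqa: E731
        free = params

    beta_std = params[: p + 1]
    sigma = float(np.exp(params[p + 1]))
    # back-transform to the raw covariate scale
    slopes = beta_std[1:] / col_scale
    intercept = beta_std[0] - float(slopes @ col_mean)
    beta = np.concatenate([[intercept], slopes])

    se = None
    pvalues: dict[str, float] = {}
    if compute_se:
        from scipy.stats import norm as _norm

        if random_intercept and tau < 1e-8:
            H = _numerical_hessian(lambda q: negll(np.append(q, tau)), free)
        else:
            H = _numerical_hessian(negll, free)
        try:
            cov = np.linalg.inv(H)
            diag = np.diag(cov).copy()
            diag[diag < 0] = np.nan
            se = np.sqrt(diag)
            # delta-method map of the intercept/slope SEs to the raw scale
            if p and np.all(np.isfinite(se[: p + 1])):
                c = np.zeros(free.size)
                c[0] = 1.0
                c[1 : p + 1] = -col_mean / col_scale
                var_icpt = float(c @ cov @ c)
                se = se.copy()
                se[0] = np.sqrt(var_icpt) if var_icpt >= 0 else np.nan
            if p:
                se[1 : p + 1] = se[1 : p + 1] / col_scale
            for i, name in enumerate(feature_names):
                if np.isfinite(se[i + 1]) and se[i + 1] > 0:
                    zstat = beta[i + 1] / se[i + 1]
                    pvalues[name] = float(2.0 * _norm.sf(abs(zstat)))
                else:
                    pvalues[name] = float("nan")
        except np.linalg.LinAlgError:
            pvalues = {name: float("nan") for name in feature_names}

    return TobitFit(
        feature_names=list(feature_names),
        beta=beta,
        sigma=sigma,
        tau=tau,
        censor_bound=censor_bound,
        loglik=loglik,
        converged=converged,
        random_intercept=random_intercept,
        n_obs=n,
        n_censored=int(censored.sum()),
        se=se,
        pvalues=pvalues,
        message=message,
    )


def _encode_groups(groups) -> tuple[np.ndarray, list]:
    groups = np.asarray(groups)
    uniq, codes = np.unique(groups, return_inverse=True)
    return codes, list(uniq)


@dataclass
class RegressionMetrics:
    """Summary of a cross-validated regression: raw and optimism-corrected MSE.

    ``mse_global_corrected = mse_global + mean(fold_diffs)`` where each fold
    difference is (out-of-sample MSE - inner-sample MSE), and
    ``r2 = 1 - mse_global_corrected / variance`` with ``variance`` the sample
    variance of the response over the full analysis set.
    """

    mse_global: float
    fold_diffs: np.ndarray
    variance: float
    mse_global_corrected: float = field(init=False)
    r2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("response variance must be positive")
        self.fold_diffs = np.asarray(self.fold_diffs, dtype=float)
        self.mse_global_corrected = float(self.mse_global + self.fold_diffs.mean())
        self.r2 = 1.0 - self.mse_global_corrected / self.variance


def mean_squared_error(predictions, truth) -> float:
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predictions.shape != truth.shape:
        raise ValueError("shape mismatch between predictions and truth")
    return float(np.mean((predictions - truth) ** 2))


def regression_metrics(mse_global: float, fold_diffs, variance: float) -> RegressionMetrics:
    """Optimism-corrected MSE and R^2 from the per-fold difference table."""
    return RegressionMetrics(float(mse_global), fold_diffs, float(variance))


def backward_select(
    X,
    y,
    feature_names: list[str],
    threshold: float = 0.05,
    fit_kwargs: dict | None = None,
) -> tuple[TobitFit, list[str]]:
    """Backward elimination by Wald p-value.

    Repeatedly drops the covariate with the largest p-value above
    ``threshold`` and refits, until every remaining covariate is retained.
    The intercept is never removed.  Returns the final fit and the removal
    trace (dropped names in order); an intercept-only model is allowed.
    """
    import pandas as pd

    fit_kwargs = dict(fit_kwargs or {})
    Xf = pd.DataFrame(np.asarray(X, dtype=float), columns=list(feature_names))
    removed: list[str] = []
    while True:
        fit = fit_tobit(
            Xf.to_numpy() if Xf.shape[1] else np.empty((len(y), 0)),
            y,
            feature_names=list(Xf.columns),
            **fit_kwargs,
        )
        if not Xf.shape[1]:
            return fit, removed
        pvals = {k: (v if np.isfinite(v) else 1.0) for k, v in fit.pvalues.items()}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= threshold:
            return fit, removed
        Xf = Xf.drop(columns=[worst])
        removed.append(worst)
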