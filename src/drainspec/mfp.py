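"""Multivariable fractional polynomials (MFP).

Each covariate x may enter the model transformed as x^p with p drawn from
the conventional eight-power set {-2, -1, -0.5, 0, 0.5, 1, 2, 3}, where
p = 0 denotes ln x.  A second-degree transform (FP2) combines two powers
(p1, p2); repeated powers (p, p) yield the pair (x^p, x^p ln x).  Because
the power set requires strictly positive arguments (and SNV intensities are
negative-valued), every covariate is first shifted to positivity and scaled
by a power of ten.

Function selection follows the closed-test sequence: the best FP2 is
compared against the linear term (LRT, 3 df); if that is not significant at
alpha the covariate stays linear; otherwise FP2 is compared against the
best FP1 (2 df) to decide between them.  Covariates with <= 3 distinct
values are forced linear.  The procedure cycles over covariates, updating
one transform at a time with the others held fixed, until stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Callable

import numpy as np
from scipy import stats

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class CovariateTransform:
    """Shift/scale plus selected powers for one covariate.

    ``z_floor`` is the smallest shifted/scaled value seen during training;
    new data below it (e.g. a left-out fold extending past the training
    minimum) is floored there so negative powers stay bounded.
    """

    powers: tuple[float, ...]  # () is not allowed; (1.0,) means linear
    shift: float
    scale: float
    z_floor: float = 1e-8

    @property
    def degree(self) -> int:
        return len(self.powers)

    def basis(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the FP basis columns for (already raw) covariate values."""
        z = (np.asarray(x, dtype=float) + self.shift) / self.scale
        z = np.maximum(z, self.z_floor)
        cols = []
        prev_power = None
        for p in self.powers:
            col = np.log(z) if p == 0.0 else z**p
            if prev_power is not None and p == prev_power:
                col = cols[-1] * np.log(z)  # repeated power: x^p * ln x
            cols.append(col)
            prev_power = p
        return np.column_stack(cols)

    def column_names(self, name: str) -> list[str]:
        labels = []
        prev = None
        for p in self.powers:
            if prev is not None and p == prev:
                labels.append(f"{name}^{p:g}*ln")
            elif p == 0.0:
                labels.append(f"ln({name})")
            else:
                labels.append(f"{name}^{p:g}")
            prev = p
        return labels


@dataclass
class FPTransform:
    """Selected transforms for a whole design matrix."""

    transforms: dict[str, CovariateTransform] = field(default_factory=dict)

    def apply(self, X, feature_names: list[str]) -> tuple[np.ndarray, list[str]]:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        cols, names = [], []
        for j, name in enumerate(feature_names):
            tr = self.transforms[name]
            cols.append(tr.basis(X[:, j]))
            names.extend(tr.column_names(name))
        return np.hstack(cols), names


def _default_shift_scale(x: np.ndarray) -> tuple[float, float]:
    """Shift to positivity and scale by a power of ten to O(1) magnitude."""
    xmin, xmax = float(np.min(x)), float(np.max(x))
    if xmin > 0:
        shift = 0.0
    else:
        spread = xmax - xmin
        eps = spread / 100.0 if spread > 0 else 1.0
        shift = -xmin + eps
    top = xmax + shift
    scale = 10.0 ** np.floor(np.log10(top)) if top > 0 else 1.0
    return shift, float(scale)


def _fp2_pairs():
    return list(combinations_with_replacement(FP_POWERS, 2))


def mfp_search(
    X,
    y,
    feature_names: list[str] | None = None,
    fitter: Callable | None = None,
    alpha: float = 0.05,
    max_cycles: int = 3,
) -> FPTransform:
    """Select an FP transform per covariate by the closed-test procedure.

    ``fitter(design_matrix, y) -> loglik`` evaluates a candidate model;
    by default a fixed-effects Tobit fit (censoring at 0) is used.  Each
    candidate design keeps the other covariates at their current transforms.
    """
    from .tobit import fit_tobit

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]

    if fitter is None:
        def fitter(design, response):  # noqa: F811
            return fit_tobit(design, response, compute_se=False).loglik

    def _with_floor(powers, j):
        shift, scale = _default_shift_scale(X[:, j])
        z_floor = (float(np.min(X[:, j])) + shift) / scale
        return CovariateTransform(powers, shift, scale, z_floor)

    current = FPTransform(
        {name: _with_floor((1.0,), j) for j, name in enumerate(feature_names)}
    )

    def loglik_with(name_j: str, candidate: CovariateTransform) -> float:
        cols = []
        for j, name in enumerate(feature_names):
            tr = candidate if name == name_j else current.transforms[name]
            cols.append(tr.basis(X[:, j]))
        return fitter(np.hstack(cols), y)

    for _ in range(max_cycles):
        changed = False
        for j, name in enumerate(feature_names):
            x = X[:, j]
            if np.unique(x).size <= 3:
                chosen = _with_floor((1.0,), j)
            else:
                linear = _with_floor((1.0,), j)
                ll_lin = loglik_with(name, linear)
                fp1 = [
                    (loglik_with(name, _with_floor((pw,), j)), (pw,))
                    for pw in FP_POWERS
                ]
                ll_fp1, powers_fp1 = max(fp1, key=lambda t: t[0])
                fp2 = [
                    (loglik_with(name, _with_floor(pair, j)), pair)
                    for pair in _fp2_pairs()
                ]
                ll_fp2, powers_fp2 = max(fp2, key=lambda t: t[0])
                # closed test: FP2 vs linear (3 df), then FP2 vs FP1 (2 df)
                p_vs_lin = stats.chi2.sf(2.0 * max(ll_fp2 - ll_lin, 0.0), df=3)
                if p_vs_lin >= alpha:
                    chosen = linear
                else:
                    p_vs_fp1 = stats.chi2.sf(2.0 * max(ll_fp2 - ll_fp1, 0.0), df=2)
                    chosen = _with_floor(
                        powers_fp2 if p_vs_fp1 < alpha else powers_fp1, j
                    )
            if chosen.powers != current.transforms[name].powers:
                changed = True
            current.transforms[name] = chosen
        if not changed:
            break
    return current


def rank_fp2_candidates(x, y, fitter=None, shift_scale=None) -> list[tuple[float, tuple]]:
    """All 36 FP2 candidates for a single covariate, best first (diagnostic)."""
    from .tobit import fit_tobit

    x = np.asarray(x, dtype=float)
    if fitter is None:
        def fitter(design, response):  # noqa: F811
            return fit_tobit(design, response, compute_se=False).loglik
    shift, scale = shift_scale or _default_shift_scale(x)
    z_floor = (float(np.min(x)) + shift) / scale
    out = []
    for pair in _fp2_pairs():
        tr = CovariateTransform(pair, shift, scale, z_floor)
        out.append((fitter(tr.basis(x), y), pair))
    out.sort(key=lambda t: -t[0])
    return out
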