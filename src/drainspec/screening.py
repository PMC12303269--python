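"""Wavelength-analyte correlation screening.

For one pathway, the SNV-scaled spectra form an (n x 288) matrix S; each
column holds the scaled intensities at one wavelength across samples.  For
each laboratory analyte vector l, Pearson's r and a two-sided p-value are
computed column by column, giving a correlation curve r(lambda), p(lambda).
Channels with |r| > 0.3 and p < 0.01 are candidate covariates for the
regression and classification models; adjacent passing channels are
collapsed to their local |r| extremum so one absorption peak yields one
feature.

No multiple-testing correction is applied across the 288 x 3 tests: the
screening is deliberately permissive (the downstream cross-validated models
are the guard against false positives), at the documented cost of an
inflated family-wise error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spectra import N_CHANNELS, WavelengthGrid


@dataclass
class CorrelationCurve:
    analyte: str
    pathway: str
    r: np.ndarray
    p: np.ndarray
    n_used: int
    grid: WavelengthGrid = field(default_factory=WavelengthGrid.linear)

    def __post_init__(self) -> None:
        finite = np.isfinite(self.r)
        if np.any(np.abs(self.r[finite]) > 1 + 1e-12):
            raise ValueError("correlation outside [-1, 1]")
        if np.any((self.p[finite] < -1e-12) | (self.p[finite] > 1 + 1e-12)):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class SelectedFeature:
    analyte: str
    pathway: str
    channel: int
    wavelength_nm: float
    r: float
    p: float

    @property
    def name(self) -> str:
        return f"{self.pathway}_{self.wavelength_nm:.2f}nm"


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided p-value.

    Pairs with a missing value in either vector are removed.  The p-value
    comes from the exact t transform t = r * sqrt((n-2)/(1-r^2)) with n-2
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        raise ValueError("zero variance in x or y")
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def _columnwise_pearson(S: np.ndarray, l: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized Pearson r/p between each column of S and the vector l."""
    keep = np.isfinite(l) & np.all(np.isfinite(S), axis=1)
    S, l = S[keep], l[keep]
    n = l.size
    if n < 3:
        raise ValueError(f"need at least 3 complete samples, got {n}")
    if l.std() == 0.0:
        raise ValueError("laboratory vector is constant; correlation undefined")
    Sc = S - S.mean(axis=0)
    lc = l - l.mean()
    col_ss = (Sc * Sc).sum(axis=0)
    denom = np.sqrt(col_ss * (lc * lc).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Sc * lc[:, None]).sum(axis=0) / denom
    r = np.clip(r, -1.0, 1.0)
    r[denom == 0.0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) == 1.0] = 0.0
    p[~np.isfinite(r)] = np.nan
    return r, p, n


def build_curves(
    snv_by_pathway: dict[str, "np.ndarray | object"],
    lab_values,
    analyte: str,
    sample_ids_by_pathway: dict[str, list[str]] | None = None,
    grid: WavelengthGrid | None = None,
) -> dict[str, CorrelationCurve]:
    """Correlation curves for one analyte across all available pathways.

    ``snv_by_pathway`` maps pathway -> (n, 288) SNV matrix; ``lab_values`` is
    either an aligned vector (same row order) or a mapping/Series keyed by
    sample id, in which case ``sample_ids_by_pathway`` provides the row keys.
    Missing lab values are removed pairwise.
    """
    grid = grid or WavelengthGrid.linear()
    curves: dict[str, CorrelationCurve] = {}
    for pathway, S in snv_by_pathway.items():
        S = np.asarray(S, dtype=float)
        if sample_ids_by_pathway is not None:
            ids = sample_ids_by_pathway[pathway]
            l = np.array(
                [float(lab_values.get(sid, np.nan)) for sid in ids], dtype=float
            )
        else:
            l = np.asarray(lab_values, dtype=float)
        if S.shape[0] != l.size:
            raise ValueError(
                f"pathway {pathway}: {S.shape[0]} spectra vs {l.size} lab values"
            )
        r, p, n = _columnwise_pearson(S, l)
        curves[pathway] = CorrelationCurve(analyte, pathway, r, p, n, grid)
    return curves


def select_features(
    curves: dict[str, CorrelationCurve],
    r_threshold: float = 0.3,
    p_threshold: float = 0.01,
    max_per_pathway: int | None = None,
    peak_window: int = 3,
    force_wavelengths: dict[str, list[float]] | None = None,
) -> list[SelectedFeature]:
    """Candidate wavelengths passing the |r| > 0.3, p < 0.01 gates.

    Adjacent passing channels are collapsed: a channel is kept only if its
    |r| is the maximum within ``peak_window`` channels on either side.
    ``force_wavelengths`` maps pathway -> wavelengths (nm) to force-include
    (absorption maxima known from the literature), resolved to the nearest
    grid channel.  Features are ranked by |r| descending.
    """
    features: list[SelectedFeature] = []
    for pathway, curve in curves.items():
        absr = np.abs(np.where(np.isfinite(curve.r), curve.r, 0.0))
        passing = (absr > r_threshold) & (curve.p < p_threshold) & np.isfinite(curve.r)
        picked: list[int] = []
        for ch in np.nonzero(passing)[0]:
            lo, hi = max(0, ch - peak_window), min(N_CHANNELS, ch + peak_window + 1)
            window = absr[lo:hi]
            if absr[ch] >= window.max() and ch - lo == int(np.argmax(window)):
                picked.append(int(ch))
        if force_wavelengths and pathway in force_wavelengths:
            for nm in force_wavelengths[pathway]:
                ch = curve.grid.nearest_channel(nm)
                if ch not in picked:
                    picked.append(ch)
        picked.sort(key=lambda ch: -absr[ch])
        if max_per_pathway is not None:
            picked = picked[:max_per_pathway]
        for ch in picked:
            features.append(
                SelectedFeature(
                    analyte=curve.analyte,
                    pathway=pathway,
                    channel=ch,
                    wavelength_nm=curve.grid[ch],
                    r=float(curve.r[ch]),
                    p=float(curve.p[ch]),
                )
            )
    features.sort(key=lambda f: -abs(f.r))
    return features
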