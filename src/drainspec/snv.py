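"""Standard Normal Variate (SNV) preprocessing and spectral diagnostics.

Raw spectra differ by large per-sample multiplicative scatter (optical path
variation, turbidity, lamp drift).  SNV removes it by centring and scaling
each spectrum individually:

    s_tilde_i = (s_i - mean(s)) / sd(s)

so every scaled spectrum has zero mean and unit variance across its 288
channels.  Scaling is applied per sample, per pathway/exposure setting,
independently.  The sample standard deviation (n-1 denominator) is used;
with 288 channels the difference from the population convention is below
0.2%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import INTENSITY_CEILING, SpectralCube


@dataclass
class SNVSpectrum:
    """An SNV-scaled spectrum with its original location/scale retained."""

    values: np.ndarray
    mu: float
    sigma: float
    sample_id: str | None = None
    pathway: str | None = None

    def invert(self) -> np.ndarray:
        """Reconstruct the original intensities."""
        return self.values * self.sigma + self.mu


def snv_normalize(
    spectrum, sample_id: str | None = None, pathway: str | None = None
) -> SNVSpectrum:
    """Scale one spectrum to zero mean / unit variance.

    Raises ``ValueError`` on constant spectra (zero variance) rather than
    propagating NaNs.
    """
    values = np.asarray(spectrum, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("SNV needs a 1-d spectrum with at least 2 points")
    mu = float(values.mean())
    sigma = float(values.std(ddof=1))
    if sigma == 0.0:
        raise ValueError(
            f"zero variance spectrum{f' (sample {sample_id})' if sample_id else ''}: "
            "SNV undefined"
        )
    return SNVSpectrum((values - mu) / sigma, mu, sigma, sample_id, pathway)


def snv_matrix(matrix) -> np.ndarray:
    """Row-wise SNV over an (n, channels) intensity matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("expected an (n, channels) matrix with >= 2 channels")
    mu = m.mean(axis=1, keepdims=True)
    sigma = m.std(axis=1, ddof=1, keepdims=True)
    if np.any(sigma == 0):
        rows = np.nonzero(sigma[:, 0] == 0)[0][:5].tolist()
        raise ValueError(f"zero variance spectrum at row(s) {rows}: SNV undefined")
    return (m - mu) / sigma


def per_wavelength_sd(matrix) -> tuple[np.ndarray, float]:
    """Column-wise sample SD across spectra, plus its mean over channels.

    This is the diagnostic used to quantify how strongly SNV collapses
    between-sample scatter: the mean per-wavelength SD drops by orders of
    magnitude once the multiplicative component is removed.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need at least two spectra to compute a per-wavelength SD")
    sd = m.std(axis=0, ddof=1)
    return sd, float(sd.mean())


def saturation_mask(cube: SpectralCube, ceiling: float = INTENSITY_CEILING) -> dict[str, np.ndarray]:
    """Per-pathway boolean mask of channels at the detector ceiling."""
    return {pw: vec >= ceiling for pw, vec in cube.pathway_spectra.items()}
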