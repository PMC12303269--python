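"""Core data model for drain-fluid spectrometry.

A bedside mini-spectrometer records, for every drain-fluid sample, light
intensity over 288 discrete channels spanning the 340-850 nm range.  Each
sample is measured through three optical pathways -- direct transmission
(DT), angular transmission (AT) and angular reflection (AR) -- each with its
own fixed exposure time.  Intensities are unitless detector counts in
[0, 65000]; 65000 is the saturation ceiling.

Alongside the spectra, a central-laboratory panel of 14 analytes is measured
per sample (hemoglobin, bilirubin, amylase, ...).  Samples are nested within
patients, and several patients contribute repeated samples, which is why the
downstream models carry per-patient random intercepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

N_CHANNELS = 288
WAVELENGTH_MIN = 340.0
WAVELENGTH_MAX = 850.0
INTENSITY_CEILING = 65000.0

PATHWAYS = ("DT", "AT", "AR")
#: exposure time per optical pathway, microseconds
EXPOSURE_US = {"DT": 20, "AT": 200, "AR": 320}

#: the fixed 14-analyte vocabulary of the drainage panel
ANALYTES = (
    "albumin",
    "pancreatic_amylase",
    "bilirubin",
    "total_protein",
    "glucose",
    "uric_acid",
    "ldh",
    "lipase",
    "erythrocytes",
    "hemoglobin",
    "leukocytes",
    "mononuclear_cells",
    "polymorphonuclear_cells",
    "triglycerides",
)


class SpectraValidationError(ValueError):
    """Raised when a spectral table or cube violates the data contract."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Channel -> wavelength calibration for the 288-channel detector.

    The default is a linear grid placing channel 0 at 340 nm and channel 287
    at 850 nm.  Devices with a non-linear calibration may supply an explicit
    288-value wavelength list, which overrides the linear default.
    """

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.shape != (N_CHANNELS,):
            raise SpectraValidationError(
                f"calibration list must have length {N_CHANNELS}, got {wl.shape}"
            )
        if not np.all(np.diff(wl) > 0):
            raise SpectraValidationError("wavelength grid must be strictly increasing")
        if wl[0] < WAVELENGTH_MIN or wl[-1] > WAVELENGTH_MAX:
            raise SpectraValidationError(
                f"grid must lie within [{WAVELENGTH_MIN}, {WAVELENGTH_MAX}] nm"
            )
        object.__setattr__(self, "wavelengths", wl)

    @classmethod
    def linear(cls) -> "WavelengthGrid":
        return cls(np.linspace(WAVELENGTH_MIN, WAVELENGTH_MAX, N_CHANNELS))

    @property
    def channel_count(self) -> int:
        return N_CHANNELS

    def nearest_channel(self, wavelength_nm: float) -> int:
        """Index of the grid channel closest to a requested wavelength."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))

    def __getitem__(self, channel: int) -> float:
        if not 0 <= channel < N_CHANNELS:
            raise IndexError(f"channel {channel} outside 0..{N_CHANNELS - 1}")
        return float(self.wavelengths[channel])


def map_channel_to_wavelength(channel_index: int, grid_spec="linear") -> float:
    """Resolve a detector channel index to its wavelength in nm.

    ``grid_spec`` is either the string ``"linear"`` or an explicit 288-value
    calibration list.
    """
    if isinstance(grid_spec, str):
        if grid_spec != "linear":
            raise ValueError(f"unknown grid spec {grid_spec!r}")
        grid = WavelengthGrid.linear()
    elif isinstance(grid_spec, WavelengthGrid):
        grid = grid_spec
    else:
        grid = WavelengthGrid(np.asarray(grid_spec, dtype=float))
    return grid[channel_index]


@dataclass
class SpectralCube:
    """All spectra of one sample: up to three pathways x 288 channels."""

    sample_id: str
    patient_id: str
    pathway_spectra: dict[str, np.ndarray]
    grid: WavelengthGrid = field(default_factory=WavelengthGrid.linear)
    exposure_us: Mapping[str, int] = field(default_factory=lambda: dict(EXPOSURE_US))

    def __post_init__(self) -> None:
        if not str(self.patient_id):
            raise SpectraValidationError(
                f"sample {self.sample_id!r}: patient_id must be non-empty "
                "(random-effects models group by patient)"
            )
        clean: dict[str, np.ndarray] = {}
        for pathway, vec in self.pathway_spectra.items():
            if pathway not in PATHWAYS:
                raise SpectraValidationError(
                    f"sample {self.sample_id!r}: unknown pathway {pathway!r}"
                )
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (N_CHANNELS,):
                raise SpectraValidationError(
                    f"sample {self.sample_id!r} pathway {pathway}: expected "
                    f"{N_CHANNELS} channels, got {arr.shape}"
                )
            bad = np.nonzero((arr < 0) | (arr > INTENSITY_CEILING))[0]
            if bad.size:
                raise SpectraValidationError(
                    f"sample {self.sample_id!r} pathway {pathway}: intensity out of "
                    f"[0, {INTENSITY_CEILING:g}] at channel(s) {bad[:5].tolist()}"
                )
            clean[pathway] = arr
        self.pathway_spectra = clean

    @property
    def missing_pathways(self) -> tuple[str, ...]:
        return tuple(p for p in PATHWAYS if p not in self.pathway_spectra)

    def intensity(self, pathway: str, channel: int) -> float:
        return float(self.pathway_spectra[pathway][channel])


@dataclass
class LabPanel:
    """Central-laboratory measurements for one sample.

    ``values`` holds only the analytes actually measured; an absent key means
    the measurement is missing (never coerced to zero).  Units follow the
    laboratory convention per analyte (mg/dl, g/dl, U/l or counts/nl).
    """

    sample_id: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for analyte, value in self.values.items():
            if analyte not in ANALYTES:
                raise SpectraValidationError(
                    f"sample {self.sample_id!r}: unknown analyte {analyte!r}"
                )
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise SpectraValidationError(
                    f"sample {self.sample_id!r}: missing values must be omitted, "
                    f"not stored as None/NaN ({analyte})"
                )
            if value < 0:
                raise SpectraValidationError(
                    f"sample {self.sample_id!r}: negative lab value "
                    f"{analyte}={value}"
                )

    def get(self, analyte: str) -> float | None:
        return self.values.get(analyte)

    def is_missing(self, analyte: str) -> bool:
        return analyte not in self.values


@dataclass(frozen=True)
class Cutoff:
    value: float
    unit: str
    #: which side of the cut-off is pathological; "above" means value > cutoff
    direction: str = "above"

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ValueError(f"direction must be 'above' or 'below', got {self.direction!r}")


class CutoffTable:
    """Per-analyte pathological cut-offs.

    Defaults follow the study protocol: blood-chemistry laboratory cut-offs
    for the enzymatic/metabolic analytes, 0 for hemoglobin and the cellular
    markers (any presence in drain fluid may indicate bleeding), and
    2.5 (mg/dl resp. g/dl) for albumin and total protein as in ascites
    diagnostics.  A value strictly greater than the cut-off is labelled
    pathological by default; the direction is configurable per analyte.
    """

    def __init__(self, cutoffs: Mapping[str, Cutoff] | None = None):
        table = dict(DEFAULT_CUTOFFS)
        if cutoffs:
            table.update(cutoffs)
        missing = set(ANALYTES) - set(table)
        if missing:
            raise ValueError(f"cut-off table must cover all analytes; missing {sorted(missing)}")
        self._table = table

    def __getitem__(self, analyte: str) -> Cutoff:
        if analyte not in self._table:
            raise KeyError(f"unknown analyte {analyte!r}")
        return self._table[analyte]

    def __contains__(self, analyte: str) -> bool:
        return analyte in self._table

    def analytes(self) -> tuple[str, ...]:
        return tuple(self._table)


DEFAULT_CUTOFFS: dict[str, Cutoff] = {
    "triglycerides": Cutoff(200.0, "mg/dl"),
    "uric_acid": Cutoff(7.2, "mg/dl"),
    "albumin": Cutoff(2.5, "mg/dl"),
    "pancreatic_amylase": Cutoff(53.0, "U/l"),
    "bilirubin": Cutoff(1.2, "mg/dl"),
    "lipase": Cutoff(53.0, "U/l"),
    "glucose": Cutoff(50.0, "mg/dl"),
    "total_protein": Cutoff(2.5, "g/dl"),
    "ldh": Cutoff(247.0, "U/l"),
    "hemoglobin": Cutoff(0.0, "mg/dl"),
    "erythrocytes": Cutoff(0.0, "counts/nl"),
    "mononuclear_cells": Cutoff(0.0, "counts/nl"),
    "polymorphonuclear_cells": Cutoff(0.0, "counts/nl"),
    "leukocytes": Cutoff(0.0, "counts/nl"),
}


def cubes_to_matrix(
    cubes: Sequence[SpectralCube], pathway: str
) -> tuple[np.ndarray, list[str], list[str]]:
    """Stack one pathway's spectra into an (n, 288) matrix.

    Cubes missing the requested pathway are excluded (per-pathway analysis
    exclusion rather than sample deletion).  Returns the matrix plus aligned
    sample and patient id lists.
    """
    rows, sample_ids, patient_ids = [], [], []
    for cube in cubes:
        if pathway in cube.pathway_spectra:
            rows.append(cube.pathway_spectra[pathway])
            sample_ids.append(cube.sample_id)
            patient_ids.append(cube.patient_id)
    if not rows:
        return np.empty((0, N_CHANNELS)), sample_ids, patient_ids
    return np.vstack(rows), sample_ids, patient_ids


def panels_to_frame(panels: Iterable[LabPanel]):
    """Lab panels as a pandas DataFrame (rows=samples, columns=analytes, NaN=missing)."""
    import pandas as pd

    records = {p.sample_id: {a: p.values.get(a, np.nan) for a in ANALYTES} for p in panels}
    return pd.DataFrame.from_dict(records, orient="index", columns=list(ANALYTES))
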