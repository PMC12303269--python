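"""Readers and writers for the canonical spectral/laboratory table dialects.

Two text dialects are canonical and round-trip bit-exactly:

* long CSV  -- columns ``sample_id, patient_id, pathway, channel,
  wavelength_nm, intensity`` (one row per channel);
* wide CSV  -- one row per (sample, pathway) with 288 intensity columns
  ``ch000..ch287``.

A third dialect mirrors the layout of the study's deposited workbook
(``supplement_xlsx``): patient identifiers in column A, one spectrum per
pathway serialized in columns C-E, and the 14 laboratory values in columns
F-S.  Numeric cells in that dialect may use a decimal comma ("3,8"), which
is parsed as a decimal point.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spectra import (
    ANALYTES,
    EXPOSURE_US,
    INTENSITY_CEILING,
    N_CHANNELS,
    PATHWAYS,
    LabPanel,
    SpectralCube,
    SpectraValidationError,
    WavelengthGrid,
)

LONG_COLUMNS = ["sample_id", "patient_id", "pathway", "channel", "wavelength_nm", "intensity"]

#: spreadsheet column layout of the deposited data workbook
_S3_SPECTRA_COLS = {"DT": "spectrum_DT", "AT": "spectrum_AT", "AR": "spectrum_AR"}


def parse_decimal(cell) -> float:
    """Parse a numeric cell, accepting German-locale decimal commas ("3,8" -> 3.8)."""
    if cell is None:
        return np.nan
    if isinstance(cell, (int, float, np.integer, np.floating)):
        return float(cell)
    text = str(cell).strip()
    if not text:
        return np.nan
    return float(text.replace(",", "."))


# ---------------------------------------------------------------------------
# writers


def write_spectra_long(cubes: Sequence[SpectralCube], path) -> None:
    rows = []
    for cube in cubes:
        wl = cube.grid.wavelengths
        for pathway, vec in cube.pathway_spectra.items():
            for ch in range(N_CHANNELS):
                rows.append((cube.sample_id, cube.patient_id, pathway, ch, wl[ch], vec[ch]))
    pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def write_spectra_wide(cubes: Sequence[SpectralCube], path) -> None:
    cols = ["sample_id", "patient_id", "pathway"] + [f"ch{c:03d}" for c in range(N_CHANNELS)]
    rows = []
    for cube in cubes:
        for pathway, vec in cube.pathway_spectra.items():
            rows.append([cube.sample_id, cube.patient_id, pathway, *vec])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.17g")


def write_lab_table(panels: Sequence[LabPanel], path) -> None:
    rows = []
    for panel in panels:
        rows.append({"sample_id": panel.sample_id, **{a: panel.values.get(a, np.nan) for a in ANALYTES}})
    pd.DataFrame(rows, columns=["sample_id", *ANALYTES]).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_supplement_workbook(
    cubes: Sequence[SpectralCube], panels: Sequence[LabPanel], path
) -> None:
    """Write a workbook in the deposited-data layout (patient id in column A,
    serialized spectra in columns C-E, laboratory values in columns F-S)."""
    by_sample = {p.sample_id: p for p in panels}
    rows = []
    for cube in cubes:
        row = {"patient_id": cube.patient_id, "sample_id": cube.sample_id}
        for pw in PATHWAYS:
            if pw in cube.pathway_spectra:
                row[_S3_SPECTRA_COLS[pw]] = ";".join(
                    "%.17g" % v for v in cube.pathway_spectra[pw]
                )
            else:
                row[_S3_SPECTRA_COLS[pw]] = ""
        panel = by_sample.get(cube.sample_id)
        for analyte in ANALYTES:
            value = panel.values.get(analyte) if panel else None
            row[analyte] = np.nan if value is None else value
        rows.append(row)
    columns = ["patient_id", "sample_id", *_S3_SPECTRA_COLS.values(), *ANALYTES]
    pd.DataFrame(rows, columns=columns).to_excel(path, index=False)


# ---------------------------------------------------------------------------
# readers


def _validate_intensities(values: np.ndarray, where: str, on_range_error: str) -> np.ndarray:
    bad = (values < 0) | (values > INTENSITY_CEILING)
    if not bad.any():
        return values
    channels = np.nonzero(bad)[0][:5].tolist()
    msg = (
        f"{where}: intensity outside [0, {INTENSITY_CEILING:g}] at channel(s) "
        f"{channels} (value(s) {values[bad][:5].tolist()})"
    )
    if on_range_error == "clip":
        warnings.warn(msg + " -- clipped", stacklevel=3)
        return np.clip(values, 0.0, INTENSITY_CEILING)
    raise SpectraValidationError(msg)


def read_spectra_table(
    path, dialect: str = "canonical_csv", on_range_error: str = "raise"
) -> list[SpectralCube]:
    """Read spectra into validated :class:`SpectralCube` objects.

    ``dialect`` is one of ``canonical_csv`` (long), ``canonical_wide`` or
    ``supplement_xlsx``.  Rows that fail validation raise a
    :class:`SpectraValidationError` naming the sample and channel unless
    ``on_range_error="clip"``.
    """
    if dialect == "canonical_csv":
        return _read_long_csv(path, on_range_error)
    if dialect == "canonical_wide":
        return _read_wide_csv(path, on_range_error)
    if dialect == "supplement_xlsx":
        return _read_supplement_xlsx(path, on_range_error)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_long_csv(path, on_range_error: str) -> list[SpectralCube]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise SpectraValidationError(f"long CSV missing columns {sorted(missing)}")
    cubes = []
    for sample_id, sample_df in df.groupby("sample_id", sort=False):
        patient_ids = sample_df["patient_id"].astype(str).unique()
        if len(patient_ids) != 1:
            raise SpectraValidationError(
                f"sample {sample_id!r}: inconsistent patient ids {patient_ids.tolist()}"
            )
        spectra: dict[str, np.ndarray] = {}
        grid = None
        for pathway, pw_df in sample_df.groupby("pathway", sort=False):
            if pathway not in PATHWAYS:
                raise SpectraValidationError(
                    f"sample {sample_id!r}: unknown pathway label {pathway!r}"
                )
            if pw_df["channel"].duplicated().any():
                dup = pw_df.loc[pw_df["channel"].duplicated(), "channel"].iloc[0]
                raise SpectraValidationError(
                    f"sample {sample_id!r} pathway {pathway}: duplicate channel {int(dup)}"
                )
            pw_df = pw_df.sort_values("channel")
            if len(pw_df) != N_CHANNELS or not np.array_equal(
                pw_df["channel"].to_numpy(), np.arange(N_CHANNELS)
            ):
                raise SpectraValidationError(
                    f"sample {sample_id!r} pathway {pathway}: expected channels "
                    f"0..{N_CHANNELS - 1}, got {len(pw_df)} rows"
                )
            values = pw_df["intensity"].to_numpy(dtype=float)
            values = _validate_intensities(
                values, f"sample {sample_id!r} pathway {pathway}", on_range_error
            )
            spectra[pathway] = values
            grid = WavelengthGrid(pw_df["wavelength_nm"].to_numpy(dtype=float))
        cubes.append(
            SpectralCube(
                sample_id=str(sample_id),
                patient_id=str(patient_ids[0]),
                pathway_spectra=spectra,
                grid=grid or WavelengthGrid.linear(),
            )
        )
    return cubes


def _read_wide_csv(path, on_range_error: str) -> list[SpectralCube]:
    df = pd.read_csv(path, float_precision="round_trip")
    ch_cols = [f"ch{c:03d}" for c in range(N_CHANNELS)]
    missing = {"sample_id", "patient_id", "pathway", *ch_cols} - set(df.columns)
    if missing:
        raise SpectraValidationError(f"wide CSV missing columns {sorted(missing)[:4]}...")
    cubes = []
    for sample_id, sample_df in df.groupby("sample_id", sort=False):
        spectra = {}
        patient_id = str(sample_df["patient_id"].iloc[0])
        for _, row in sample_df.iterrows():
            pathway = row["pathway"]
            if pathway not in PATHWAYS:
                raise SpectraValidationError(
                    f"sample {sample_id!r}: unknown pathway label {pathway!r}"
                )
            if pathway in spectra:
                raise SpectraValidationError(
                    f"sample {sample_id!r}: duplicate pathway {pathway}"
                )
            values = row[ch_cols].to_numpy(dtype=float)
            spectra[pathway] = _validate_intensities(
                values, f"sample {sample_id!r} pathway {pathway}", on_range_error
            )
        cubes.append(SpectralCube(str(sample_id), patient_id, spectra))
    return cubes


def _read_supplement_xlsx(path, on_range_error: str) -> list[SpectralCube]:
    df = pd.read_excel(path)
    cubes = []
    for _, row in df.iterrows():
        sample_id = str(row.get("sample_id", row.name))
        spectra = {}
        for pw, col in _S3_SPECTRA_COLS.items():
            cell = row.get(col)
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell) == "":
                continue
            values = np.array([parse_decimal(v) for v in str(cell).split(";")], dtype=float)
            if values.shape != (N_CHANNELS,):
                raise SpectraValidationError(
                    f"sample {sample_id!r} pathway {pw}: serialized spectrum has "
                    f"{values.size} values, expected {N_CHANNELS}"
                )
            spectra[pw] = _validate_intensities(
                values, f"sample {sample_id!r} pathway {pw}", on_range_error
            )
        cubes.append(SpectralCube(sample_id, str(row["patient_id"]), spectra))
    return cubes


def read_lab_table(path, dialect: str = "canonical_csv") -> list[LabPanel]:
    """Read laboratory panels.  Empty cells become missing values, never zeros."""
    if dialect == "canonical_csv":
        df = pd.read_csv(path, float_precision="round_trip")
    elif dialect == "supplement_xlsx":
        df = pd.read_excel(path)
        for col in df.columns:
            if col in ANALYTES:
                df[col] = df[col].map(parse_decimal)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    unknown = [
        c
        for c in df.columns
        if c not in ANALYTES and c not in ("sample_id", "patient_id")
        and not c.startswith("spectrum_")
    ]
    if unknown:
        warnings.warn(f"ignoring unknown analyte column(s) {unknown}", stacklevel=2)
    panels = []
    for _, row in df.iterrows():
        sample_id = str(row.get("sample_id", row.name))
        values = {}
        for analyte in ANALYTES:
            if analyte not in df.columns:
                continue
            value = row[analyte]
            if isinstance(value, str):
                value = parse_decimal(value)
            if value is None or (isinstance(value, float) and np.isnan(value)):
                continue
            if value < 0:
                raise SpectraValidationError(
                    f"sample {sample_id!r}: negative lab value {analyte}={value}"
                )
            values[analyte] = float(value)
        panels.append(LabPanel(sample_id=sample_id, values=values))
    return panels
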