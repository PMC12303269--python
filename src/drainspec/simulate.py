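"""Synthetic drain-fluid cohort generator.

Emulates the statistical structure the downstream analyses rely on, without
claiming radiometric realism:

* patients contribute a variable number of repeated samples;
* analyte concentrations are right-skewed (log-normal) with a point mass at
  zero for the bleeding markers (hemoglobin, erythrocytes, cell counts);
* each analyte attenuates light at characteristic wavelengths following a
  Beer-Lambert law with Gaussian absorptivity profiles, so transmitted
  intensity falls with concentration (negative intensity-concentration
  correlations at the absorption peaks);
* a per-patient log-intensity intercept and a per-sample multiplicative
  scatter distort every spectrum (SNV removes these);
* per-patient shifts also enter the analyte concentrations and the
  zero-inflation propensity, so models with random intercepts have a real
  advantage to detect;
* additive detector noise and a hard saturation ceiling at 65000 counts.

The generator is bit-reproducible for a fixed seed and returns a truth
record holding every latent quantity for recovery tests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit, roots_hermitenorm

from .spectra import (
    ANALYTES,
    INTENSITY_CEILING,
    LabPanel,
    SpectralCube,
    WavelengthGrid,
    WAVELENGTH_MAX,
    WAVELENGTH_MIN,
)


@dataclass(frozen=True)
class AbsorptionPeak:
    """Gaussian absorptivity profile: absorbance contribution per unit concentration."""

    center_nm: float
    width_nm: float
    strength: float  # absorbance units per concentration unit at the peak center


@dataclass
class AnalyteModel:
    """Concentration distribution + optical signature of one analyte."""

    log_mean: float
    log_sd: float
    unit: str = "mg/dl"
    zero_mass: float = 0.0  # marginal probability of an exact zero
    patient_sd: float = 0.4  # SD of per-patient shift on the log scale
    zero_patient_sd: float = 1.0  # SD of per-patient shift on the zero-propensity logit
    peaks: tuple[AbsorptionPeak, ...] = ()


@dataclass
class SyntheticConfig:
    """Study-scale defaults: ~180 patients, 1-6 samples each (~520 samples)."""

    n_patients: int = 180
    samples_per_patient_min: int = 1
    samples_per_patient_max: int = 5
    seed: int = 0
    patient_effect_sd: float = 0.25  # per-patient log-intensity intercept SD
    sample_scatter_sd: float = 0.45  # per-sample log multiplicative scatter SD
    baseline_offset: float = 300.0  # additive counts
    noise_sd: float = 40.0  # additive Gaussian detector noise, counts
    lamp_amplitude: float = 30000.0
    lamp_center_nm: float = 620.0
    lamp_width_nm: float = 160.0
    lamp_floor: float = 1500.0
    #: per-pathway detector gain (path length / exposure compound factor)
    pathway_gain: dict = field(default_factory=lambda: {"DT": 1.0, "AT": 0.85, "AR": 0.55})
    #: per-pathway optical path-length multiplier on absorbance
    pathway_pathlength: dict = field(default_factory=lambda: {"DT": 1.0, "AT": 0.8, "AR": 0.5})
    ceiling: float = INTENSITY_CEILING
    analytes: dict = field(default_factory=lambda: default_analyte_models())

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if self.samples_per_patient_min < 1 or (
            self.samples_per_patient_max < self.samples_per_patient_min
        ):
            raise ValueError("invalid samples-per-patient range")
        for name in ("patient_effect_sd", "sample_scatter_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for analyte, model in self.analytes.items():
            for peak in model.peaks:
                if not WAVELENGTH_MIN <= peak.center_nm <= WAVELENGTH_MAX:
                    raise ValueError(
                        f"{analyte}: peak at {peak.center_nm} nm outside "
                        f"[{WAVELENGTH_MIN}, {WAVELENGTH_MAX}]"
                    )

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        import json

        raw = asdict(self)
        raw["analytes"] = {
            name: {**asdict(m), "peaks": [list(asdict(p).values()) for p in m.peaks]}
            for name, m in self.analytes.items()
        }
        # normalize numpy scalars/tuples to plain JSON types for clean YAML
        raw = json.loads(json.dumps(raw, default=float))
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text())
        analytes = {}
        for name, m in raw.pop("analytes", {}).items():
            peaks = tuple(AbsorptionPeak(*p) for p in m.pop("peaks", []))
            analytes[name] = AnalyteModel(**m, peaks=peaks)
        return cls(**raw, analytes=analytes or default_analyte_models())


def default_analyte_models() -> dict[str, AnalyteModel]:
    """Default concentration/optics models for the 14-analyte panel.

    Log-normal locations and scales are chosen so the fraction exceeding the
    clinical cut-off is realistic for post-operative drain fluid (rare for
    triglycerides and uric acid, majority for LDH and the bleeding markers).
    Absorption peaks sit at the visible-range maxima known for the pigmented
    analytes (hemoglobin around 363/514/557/586 nm, bilirubin around
    496 nm); glucose and the cell counts carry no visible-range signature,
    so their screening should come up empty.
    """
    ln = np.log
    return {
        "hemoglobin": AnalyteModel(
            log_mean=ln(1.0), log_sd=0.9, unit="mg/dl", zero_mass=1 / 3,
            peaks=(
                AbsorptionPeak(586.0, 10.0, 0.30),
                AbsorptionPeak(514.0, 12.0, 0.22),
                AbsorptionPeak(557.0, 10.0, 0.15),
                AbsorptionPeak(363.0, 14.0, 0.10),
            ),
        ),
        "erythrocytes": AnalyteModel(
            log_mean=ln(0.3), log_sd=0.8, unit="counts/nl", zero_mass=0.138,
            peaks=(
                AbsorptionPeak(586.0, 10.0, 0.55),
                AbsorptionPeak(518.0, 12.0, 0.40),
                AbsorptionPeak(551.0, 10.0, 0.35),
            ),
        ),
        "bilirubin": AnalyteModel(
            log_mean=ln(0.8), log_sd=1.1, unit="mg/dl",
            peaks=(AbsorptionPeak(496.0, 25.0, 0.060),),
        ),
        "albumin": AnalyteModel(
            log_mean=ln(1.2), log_sd=0.6, unit="mg/dl",
            peaks=(AbsorptionPeak(580.0, 15.0, 0.12),),
        ),
        "total_protein": AnalyteModel(
            log_mean=ln(2.2), log_sd=0.5, unit="g/dl",
            peaks=(AbsorptionPeak(537.0, 15.0, 0.08),),
        ),
        "uric_acid": AnalyteModel(
            log_mean=ln(3.0), log_sd=0.63, unit="mg/dl",
            peaks=(AbsorptionPeak(354.0, 12.0, 0.04),),
        ),
        "ldh": AnalyteModel(
            log_mean=5.89, log_sd=1.0, unit="U/l",
            peaks=(AbsorptionPeak(659.0, 20.0, 0.0005),),
        ),
        "triglycerides": AnalyteModel(
            log_mean=3.70, log_sd=0.9, unit="mg/dl",
            peaks=(
                AbsorptionPeak(588.0, 15.0, 0.0015),
                AbsorptionPeak(667.0, 20.0, 0.0012),
            ),
        ),
        "lipase": AnalyteModel(log_mean=3.29, log_sd=1.2, unit="U/l"),
        "pancreatic_amylase": AnalyteModel(log_mean=2.93, log_sd=1.2, unit="U/l"),
        "glucose": AnalyteModel(log_mean=3.75, log_sd=0.8, unit="mg/dl"),
        "leukocytes": AnalyteModel(
            log_mean=ln(0.5), log_sd=1.0, unit="counts/nl", zero_mass=0.01
        ),
        "mononuclear_cells": AnalyteModel(
            log_mean=ln(0.4), log_sd=1.0, unit="counts/nl", zero_mass=0.083
        ),
        "polymorphonuclear_cells": AnalyteModel(
            log_mean=ln(0.6), log_sd=1.0, unit="counts/nl", zero_mass=0.02
        ),
    }


def _gauss(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def _calibrate_zero_logit(target: float, tau: float, nodes: int = 40) -> float:
    """Intercept alpha such that E_b[expit(alpha + b)] == target for b ~ N(0, tau^2).

    Solved by Gauss-Hermite quadrature + root finding so the *marginal*
    zero fraction matches the configured point mass despite the per-patient
    random effect on the propensity.
    """
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    if tau == 0.0:
        return float(logit(target))
    z, w = roots_hermitenorm(nodes)
    w = w / w.sum()

    def marginal(alpha: float) -> float:
        return float(np.sum(w * expit(alpha + tau * z))) - target

    return float(brentq(marginal, -40.0, 40.0))


def simulate_cohort(
    config: SyntheticConfig,
) -> tuple[list[SpectralCube], list[LabPanel], dict]:
    """Draw a full synthetic cohort.

    Returns spectra cubes, laboratory panels and a truth record with every
    latent quantity (concentrations, patient intercepts, per-sample scatter)
    for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    grid = WavelengthGrid.linear()
    wl = grid.wavelengths
    lamp = config.lamp_amplitude * _gauss(wl, config.lamp_center_nm, config.lamp_width_nm)
    lamp = lamp + config.lamp_floor

    n_samples_per_patient = rng.integers(
        config.samples_per_patient_min,
        config.samples_per_patient_max + 1,
        size=config.n_patients,
    )
    patient_ids = [f"P{i:04d}" for i in range(config.n_patients)]
    patient_intercept = rng.normal(0.0, config.patient_effect_sd, size=config.n_patients)

    analyte_names = [a for a in ANALYTES if a in config.analytes]
    # per-patient latent shifts per analyte: concentration location + zero propensity
    conc_shift = {
        a: rng.normal(0.0, config.analytes[a].patient_sd, size=config.n_patients)
        for a in analyte_names
    }
    zero_shift = {
        a: rng.normal(0.0, config.analytes[a].zero_patient_sd, size=config.n_patients)
        for a in analyte_names
    }
    zero_alpha = {
        a: _calibrate_zero_logit(
            config.analytes[a].zero_mass, config.analytes[a].zero_patient_sd
        )
        for a in analyte_names
    }

    # precompute per-analyte absorptivity profiles on the grid
    profiles = {
        a: sum(
            (peak.strength * _gauss(wl, peak.center_nm, peak.width_nm) for peak in
             config.analytes[a].peaks),
            start=np.zeros_like(wl),
        )
        for a in analyte_names
    }

    cubes: list[SpectralCube] = []
    panels: list[LabPanel] = []
    conc_rows: dict[str, dict[str, float]] = {}
    scatter: dict[str, float] = {}
    sample_patient: dict[str, str] = {}

    for p_idx, pid in enumerate(patient_ids):
        for j in range(n_samples_per_patient[p_idx]):
            sid = f"{pid}S{j}"
            sample_patient[sid] = pid
            # concentrations
            conc: dict[str, float] = {}
            for a in analyte_names:
                model = config.analytes[a]
                p_zero = expit(zero_alpha[a] + zero_shift[a][p_idx]) if model.zero_mass > 0 else 0.0
                is_zero = rng.random() < p_zero
                draw = float(
                    np.exp(model.log_mean + conc_shift[a][p_idx] + rng.normal(0.0, model.log_sd))
                )
                conc[a] = 0.0 if is_zero else draw
            conc_rows[sid] = conc
            panels.append(LabPanel(sample_id=sid, values=dict(conc)))

            # optics
            v_s = rng.normal(0.0, config.sample_scatter_sd)
            scatter[sid] = v_s
            g = np.exp(patient_intercept[p_idx] + v_s)
            absorbance_unit = sum(
                (profiles[a] * conc[a] for a in analyte_names), start=np.zeros_like(wl)
            )
            spectra: dict[str, np.ndarray] = {}
            for pw in ("DT", "AT", "AR"):
                transmitted = (
                    config.pathway_gain[pw]
                    * g
                    * lamp
                    * 10.0 ** (-config.pathway_pathlength[pw] * absorbance_unit)
                )
                noisy = transmitted + config.baseline_offset + rng.normal(
                    0.0, config.noise_sd, size=wl.size
                )
                spectra[pw] = np.clip(noisy, 0.0, config.ceiling)
            cubes.append(SpectralCube(sid, pid, spectra, grid=grid))

    truth = {
        "concentrations": pd.DataFrame.from_dict(conc_rows, orient="index"),
        "patient_intercept": pd.Series(patient_intercept, index=patient_ids),
        "sample_scatter": pd.Series(scatter),
        "sample_patient": pd.Series(sample_patient),
        "config": config,
    }
    return cubes, panels, truth


#: Table-4-style default wavelength columns for the single-analyte workbook
S4_DEFAULT_COLUMNS = (("DT", 342.41), ("AT", 363.92), ("AR", 557.5), ("DT", 586.83))


def emit_supplement_layout(
    cubes: list[SpectralCube],
    panels: list[LabPanel],
    outdir,
    s4_analyte: str = "hemoglobin",
    s4_cutoff: float = 0.0,
    s4_columns=S4_DEFAULT_COLUMNS,
) -> dict[str, Path]:
    """Write a simulated cohort in every supported dialect.

    Produces the canonical long/wide CSVs and lab CSV, a workbook in the
    deposited-data layout, and a single-analyte workbook (binary label,
    laboratory value, patient id, then one SNV-intensity column per selected
    wavelength) mirroring the worked hemoglobin example layout.
    """
    from . import io as dio
    from .snv import snv_normalize

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "spectra_long": outdir / "spectra_long.csv",
        "spectra_wide": outdir / "spectra_wide.csv",
        "lab": outdir / "lab.csv",
        "supplement": outdir / "supplement_s3.xlsx",
        "single_analyte": outdir / f"supplement_s4_{s4_analyte}.xlsx",
    }
    dio.write_spectra_long(cubes, paths["spectra_long"])
    dio.write_spectra_wide(cubes, paths["spectra_wide"])
    dio.write_lab_table(panels, paths["lab"])
    dio.write_supplement_workbook(cubes, panels, paths["supplement"])

    by_sample = {p.sample_id: p for p in panels}
    grid = cubes[0].grid if cubes else WavelengthGrid.linear()
    rows = []
    for cube in cubes:
        panel = by_sample.get(cube.sample_id)
        if panel is None or panel.is_missing(s4_analyte):
            continue
        value = panel.values[s4_analyte]
        row = {
            "binary": int(value > s4_cutoff),
            "lab_value": value,
            "patient_id": cube.patient_id,
        }
        ok = True
        for pw, nm in s4_columns:
            if pw not in cube.pathway_spectra:
                ok = False
                break
            scaled = snv_normalize(cube.pathway_spectra[pw]).values
            row[f"{pw}_{nm}nm"] = scaled[grid.nearest_channel(nm)]
        if ok:
            rows.append(row)
    cols = ["binary", "lab_value", "patient_id"] + [f"{pw}_{nm}nm" for pw, nm in s4_columns]
    pd.DataFrame(rows, columns=cols).to_excel(paths["single_analyte"], index=False)
    return paths
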