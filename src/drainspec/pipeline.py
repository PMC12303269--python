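"""End-to-end orchestration: simulate/ingest -> SNV -> screen -> model -> validate.

The pipeline mirrors the study workflow: spectra are SNV-scaled per sample
and pathway; per-analyte correlation curves select candidate wavelengths
(|r| > 0.3, p < 0.01); the selected SNV intensities feed (a) a
fractional-polynomial Tobit regression of the concentration, with backward
selection and an optional per-patient random intercept, and (b) a logistic
classification of the pathological/non-pathological coding -- both assessed
with the five-fold optimism correction.

All randomness flows from a single base seed: each stage derives its own
stream via ``numpy.random.SeedSequence([base_seed, stage_index])`` with a
fixed stage numbering (0 simulate, 1 folds-regression, 2 folds-
classification), so reruns are byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import balanced_accuracy, binarize, fit_logistic, roc_auc
from .mfp import mfp_search
from .screening import SelectedFeature, build_curves, select_features
from .simulate import SyntheticConfig, simulate_cohort
from .snv import snv_matrix
from .spectra import (
    ANALYTES,
    CutoffTable,
    LabPanel,
    PATHWAYS,
    SpectralCube,
    WavelengthGrid,
    cubes_to_matrix,
    panels_to_frame,
)
from .tobit import backward_select, fit_tobit, mean_squared_error, regression_metrics
from .validation import FoldReport, corrected_metric, make_folds

_STAGE_SEED = {"simulate": 0, "folds_regression": 1, "folds_classification": 2}


def derive_seed(base_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(base_seed), _STAGE_SEED[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    seed: int = 0
    folds: int = 5
    group_folds_by_patient: bool = False  # the study randomized samples, not patients
    r_threshold: float = 0.3
    p_threshold: float = 0.01
    max_features_per_pathway: int = 2
    max_features_total: int = 5
    random_effects: bool = True
    censor_bound: float = 0.0
    use_fractional_polynomials: bool = True
    screen_analytes: tuple = ANALYTES
    regression_analytes: tuple = ("hemoglobin", "bilirubin")
    classification_analytes: tuple = ("hemoglobin", "triglycerides")
    synthetic: SyntheticConfig | None = None

    def resolved_synthetic(self) -> SyntheticConfig:
        if self.synthetic is not None:
            return self.synthetic
        return SyntheticConfig(seed=derive_seed(self.seed, "simulate"))


@dataclass
class SNVDataset:
    """SNV-scaled spectra per pathway, aligned with the laboratory frame."""

    matrices: dict[str, np.ndarray]  # pathway -> (n_pw, 288)
    sample_ids: dict[str, list[str]]
    patient_ids: dict[str, list[str]]
    lab: pd.DataFrame  # rows = sample ids, columns = analytes (NaN = missing)
    sample_patient: dict[str, str]
    grid: WavelengthGrid = field(default_factory=WavelengthGrid.linear)


def prepare_snv(cubes: list[SpectralCube], panels: list[LabPanel]) -> SNVDataset:
    matrices, sample_ids, patient_ids = {}, {}, {}
    for pw in PATHWAYS:
        m, sids, pids = cubes_to_matrix(cubes, pw)
        if m.shape[0]:
            matrices[pw] = snv_matrix(m)
            sample_ids[pw] = sids
            patient_ids[pw] = pids
    lab = panels_to_frame(panels)
    sample_patient = {c.sample_id: c.patient_id for c in cubes}
    grid = cubes[0].grid if cubes else WavelengthGrid.linear()
    return SNVDataset(matrices, sample_ids, patient_ids, lab, sample_patient, grid)


def screen_analyte(data: SNVDataset, analyte: str, config: RunConfig):
    """Correlation curves + gated features for one analyte; empty when the
    analyte has no visible-range signature (e.g. glucose)."""
    lab = data.lab[analyte]
    try:
        curves = build_curves(
            data.matrices, lab, analyte,
            sample_ids_by_pathway=data.sample_ids, grid=data.grid,
        )
    except ValueError:
        return {}, []
    features = select_features(
        curves,
        r_threshold=config.r_threshold,
        p_threshold=config.p_threshold,
        max_per_pathway=config.max_features_per_pathway,
    )
    return curves, features[: config.max_features_total]


def feature_design(
    data: SNVDataset, features: list[SelectedFeature], analyte: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
    """Design matrix of SNV intensities at the selected wavelengths.

    Rows are the samples measured in every required pathway with a
    non-missing lab value; returns (X, y, groups, feature_names, sample_ids).
    """
    if not features:
        raise ValueError(f"{analyte}: no features selected")
    needed_pathways = sorted({f.pathway for f in features})
    common = None
    for pw in needed_pathways:
        ids = set(data.sample_ids[pw])
        common = ids if common is None else common & ids
    lab = data.lab[analyte].dropna()
    common &= set(lab.index)
    ordered = [sid for sid in data.lab.index if sid in common]
    if len(ordered) < 10:
        raise ValueError(f"{analyte}: only {len(ordered)} usable samples")
    row_of = {pw: {sid: i for i, sid in enumerate(data.sample_ids[pw])} for pw in needed_pathways}
    cols = []
    names = []
    for f in features:
        rows = [row_of[f.pathway][sid] for sid in ordered]
        cols.append(data.matrices[f.pathway][rows, f.channel])
        names.append(f.name)
    X = np.column_stack(cols)
    y = lab.loc[ordered].to_numpy(dtype=float)
    groups = np.array([data.sample_patient[sid] for sid in ordered])
    return X, y, groups, names, ordered


def regress_analyte(
    data: SNVDataset, features: list[SelectedFeature], analyte: str, config: RunConfig
):
    """Cross-validated fractional-polynomial Tobit regression for one analyte.

    Within each training set: FP transform search (fixed-effects working
    fitter), backward selection, then the final fit with the configured
    random-intercept setting.  Returns (FoldReport, RegressionMetrics,
    final global TobitFit).
    """
    X, y, groups, names, _ = feature_design(data, features, analyte)
    folds = make_folds(
        np.arange(y.size),
        config.folds,
        seed=derive_seed(config.seed, "folds_regression"),
        groups=groups if config.group_folds_by_patient else None,
    )
    final_fit_holder = {}

    def fit_predict(train_idx):
        Xt, yt, gt = X[train_idx], y[train_idx], groups[train_idx]
        if config.use_fractional_polynomials:
            transform = mfp_search(Xt, yt, feature_names=names)
            Xt_fp, fp_names = transform.apply(Xt, names)
        else:
            transform, Xt_fp, fp_names = None, Xt, list(names)
        fit, _removed = backward_select(
            Xt_fp, yt, fp_names,
            fit_kwargs={"censor_bound": config.censor_bound, "compute_se": True},
        )
        kept = fit.feature_names
        if config.random_effects and kept:
            keep_idx = [fp_names.index(k) for k in kept]
            fit = fit_tobit(
                Xt_fp[:, keep_idx], yt,
                censor_bound=config.censor_bound,
                random_intercept=True, groups=gt,
                feature_names=kept, compute_se=False,
            )
        final_fit_holder["fit"] = fit
        keep_idx = [fp_names.index(k) for k in fit.feature_names]

        def predict(idx):
            Xe = X[idx]
            Xe_fp = transform.apply(Xe, names)[0] if transform is not None else Xe
            return fit.predict(Xe_fp[:, keep_idx] if keep_idx else np.empty((len(idx), 0)))

        return predict

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = corrected_metric(fit_predict, mean_squared_error, y, folds)
    metrics = regression_metrics(
        report.global_metric, report.fold_diffs, float(np.var(y, ddof=1))
    )
    return report, metrics, final_fit_holder.get("fit")


def classify_analyte(
    data: SNVDataset,
    features: list[SelectedFeature],
    analyte: str,
    config: RunConfig,
    cutoffs: CutoffTable | None = None,
):
    """Cross-validated logistic classification of the pathological coding.

    One model refit per fold scores both metrics, so the AUC and BAC fold
    reports share identical fold fits.  Returns a dict with FoldReports
    keyed 'auc'/'bac' plus the final global LogisticFit.
    """
    cutoffs = cutoffs or CutoffTable()
    X_all, y_conc, groups, names, ordered = feature_design(data, features, analyte)
    label_set = binarize(
        [LabPanel(sid, {analyte: v}) for sid, v in zip(ordered, y_conc)],
        cutoffs,
        analyte,
    )
    y = label_set.vector(ordered)
    if np.unique(y).size < 2:
        raise ValueError(f"{analyte}: only one class present after binarization")
    folds = make_folds(
        np.arange(y.size),
        config.folds,
        seed=derive_seed(config.seed, "folds_classification"),
        groups=groups if config.group_folds_by_patient else None,
    )

    def fit_on(idx):
        return fit_logistic(
            X_all[idx], y[idx],
            random_intercept=config.random_effects,
            groups=groups[idx] if config.random_effects else None,
            feature_names=names,
        )

    inner = {"auc": [], "bac": []}
    outer = {"auc": [], "bac": []}
    failures = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for f in np.unique(folds):
            train = np.nonzero(folds != f)[0]
            test = np.nonzero(folds == f)[0]
            try:
                fit = fit_on(train)
                fold_vals = []
                for idx in (train, test):
                    prob = fit.predict_proba(X_all[idx])
                    fold_vals.append(
                        (roc_auc(prob, y[idx])[0], balanced_accuracy(prob, y[idx]))
                    )
            except ValueError as exc:  # e.g. one-class fold
                failures.append((int(f), repr(exc)))
                fold_vals = [(np.nan, np.nan), (np.nan, np.nan)]
            for (auc_val, bac_val), dest in zip(fold_vals, (inner, outer)):
                dest["auc"].append(auc_val)
                dest["bac"].append(bac_val)
        global_fit = fit_on(np.arange(y.size))
        prob_all = global_fit.predict_proba(X_all)
    k = int(np.unique(folds).size)
    auc_global, roc_points = roc_auc(prob_all, y)
    reports = {
        "auc": FoldReport(k, inner["auc"], outer["auc"], auc_global, failures=list(failures)),
        "bac": FoldReport(
            k, inner["bac"], outer["bac"], balanced_accuracy(prob_all, y),
            failures=list(failures),
        ),
    }
    return reports, global_fit, roc_points, y


def run_pipeline(config: RunConfig, outdir, cubes=None, panels=None) -> dict:
    """Run the full workflow and write per-analyte artifacts under ``outdir``.

    With no input data, a synthetic cohort is simulated from the derived
    seed.  Returns the manifest (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "errors": {},
    }
    if cubes is None or panels is None:
        syn = config.resolved_synthetic()
        cubes, panels, _truth = simulate_cohort(syn)
        manifest["stages"]["simulate"] = {
            "n_patients": syn.n_patients,
            "n_samples": len(cubes),
            "seed": syn.seed,
        }
    data = prepare_snv(cubes, panels)

    curve_rows, feature_rows = [], []
    features_by_analyte: dict[str, list[SelectedFeature]] = {}
    for analyte in config.screen_analytes:
        curves, features = screen_analyte(data, analyte, config)
        features_by_analyte[analyte] = features
        selected = {(f.pathway, f.channel) for f in features}
        for pw, curve in curves.items():
            for ch in range(curve.r.size):
                curve_rows.append(
                    (analyte, pw, ch, curve.grid[ch], curve.r[ch], curve.p[ch],
                     (pw, ch) in selected)
                )
        for f in features:
            feature_rows.append(
                (analyte, f.pathway, f.channel, f.wavelength_nm, f.r, f.p)
            )
    pd.DataFrame(
        curve_rows,
        columns=["analyte", "pathway", "channel", "wavelength_nm", "r", "p", "selected"],
    ).to_csv(outdir / "correlation_curves.csv", index=False)
    pd.DataFrame(
        feature_rows, columns=["analyte", "pathway", "channel", "wavelength_nm", "r", "p"]
    ).to_csv(outdir / "selected_features.csv", index=False)
    manifest["stages"]["screen"] = {
        a: len(f) for a, f in features_by_analyte.items()
    }

    regression_rows = []
    for analyte in config.regression_analytes:
        try:
            report, metrics, _fit = regress_analyte(
                data, features_by_analyte[analyte], analyte, config
            )
        except ValueError as exc:
            manifest["errors"][f"regression:{analyte}"] = str(exc)
            continue
        row = {
            "analyte": analyte,
            **{f"fold_diff_{i + 1}": d for i, d in enumerate(report.fold_diffs)},
            "mse_global": metrics.mse_global,
            "mse_global_corrected": metrics.mse_global_corrected,
            "variance": metrics.variance,
            "r2": metrics.r2,
        }
        regression_rows.append(row)
    if regression_rows:
        pd.DataFrame(regression_rows).to_csv(outdir / "regression_report.csv", index=False)

    classification_rows = []
    for analyte in config.classification_analytes:
        try:
            reports, _fit, roc_points, _y = classify_analyte(
                data, features_by_analyte[analyte], analyte, config
            )
        except ValueError as exc:
            manifest["errors"][f"classification:{analyte}"] = str(exc)
            continue
        classification_rows.append(
            {
                "analyte": analyte,
                "auc_global": reports["auc"].global_metric,
                "auc_corrected": reports["auc"].corrected,
                "bac_global": reports["bac"].global_metric,
                "bac_corrected": reports["bac"].corrected,
                "random_effects": config.random_effects,
            }
        )
        np.savetxt(
            outdir / f"roc_{analyte}.csv",
            roc_points,
            delimiter=",",
            header="fpr,tpr",
            comments="",
        )
    if classification_rows:
        pd.DataFrame(classification_rows).to_csv(
            outdir / "classification_report.csv", index=False
        )

    manifest["stages"]["regression"] = [r["analyte"] for r in regression_rows]
    manifest["stages"]["classification"] = [r["analyte"] for r in classification_rows]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
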