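"""Published reference values from the originating drain-fluid study.

These printed summary tables are *inputs* to the reproduction harness: the
fold-difference tables feed the correction arithmetic, the headline
correlations and SNV standard deviations are the comparison targets when a
user supplies the study's deposited data workbook, and the pathological
percentages anchor the cut-off binarization.

The reported erythrocytes R^2 (0.625) is known not to satisfy the study's
own formula R^2 = 1 - corrected MSE / variance (which gives 0.651); the
harness reports both numbers rather than hiding the discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class RegressionRow:
    """One analyte's published cross-validated Tobit summary."""

    fold_diffs: tuple[float, ...]  # out-of-sample minus inner-sample MSE, 5 folds
    mse_global: float
    mse_global_corrected: float  # as printed
    variance: float
    r2: float  # as printed


#: published per-analyte regression summaries (random-effects Tobit models)
REGRESSION_TABLE: dict[str, RegressionRow] = {
    "erythrocytes": RegressionRow((0.021, 0.044, -0.014, -0.029, 0.009), 0.082, 0.088, 0.252, 0.625),
    "hemoglobin": RegressionRow((2.184, -0.698, 0.691, -0.657, -1.101), 1.103, 1.187, 3.291, 0.639),
    "bilirubin": RegressionRow((35.58, -8.907, -14.132, -20.432, 11.140), 33.091, 33.741, 71.524, 0.529),
    "albumin": RegressionRow((0.615, -0.371, -0.069, 0.316, -0.25), 1.234, 1.282, 2.352, 0.454),
    "total_protein": RegressionRow((0.957, -0.133, -0.074, -0.608, 0.635), 3.589, 3.744, 4.996, 0.251),
    "uric_acid": RegressionRow((-4.399, -3.061, -7.006, 7.211, 11.67), 14.209, 15.091, 21.879, 0.31),
}

#: hemoglobin classification with random intercept: global inner-sample AUC,
#: published mean differential (inner minus out-of-sample), corrected AUC
HEMOGLOBIN_AUC_GLOBAL = 0.977
HEMOGLOBIN_AUC_MEAN_DIFFERENTIAL = 0.03
HEMOGLOBIN_AUC_CORRECTED = 0.947

#: final corrected classification metrics per analyte: (AUC+RE, BAC+RE, AUC-RE, BAC-RE)
CLASSIFICATION_TABLE: dict[str, tuple[float, float, float, float]] = {
    "hemoglobin": (0.947, 0.853, 0.945, 0.889),
    "triglycerides": (0.941, 0.789, 0.827, 0.778),
    "ldh": (0.94, 0.806, 0.893, 0.757),
    "bilirubin": (0.918, 0.807, 0.723, 0.722),
    "erythrocytes": (0.905, 0.792, 0.897, 0.740),
    "total_protein": (0.884, 0.914, 0.797, 0.725),
    "albumin": (0.882, 0.741, 0.877, 0.757),
    "uric_acid": (0.856, 0.831, 0.746, 0.613),
    "pancreatic_amylase": (0.845, 0.762, 0.702, 0.526),
    "lipase": (0.826, 0.75, 0.666, 0.582),
}

#: headline screening correlations: analyte -> ((wavelength nm, r), ...)
CORRELATION_MAXIMA: dict[str, tuple[tuple[float, float], ...]] = {
    "hemoglobin": ((586.0, -0.67), (514.0, -0.62), (557.0, -0.45), (363.0, -0.37)),
    "erythrocytes": ((586.0, -0.46), (518.0, -0.425), (551.0, -0.411), (665.0, 0.446)),
    "bilirubin": ((582.0, 0.56), (496.0, -0.49)),
}

#: mean per-wavelength SD of the AT_200 setting's spectra, before / after SNV
SNV_SD_BEFORE = 2517.71
SNV_SD_AFTER = 0.19

#: published pathological percentages per analyte at the default cut-offs
PATHOLOGICAL_PERCENT: dict[str, float] = {
    "triglycerides": 3.8,
    "uric_acid": 8.3,
    "albumin": 16.0,
    "pancreatic_amylase": 19.4,
    "bilirubin": 19.4,
    "lipase": 28.6,
    "glucose": 41.9,
    "total_protein": 50.3,
    "ldh": 64.9,
    "hemoglobin": 66.7,
    "erythrocytes": 86.2,
    "mononuclear_cells": 91.7,
    "polymorphonuclear_cells": 98.0,
    "leukocytes": 99.0,
}
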