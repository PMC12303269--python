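# Methods

## Data model

A sample is a `SpectralCube`: up to three pathways (DT/AT/AR, exposure
20/200/320 µs) × 288 intensity channels in [0, 65000] counts on a
wavelength grid spanning 340–850 nm. The default grid is linear (channel 0
at 340 nm, channel 287 at 850 nm, spacing ≈ 1.777 nm). Real devices have a
calibration polynomial the linear grid only approximates — reported
wavelengths such as 586.83 nm are therefore always resolved to the nearest
grid channel, and an explicit 288-value calibration list overrides the
linear default when known. Laboratory panels hold the 14-analyte
vocabulary; a missing measurement is an absent key, never zero. Cut-offs
default to the clinical table (0 for hemoglobin, erythrocytes and the cell
counts; 2.5 for albumin/total protein; 200 mg/dl triglycerides; …) with
"value strictly above cut-off = pathological". The direction is
per-analyte configurable because the bleeding-marker rationale (any
presence is abnormal) fixes the "above" convention, and the published
pathological percentages are only consistent with it.

Samples with a missing pathway are excluded per pathway, not deleted:
each pathway's correlation curve uses whatever samples carry that pathway.
Saturated readings (= 65000) are retained and flagged by `saturation_mask`;
masking them out of downstream statistics is a config switch, off by
default, because the measurement protocol handled overexposure by choosing
exposure times rather than dropping channels.

## SNV

`snv_normalize` maps s → (s − μ)/σ per sample, per pathway, with the
sample SD (n−1). The two SD conventions differ by < 0.2% at 288 points;
the choice is recorded so comparisons against externally computed summary
SDs allow for it. Constant spectra raise an error rather than emitting
NaNs. The diagnostic `per_wavelength_sd` quantifies the scatter collapse:
on scatter-dominated cohorts the mean per-wavelength SD drops by about
four orders of magnitude after scaling.

## Correlation screening

Pearson r per channel with the exact t-transform p-value; pairs with a
missing laboratory value are removed pairwise. No multiple-testing
correction is applied across the 288 × 3 tests — screening at raw p < 0.01
is deliberately permissive and inflates the family-wise error rate; the
guard against spurious wavelengths is the cross-validated modelling stage,
not the screen. Adjacent passing channels are collapsed to local |r|
extrema within ±3 channels (one absorption peak, one covariate); the
window is an implementation choice, as published wavelength lists never
state how neighbours were merged. Known literature wavelengths can be
force-included below the gates. At most 2 features per pathway and 5 in
total enter the models by default — enough to span the planted signatures
while keeping ≥ 10 observations per coefficient at cohort scale.

## Censored regression

Concentrations are left-censored at 0 by default (assay floor; the bound is
configurable per analyte). The Tobit log-likelihood uses the standard
density/mass split; with no censored observations it reduces exactly to
the Gaussian likelihood, which is one of the test oracles. Fitting is
L-BFGS-B with an analytic gradient; design columns are standardized
internally for conditioning and the coefficients and standard errors are
mapped back by the delta method. Wald SEs come from the central-difference
Hessian at the optimum.

The per-patient random intercept b ~ N(0, τ²) is integrated out by plain
(non-adaptive) Gauss–Hermite quadrature with 25 nodes by default. At this
study's group sizes (1–5 samples per patient) plain quadrature at that
order matches a numerically integrated marginal likelihood to < 1e-6
(tested); adaptive quadrature would only matter for much larger groups. τ
is bounded below at 0, so a zero variance is estimated on the boundary.
Prediction for unseen patients uses the population intercept (random
effect at its mean), and the expected-response formula
E[max(y*, L)] = L·Φ((L−μ)/s) + μ·Φ((μ−L)/s) + s·φ((μ−L)/s) with
s² = σ² + τ², which is what the observed laboratory value estimates.

### Fractional polynomials

Powers from {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 ≡ ln), FP2 pairs including
repeated powers (x^p, x^p ln x). Covariates are shifted to positivity
(SNV intensities are negative-valued) and scaled by a power of ten. The
closed test compares best-FP2 vs linear (LRT, 3 df) and then FP2 vs best
FP1 (2 df) at α = 0.05; covariates with ≤ 3 distinct values stay linear.
When a fitted transform is applied to new data (a held-out fold), values
below the training minimum are floored at the training-domain minimum —
negative powers would otherwise explode on extrapolated inputs.

Inside cross-validation the FP search uses the fixed-effects Tobit as the
working fitter and the random intercept is added only in the final refit
per fold; the transform choice is driven by the mean structure, which the
random intercept barely moves, and this keeps the 44-model-per-covariate
search affordable.

### Backward selection

Iteratively drops the covariate with the largest Wald p above 0.05 and
refits; the intercept is never dropped and an intercept-only model is a
legal (flagged) outcome. The criterion is a package choice — the selection
procedure is standard but its retention rule is rarely printed.

## Classification

Plain logistic regression is fitted via statsmodels; the mixed model
maximizes the Gauss–Hermite-integrated Bernoulli likelihood directly, with
the same node count as the regression. The random-intercept SD is bounded
at 5 logits: under patient-level quasi-separation (rare outcomes where
every patient is entirely pathological or entirely normal) the unbounded
MLE diverges and destroys the fixed effects, while an SD of 5 already
saturates the per-patient probabilities; a fit sitting on the bound is
flagged as suspected separation. Perfect separation in the plain model is
likewise flagged, never silently accepted.

AUC is computed by average ranks (exact Mann–Whitney with ½ credit for
ties) and is tested against an exhaustive pairwise oracle and
scikit-learn. Balanced accuracy thresholds the predicted probability at
0.5 by default; the threshold is configurable because published BAC values
rarely state theirs.

## Optimism correction

`make_folds` deals permuted samples round-robin into k = 5 folds
(deterministic per seed); the default randomizes samples, not patients,
mirroring the study design, and a grouped splitter that keeps all of a
patient's samples in one fold is available as the statistically safer
option. For each fold the entire procedure — FP search, backward
selection, final fit — is refit on the training 80%; the metric is
recorded on the training data (inner) and the left-out fold (outer), and

    corrected = global + mean(outer − inner)

with the global metric from a fit on all data. The signed mean difference
makes the same formula work for losses (MSE: corrected ends above global)
and scores (AUC/BAC: corrected ends below). R² = 1 − corrected MSE /
variance, with variance the sample variance of the response over the full
analysis set — the definition that reproduces the published R² column for
five of six analytes (the sixth is inconsistent with its own inputs and is
reported as such by the reference-arithmetic harness).

## Synthetic cohort

The generator emulates the statistical structure the analyses assume, not
device radiometry. Defaults are study scale: 180 patients, 1–5 samples
each (~520–560 samples). Per sample and pathway,

    I(λ) = clip( gain_pw · e^(u_p + v_s) · I₀(λ) · 10^(−path_pw · Σ_a ε_a(λ) c_a)
                 + baseline + noise, 0, 65000 )

with u_p ~ N(0, 0.25²) the patient intercept, v_s ~ N(0, 0.45²) the sample
scatter, I₀ a broad Gaussian lamp (amplitude 30000 counts, centre 620 nm,
width 160 nm, floor 1500), Gaussian absorptivity profiles ε_a, additive
noise SD 40 counts. Concentrations are log-normal with per-patient
location shifts (SD 0.4 log units); the bleeding markers and cell counts
are zero-inflated with a patient-level propensity (logit SD 1) whose
intercept is calibrated by quadrature so the marginal zero fraction equals
the configured point mass (hemoglobin 1/3, matching the reported
pathological fraction at cut-off 0). Absorption peaks sit at the
visible-range maxima of the pigmented analytes (hemoglobin 363/514/557/586
nm, bilirubin 496 nm, …); glucose and the cell counts carry none, so their
screening correctly returns nothing. Log-normal locations were chosen once
so that the fraction above each clinical cut-off is realistic for drain
fluid (triglycerides rare, LDH majority).

What the generator does **not** emulate: wavelength-dependent detector
response, fluorescence, turbidity scattering, inter-analyte concentration
correlations, or the device's true calibration polynomial. Passing tests
therefore demonstrate that the statistical machinery recovers planted
structure under the stated noise model — not that the models would achieve
the same accuracy on real drain fluid.

One consequence of SNV worth knowing: because each spectrum is scaled by
its own σ, concentration leaks into every channel through the spectrum's
mean and SD, and the correlation extremum can shift a few channels away
from the true absorption centre when the peak absorbance leaves the
quasi-linear regime or sits on a steep lamp slope. The planted-peak
localization tests therefore calibrate the planted signal to the
quasi-linear regime (width 6 nm, strength 0.05 absorbance per unit), where
localization is within ±2 channels.

## Problem sizes and numerical choices

Cross-validated runs use the study-scale cohort (~560 samples) with two
regression and two classification analytes by default — a full run
completes in about a minute on one core, and all tolerances used in tests
(optimizer ftol 1e-12, quadrature agreement 1e-6, oracle agreement 1e-12)
are stated next to the tests that use them. All randomness flows from one
base seed through fixed-stage `SeedSequence` derivation, so every artifact
is reproducible byte for byte.

## Known limitations

* The Tobit SEs come from a numerical Hessian; near-collinear FP bases can
  make them unstable (flagged as NaN p-values, treated as removable by
  backward selection).
* The mixed-model quadrature is non-adaptive; for cohorts with many more
  samples per patient than studied here, switch to more nodes.
* The screening stage's raw p < 0.01 gate is anti-conservative by design;
  do not interpret selected wavelengths as confirmatory findings.
* With rare outcomes (< ~5% prevalence) fold-wise classification metrics
  are noisy and single folds can lack positive samples; failures are
  recorded per fold rather than silently dropped.
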