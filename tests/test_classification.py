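"""Binarization, logistic models (with/without random intercept), AUC and BAC."""

import numpy as np
import pytest

from drainspec.classification import (
    balanced_accuracy,
    binarize,
    fit_logistic,
    roc_auc,
)
from drainspec.spectra import CutoffTable, LabPanel


def brute_force_auc(scores, labels):
    """Exhaustive pairwise Mann-Whitney oracle (ties count 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestBinarize:
    def test_hemoglobin_zero_cutoff(self):
        panels = [
            LabPanel("a", {"hemoglobin": 0.0}),
            LabPanel("b", {"hemoglobin": 0.5}),
        ]
        labels = binarize(panels, CutoffTable(), "hemoglobin")
        assert labels.labels == {"a": 0, "b": 1}

    def test_missing_values_excluded(self):
        panels = [LabPanel("a", {}), LabPanel("b", {"bilirubin": 2.0})]
        labels = binarize(panels, CutoffTable(), "bilirubin")
        assert labels.labels == {"b": 1}

    def test_empty_panel_list(self):
        assert binarize([], CutoffTable(), "glucose").labels == {}

    def test_unknown_analyte_rejected(self):
        with pytest.raises(KeyError):
            binarize([], CutoffTable(), "creatinine")

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(0)
        panels = [
            LabPanel(f"s{i}", {"triglycerides": float(v)})
            for i, v in enumerate(rng.uniform(0, 400, 50))
        ]
        forward = binarize(panels, CutoffTable(), "triglycerides")
        backward = binarize(panels[::-1], CutoffTable(), "triglycerides")
        assert forward.labels == backward.labels
        assert binarize(panels, CutoffTable(), "triglycerides").labels == forward.labels

    def test_direction_below_flips_labels(self):
        from drainspec.spectra import Cutoff

        cutoffs = CutoffTable({"glucose": Cutoff(50.0, "mg/dl", direction="below")})
        panels = [LabPanel("a", {"glucose": 10.0}), LabPanel("b", {"glucose": 90.0})]
        labels = binarize(panels, cutoffs, "glucose")
        assert labels.labels == {"a": 1, "b": 0}

    def test_synthetic_pathological_fraction_is_deterministic(self, small_cohort):
        _, panels, _ = small_cohort
        l1 = binarize(panels, CutoffTable(), "hemoglobin")
        l2 = binarize(panels, CutoffTable(), "hemoglobin")
        assert l1.labels == l2.labels


class TestRocAuc:
    def test_perfect_separation(self):
        auc, points = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0
        assert points[0].tolist() == [0.0, 0.0]
        assert points[-1].tolist() == [1.0, 1.0]

    def test_worked_example(self):
        auc, _ = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == 0.75  # 3 of 4 pairs correctly ordered

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(10, 200))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        scores = rng.normal(size=300)
        labels = rng.integers(0, 2, 300)
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        base, _ = roc_auc(scores, labels)
        for f in (np.exp, np.tanh, lambda s: 3 * s - 7):
            transformed, _ = roc_auc(f(scores), labels)
            assert transformed == pytest.approx(base, abs=1e-12)

    def test_null_scores_give_half(self):
        """Random scores on balanced labels: mean AUC 0.5 within 3 SDs."""
        rng = np.random.default_rng(4)
        reps, n = 10_000, 40
        labels = np.array([0, 1] * (n // 2))
        scores = rng.normal(size=(reps, n))
        from scipy.stats import rankdata

        ranks = rankdata(scores, axis=1)
        n1 = n // 2
        aucs = (ranks[:, labels == 1].sum(axis=1) - n1 * (n1 + 1) / 2) / (n1 * n1)
        sd = aucs.std(ddof=1) / np.sqrt(reps)
        assert abs(aucs.mean() - 0.5) < 3 * sd
        one, _ = roc_auc(scores[0], labels)
        assert one == pytest.approx(aucs[0], abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestBalancedAccuracy:
    def test_perfect_predictions(self):
        assert balanced_accuracy([0.9, 0.1], [1, 0]) == 1.0

    def test_confusion_table_example(self):
        """TP 8, FN 2, TN 9, FP 1 -> sensitivity 0.8, specificity 0.9, BAC 0.85."""
        probs = [0.9] * 8 + [0.1] * 2 + [0.1] * 9 + [0.9] * 1
        labels = [1] * 10 + [0] * 10
        assert balanced_accuracy(probs, labels) == pytest.approx(0.85)

    def test_majority_class_predictor_scores_half(self):
        probs = np.zeros(100)
        labels = np.r_[np.ones(5), np.zeros(95)]
        assert balanced_accuracy(probs, labels) == 0.5

    def test_one_class_truth_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy([0.5, 0.6], [1, 1])


class TestFitLogistic:
    def test_null_slopes_within_three_se(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(500, 2))
        y = rng.integers(0, 2, 500).astype(float)
        fit = fit_logistic(X, y)
        assert fit.converged and not fit.separation_suspected
        for slope, se in zip(fit.beta[1:], fit.se[1:]):
            assert abs(slope) < 3 * se

    def test_glm_matches_sklearn_unpenalized(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(6)
        X = rng.normal(size=(400, 2))
        eta = 0.5 + X @ np.array([1.0, -0.7])
        y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(X, y)
        sk = LogisticRegression(penalty=None, max_iter=500).fit(X, y)
        assert fit.beta[0] == pytest.approx(sk.intercept_[0], abs=1e-4)
        np.testing.assert_allclose(fit.beta[1:], sk.coef_[0], atol=1e-4)

    def test_mixed_model_at_tau_zero_matches_glm(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(400, 1))
        eta = 0.3 + 1.2 * X[:, 0]
        y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(float)
        groups = np.repeat(np.arange(80), 5)
        glm = fit_logistic(X, y)
        glmer = fit_logistic(X, y, random_intercept=True, groups=groups)
        assert glmer.tau == pytest.approx(0.0, abs=0.05)
        np.testing.assert_allclose(glmer.beta, glm.beta, atol=0.05)

    def test_recovers_random_intercept(self):
        rng = np.random.default_rng(8)
        n_groups = 150
        groups = np.repeat(np.arange(n_groups), 4)
        n = groups.size
        X = rng.normal(size=(n, 1))
        b = rng.normal(0, 1.5, n_groups)[groups]
        eta = 0.2 + 1.0 * X[:, 0] + b
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(X, y, random_intercept=True, groups=groups)
        assert fit.converged
        assert fit.tau == pytest.approx(1.5, abs=0.45)
        assert fit.beta[1] == pytest.approx(1.0, abs=0.3)

    def test_perfect_separation_flagged(self):
        X = np.r_[np.full(20, -1.0), np.full(20, 1.0)][:, None]
        y = np.r_[np.zeros(20), np.ones(20)]
        fit = fit_logistic(X, y)
        assert fit.separation_suspected

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.zeros((10, 1)), np.ones(10))

    def test_planted_signal_gives_cross_validated_auc_above_09(self, snv_data):
        """Strong planted bilirubin optics -> cross-validated AUC > 0.9.

        Bilirubin is used because its cut-off splits the cohort into two
        well-populated classes even in a compact cohort."""
        from drainspec.pipeline import RunConfig, classify_analyte, screen_analyte

        config = RunConfig(seed=2, random_effects=False)
        _, features = screen_analyte(snv_data, "bilirubin", config)
        reports, _, _, _ = classify_analyte(snv_data, features, "bilirubin", config)
        assert not reports["auc"].failures
        assert reports["auc"].corrected > 0.9
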