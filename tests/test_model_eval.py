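"""Dataset assembly, classifiers, confusion metrics, DeLong AUC and Youden."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mtphen.model_eval import (
    DiagnosticModel,
    build_modelling_dataset,
    confusion_metrics,
    fit_logistic,
    fit_random_forest,
    roc_auc_delong,
    youden_threshold,
)


def frame(similarity, labels, term_count=None, average_ic=None):
    n = len(similarity)
    return pd.DataFrame(
        {
            "mean_similarity": similarity,
            "term_count": term_count if term_count is not None else np.full(n, 4),
            "average_ic": average_ic if average_ic is not None else np.full(n, 2.0),
            "label": labels,
        }
    )


def pair_count_auc(scores, labels):
    """Exhaustive Mann-Whitney pair counting with half-credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestBuildModellingDataset:
    def _cohorts(self, n_pos, n_neg, seed=0):
        rng = np.random.default_rng(seed)
        pos = pd.DataFrame(
            {
                "mean_similarity": rng.uniform(0.4, 1.0, n_pos),
                "term_count": rng.integers(1, 14, n_pos),
                "average_ic": rng.uniform(1, 4, n_pos),
            }
        )
        neg = pd.DataFrame(
            {
                "mean_similarity": rng.uniform(0.0, 0.6, n_neg),
                "term_count": rng.integers(1, 14, n_neg),
                "average_ic": rng.uniform(1, 4, n_neg),
            }
        )
        return pos, neg

    def test_balancing_subsamples_negatives(self):
        pos, neg = self._cohorts(10, 40)
        train, test = build_modelling_dataset(pos, neg, balance=True, seed=0)
        combined = pd.concat([train, test])
        assert (combined.label == 1).sum() == 10
        assert (combined.label == 0).sum() == 10

    def test_stratified_80_20_split_counts(self):
        pos, neg = self._cohorts(10, 10)
        train, test = build_modelling_dataset(pos, neg, balance=False, seed=0)
        assert len(train) == 16 and len(test) == 4
        assert (train.label == 1).sum() == 8 and (train.label == 0).sum() == 8
        assert (test.label == 1).sum() == 2 and (test.label == 0).sum() == 2

    def test_seeded_subsampling_reproducible(self):
        pos, neg = self._cohorts(10, 40)
        a = build_modelling_dataset(pos, neg, balance=True, seed=42)
        b = build_modelling_dataset(pos, neg, balance=True, seed=42)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_empty_class_rejected(self):
        pos, neg = self._cohorts(10, 10)
        with pytest.raises(ValueError):
            build_modelling_dataset(pos.iloc[:0], neg)


class TestLogistic:
    def test_parameter_recovery_from_generative_model(self):
        rng = np.random.default_rng(123)
        n = 2000
        x = rng.uniform(0, 1, n)
        intercept, slope = -3.0, 6.0
        y = rng.random(n) < expit(intercept + slope * x)
        results = fit_logistic(frame(x, y.astype(int)), seed=0)
        assert results.params["intercept"] == pytest.approx(intercept, rel=0.10)
        assert results.params["mean_similarity"] == pytest.approx(slope, rel=0.10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(frame([0.1, 0.9], [1, 1]))

    def test_probability_half_at_logit_root(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 500)
        y = (rng.random(500) < expit(-2 + 4 * x)).astype(int)
        results = fit_logistic(frame(x, y), seed=0)
        root = -results.params["intercept"] / results.params["mean_similarity"]
        p = results.predict_proba(frame([root], [1]))
        assert p[0] == pytest.approx(0.5, abs=1e-9)

    def test_separation_guard_warns_and_fits(self):
        x = np.concatenate([np.linspace(0.7, 1, 20), np.linspace(0, 0.3, 20)])
        y = np.array([1] * 20 + [0] * 20)
        with pytest.warns(RuntimeWarning, match="separation"):
            results = fit_logistic(frame(x, y), seed=0)
        assert results.separation_guard
        assert np.isfinite(results.params["mean_similarity"])
        assert results.evaluate(frame(x, y)).accuracy == 1.0


class TestRandomForest:
    def test_similarity_ranked_most_important_when_only_it_separates(self):
        rng = np.random.default_rng(9)
        n = 300
        labels = np.array([1] * (n // 2) + [0] * (n // 2))
        similarity = np.where(
            labels == 1, rng.uniform(0.5, 1.0, n), rng.uniform(0.0, 0.5, n)
        )
        # label-independent by design
        term_count = rng.integers(1, 14, n)
        avg_ic = rng.uniform(1, 4, n)
        results = fit_random_forest(
            frame(similarity, labels, term_count, avg_ic), seed=0
        )
        assert results.importances.index[0] == "mean_similarity"

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(3)
        data = frame(rng.uniform(0, 1, 80), rng.integers(0, 2, 80))
        if data.label.nunique() < 2:  # pragma: no cover - guard
            data.loc[0, "label"] = 1 - data.loc[0, "label"]
        a = fit_random_forest(data, n_trees=50, seed=7).predict_proba(data)
        b = fit_random_forest(data, n_trees=50, seed=7).predict_proba(data)
        np.testing.assert_array_equal(a, b)

    def test_perfectly_separated_data_scores_perfectly(self):
        x = np.concatenate([np.linspace(0.8, 1, 15), np.linspace(0, 0.2, 15)])
        y = np.array([1] * 15 + [0] * 15)
        results = fit_random_forest(frame(x, y), n_trees=50, seed=0)
        assert results.evaluate(frame(x, y)).accuracy == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_random_forest(frame([0.1, 0.9], [0, 0]))


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        m = confusion_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert m.accuracy == m.sensitivity == m.specificity == 1.0
        assert m.kappa == 1.0

    def test_fixed_two_by_two_hand_values(self):
        y_true = [1] * 46 + [0] * 54
        y_pred = [1] * 40 + [0] * 6 + [1] * 9 + [0] * 45
        m = confusion_metrics(y_true, y_pred)
        assert (m.tp, m.fn, m.fp, m.tn) == (40, 6, 9, 45)
        assert m.accuracy == pytest.approx(0.85)
        assert m.sensitivity == pytest.approx(40 / 46)
        assert m.specificity == pytest.approx(45 / 54)
        assert m.ppv == pytest.approx(40 / 49)
        assert m.npv == pytest.approx(45 / 51)
        assert m.balanced_accuracy == pytest.approx(0.5 * (40 / 46 + 45 / 54))
        p_e = (46 * 49 + 54 * 51) / 100**2
        assert m.kappa == pytest.approx((0.85 - p_e) / (1 - p_e))

    def test_chance_agreement_kappa_near_zero(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, 4000)
        y_pred = rng.permutation(y_true)
        m = confusion_metrics(y_true, y_pred)
        assert abs(m.kappa) < 0.05

    def test_undefined_ratio_is_nan_with_warning(self):
        with pytest.warns(RuntimeWarning, match="PPV"):
            m = confusion_metrics([1, 0], [0, 0])
        assert np.isnan(m.ppv)

    def test_balanced_accuracy_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            y_true = rng.integers(0, 2, 50)
            if len(set(y_true)) < 2:
                continue
            y_pred = rng.integers(0, 2, 50)
            m = confusion_metrics(y_true, y_pred)
            assert m.balanced_accuracy == pytest.approx(
                0.5 * (m.sensitivity + m.specificity)
            )


class TestRocAucDelong:
    def test_perfect_separation(self):
        r = roc_auc_delong([0.8, 0.9, 0.1, 0.2], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_tie_across_classes_counts_half(self):
        scores = [0.9, 0.5, 0.5, 0.2]
        labels = [1, 1, 0, 0]
        r = roc_auc_delong(scores, labels)
        assert r.auc == pytest.approx(pair_count_auc(scores, labels))

    @pytest.mark.parametrize("seed", range(8))
    def test_auc_equals_pair_counting_on_random_instances(self, seed):
        rng = np.random.default_rng(700 + seed)
        n = int(rng.integers(10, 200))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if len(set(labels.tolist())) < 2:
            labels[0] = 1 - labels[0]
        r = roc_auc_delong(scores, labels)
        assert r.auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)
        assert r.ci_lower <= r.auc <= r.ci_upper

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        assert roc_auc_delong(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_constant_scores_degenerate(self):
        with pytest.warns(RuntimeWarning):
            r = roc_auc_delong([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0])
        assert r.auc == 0.5

    def test_matches_frozen_proc_delong_interval(self):
        """Expected values computed once with pROC's ci.auc(method='delong')."""
        pos = [0.746, 0.544, 0.813, 0.841, 0.407, 0.505, 0.719, 0.653, 0.697,
               0.572, 0.832, 0.817, 0.71, 0.869, 0.77, 0.571, 0.755, 0.556,
               0.832, 0.693, 0.672, 0.598, 0.883, 0.677, 0.636]
        neg = [0.397, 0.53, 0.505, 0.512, 0.515, 0.771, 0.389, 0.373, 0.328,
               0.542, 0.619, 0.433, 0.324, 0.326, 0.548, 0.561, 0.531, 0.35,
               0.485, 0.468, 0.483, 0.581, 0.484, 0.552, 0.46, 0.493, 0.545,
               0.231, 0.402, 0.379, 0.354, 0.409, 0.674, 0.32, 0.595, 0.198,
               0.4, 0.474, 0.538, 0.557]
        scores = np.array(pos + neg)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        r = roc_auc_delong(scores, labels)
        assert r.auc == pytest.approx(0.9135, abs=1e-10)
        assert r.auc_variance == pytest.approx(0.001377288462, abs=1e-10)
        # pROC uses qnorm(0.975); the 1.96 convention here differs < 5e-5
        assert r.ci_lower == pytest.approx(0.8407621357, abs=5e-5)
        assert r.ci_upper == pytest.approx(0.9862378643, abs=5e-5)


class TestYouden:
    def test_perfect_separation_j_one(self):
        r = roc_auc_delong([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        out = youden_threshold(r)
        assert out["j"] == pytest.approx(1.0)
        assert out["sensitivity"] == out["specificity"] == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_optimum_matches_exhaustive_cutpoint_scan(self, seed):
        rng = np.random.default_rng(800 + seed)
        n = int(rng.integers(8, 60))
        scores = np.round(rng.random(n), 2)
        labels = rng.integers(0, 2, n)
        if len(set(labels.tolist())) < 2:
            labels[0] = 1 - labels[0]
        r = roc_auc_delong(scores, labels)
        out = youden_threshold(r)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        best_j, best_thr = -np.inf, None
        for thr in r.thresholds:  # exhaustive scan over every cutpoint
            j = (pos >= thr).mean() + (neg < thr).mean() - 1.0
            if j > best_j + 1e-15:
                best_j, best_thr = j, thr
        assert out["j"] == pytest.approx(best_j, abs=1e-12)
        assert out["threshold"] == best_thr  # ties break toward lowest

    def test_logistic_closed_form_similarity(self):
        rng = np.random.default_rng(31)
        x = rng.uniform(0, 1, 400)
        y = (rng.random(400) < expit(-4 + 8 * x)).astype(int)
        results = fit_logistic(frame(x, y), seed=0)
        test = frame(x, y)
        out = results.youden(test)
        b0 = results.params["intercept"]
        b1 = results.params["mean_similarity"]
        thr = out["threshold"]
        expected = (np.log(thr / (1 - thr)) - b0) / b1
        assert out["similarity_at_threshold"] == pytest.approx(expected, abs=1e-9)

    def test_quantile_matching_for_nonmonotone_model(self):
        rng = np.random.default_rng(8)
        sim = rng.uniform(0, 1, 100)
        scores = rng.uniform(0, 1, 100)
        labels = rng.integers(0, 2, 100)
        labels[0] = 1
        labels[1] = 0
        r = roc_auc_delong(scores, labels)
        out = youden_threshold(r, similarity=sim, scores=scores)
        frac_above = (scores >= out["threshold"]).mean()
        expected = np.quantile(sim, 1 - frac_above, method="midpoint")
        assert out["similarity_at_threshold"] == pytest.approx(expected)


class TestModelResultsApi:
    def test_summary_mentions_kind_and_coefficients(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 200)
        y = (rng.random(200) < expit(-2 + 4 * x)).astype(int)
        results = fit_logistic(frame(x, y), seed=0)
        text = results.summary()
        assert "logistic" in text
        assert "mean_similarity" in text
        assert "intercept" in text

    def test_cv_summary_has_five_folds(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1, 100)
        y = (rng.random(100) < expit(-2 + 4 * x)).astype(int)
        if len(set(y.tolist())) < 2:
            y[0] = 1 - y[0]
        results = fit_logistic(frame(x, y), folds=5, seed=0)
        assert results.cv_accuracies.size == 5
        assert 0.0 <= results.cv_accuracy_mean <= 1.0
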