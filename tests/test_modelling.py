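"""Classifier training, metrics, CV, staged tuning and McNemar comparison."""

import numpy as np
import pytest

from trialterm.model import (
    ClassifierSpec,
    ContingencyTable,
    TerminationRiskModel,
    compute_metrics,
    cross_validate,
    mcnemar_table,
    mcnemar_test,
    train_classifier,
    tune_staged,
)


def planted_data(n=600, d=10, seed=0, signal=1.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    z = signal * X[:, 0] - signal * X[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-z))).astype(int)
    return X, y


class TestTrainClassifier:
    @pytest.mark.parametrize("family", ["random_forest", "gradient_boosting"])
    def test_tree_families_fit_separable_data(self, family):
        X = np.array([[0.0], [0.1], [0.9], [1.0]] * 5)
        y = np.array([0, 0, 1, 1] * 5)
        model = train_classifier(ClassifierSpec(family, {}, 0), X, y)
        assert np.array_equal(model.predict(X), y)

    @pytest.mark.parametrize(
        "family", ["logistic_regression", "random_forest", "gradient_boosting"]
    )
    def test_seeded_reproducibility(self, family):
        X, y = planted_data(300)
        spec = ClassifierSpec(family, {"n_trees": 50}, seed=3)
        p1 = train_classifier(spec, X, y).predict_proba(X)[:, 1]
        p2 = train_classifier(spec, X, y).predict_proba(X)[:, 1]
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            train_classifier(ClassifierSpec("logistic_regression"),
                             np.ones((5, 2)), np.ones(5))

    def test_gradient_boosting_recovers_planted_signal(self):
        X, y = planted_data(5000, seed=1)
        spec = ClassifierSpec("gradient_boosting", {"max_depth": 3, "n_trees": 150}, 0)
        model = train_classifier(spec, X[:3500], y[:3500])
        from sklearn.metrics import roc_auc_score

        auc = roc_auc_score(y[3500:], model.predict_proba(X[3500:])[:, 1])
        assert auc > 0.70

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("gradient_boosting", {"subsample_rows": 1.5})
        with pytest.raises(ValueError):
            ClassifierSpec("no_such_family")


class TestComputeMetrics:
    def test_perfect_predictions(self):
        r = compute_metrics([0, 1, 0, 1], [0.1, 0.9, 0.2, 0.8])
        assert (r.roc_auc, r.balanced_accuracy, r.f1_class0) == (1.0, 1.0, 1.0)

    def test_constant_probability_is_chance(self):
        y = [0, 1] * 10
        r = compute_metrics(y, [0.5] * 20)
        assert r.roc_auc == 0.5
        assert r.balanced_accuracy == 0.5

    def test_auc_equals_pairwise_concordance(self, rng):
        y = rng.integers(0, 2, size=10)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, size=10)
        p = rng.random(10)
        conc = 0.0
        pairs = 0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                pairs += 1
                conc += (p[i] > p[j]) + 0.5 * (p[i] == p[j])
        assert compute_metrics(y, p).roc_auc == pytest.approx(conc / pairs)

    def test_balanced_accuracy_identity(self, rng):
        y = np.r_[np.zeros(30), np.ones(70)].astype(int)
        p = rng.random(100)
        r = compute_metrics(y, p)
        assert r.balanced_accuracy == pytest.approx(
            (r.class0_accuracy + r.class1_accuracy) / 2
        )

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 1, 1], [0.5, 0.6, 0.7])


class TestCrossValidate:
    def test_fold_means_reported(self):
        X, y = planted_data(400, seed=2)
        rep = cross_validate(ClassifierSpec("logistic_regression"), X, y,
                             n_folds=5, seed=0)
        for key, values in rep.per_fold.items():
            assert len(values) == 5
            assert getattr(rep, key) == pytest.approx(np.mean(values))

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(600, 10))
        y = (rng.random(600) > 0.85).astype(int)  # imbalanced, no signal
        rep = cross_validate(
            ClassifierSpec("logistic_regression", {}, 0), X, y, n_folds=5, seed=1
        )
        assert 0.40 <= rep.balanced_accuracy <= 0.60


class TestTuneStaged:
    def test_singleton_grids_returned_verbatim(self):
        X, y = planted_data(200, seed=3)
        spec = tune_staged("gradient_boosting", X, y,
                           {"max_depth": [3], "min_child_weight": [1]},
                           {"subsample_rows": [0.9], "subsample_cols": [0.9]},
                           seed=0)
        assert spec.hyperparameters["max_depth"] == 3
        assert spec.hyperparameters["subsample_rows"] == 0.9

    def test_dominant_config_selected(self):
        # depth-1 trees cannot represent the XOR-ish interaction; depth-3 can
        rng = np.random.default_rng(4)
        X = rng.normal(size=(800, 4))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        spec = tune_staged("gradient_boosting", X, y,
                           {"max_depth": [1, 3], "min_child_weight": [1]},
                           {}, seed=0,
                           base_hyperparameters={"n_trees": 60})
        assert spec.hyperparameters["max_depth"] == 3


class TestMcNemar:
    def test_table_counts_match_naive_tally(self, rng):
        y = rng.integers(0, 2, size=200)
        p1 = rng.integers(0, 2, size=200)
        p2 = rng.integers(0, 2, size=200)
        t = mcnemar_table(y, p1, p2)
        assert t.a == sum((p1 == y) & (p2 == y))
        assert t.b == sum((p1 == y) & (p2 != y))
        assert t.c == sum((p1 != y) & (p2 == y))
        assert t.n == 200

    def test_identical_predictions_no_discordance(self):
        y = np.array([0, 1, 1, 0])
        p = np.array([0, 1, 0, 0])
        t = mcnemar_table(y, p, p)
        assert t.b == t.c == 0

    def test_opposite_models(self):
        y = np.ones(10, dtype=int)
        t = mcnemar_table(y, np.ones(10, dtype=int), np.zeros(10, dtype=int))
        assert (t.a, t.b, t.c, t.d) == (0, 10, 0, 0)

    def test_published_contingency_reproduces_statistic(self):
        t = ContingencyTable(a=20700, b=1642, c=2261, d=9178)
        stat, p, reject = mcnemar_test(t, continuity_correction=True, alpha=0.01)
        assert stat == pytest.approx(97.85, abs=0.005)
        assert p == pytest.approx(4.504e-23, rel=1e-3)
        assert reject

    def test_uncorrected_variant(self):
        t = ContingencyTable(a=20700, b=1642, c=2261, d=9178)
        stat, _, _ = mcnemar_test(t, continuity_correction=False)
        assert stat == pytest.approx(619**2 / 3903, rel=1e-12)
        assert stat == pytest.approx(98.17, abs=0.005)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        t = ContingencyTable(a=50, b=17, c=5, d=8)
        stat, p, _ = mcnemar_test(t, continuity_correction=True)
        sm = sm_mcnemar([[t.a, t.b], [t.c, t.d]], exact=False, correction=True)
        assert stat == pytest.approx(sm.statistic)
        assert p == pytest.approx(sm.pvalue)

    def test_equal_discordance_uncorrected_is_zero(self):
        stat, p, reject = mcnemar_test(ContingencyTable(5, 4, 4, 2),
                                       continuity_correction=False)
        assert stat == 0.0 and p == 1.0 and not reject

    def test_symmetry_and_monotonicity(self):
        s1, _, _ = mcnemar_test(ContingencyTable(0, 30, 10, 0))
        s2, _, _ = mcnemar_test(ContingencyTable(0, 10, 30, 0))
        assert s1 == s2
        _, p_small, _ = mcnemar_test(ContingencyTable(0, 25, 15, 0))
        _, p_large, _ = mcnemar_test(ContingencyTable(0, 35, 5, 0))
        assert p_large < p_small

    def test_no_disagreement_is_degenerate(self):
        with pytest.raises(ValueError, match="disagree"):
            mcnemar_test(ContingencyTable(5, 0, 0, 5))


class TestModelResultsObjects:
    def test_fit_summary_and_compare(self):
        from trialterm.selection import split_train_test

        X, y = planted_data(700, d=8, seed=6)
        ids = [f"N{i}" for i in range(700)]
        split = split_train_test(ids, y, seed=0)
        m_full = TerminationRiskModel.from_arrays(
            X, y, row_ids=ids,
            spec=ClassifierSpec("gradient_boosting", {"max_depth": 3, "n_trees": 60}, 0),
            split=split,
        )
        res_full = m_full.fit(cv_folds=3)
        assert res_full.test_report is not None
        assert "balanced accuracy" in res_full.summary()
        # degraded model: only the last (noise) features
        m_noise = TerminationRiskModel.from_arrays(
            X[:, 4:], y, row_ids=ids,
            spec=ClassifierSpec("gradient_boosting", {"max_depth": 3, "n_trees": 60}, 0),
            split=split,
        )
        res_noise = m_noise.fit(cv_folds=3)
        cmp = res_full.compare(res_noise, alpha=0.01)
        assert cmp.table.n == len(split.test_ids)
        assert cmp.reject_null  # real signal vs pure noise must separate
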