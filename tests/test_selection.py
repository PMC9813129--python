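"""Train/test splitting, undersampling, ANOVA-F ranking and elbow search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from trialterm.selection import (
    StratificationError,
    ablation_elbow,
    anova_f_scores,
    find_elbow,
    select_k_best,
    split_train_test,
    undersample,
)


def imbalanced_ids(n=1000, fail=0.15, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"N{i}" for i in range(n)]
    labels = (rng.random(n) > fail).astype(int)
    return ids, labels


class TestSplit:
    def test_sizes(self):
        ids, labels = imbalanced_ids(100)
        s = split_train_test(ids, labels, ratio=0.7, seed=1)
        assert len(s.train_ids) == 70 and len(s.test_ids) == 30
        assert set(s.train_ids) | set(s.test_ids) == set(ids)
        assert not set(s.train_ids) & set(s.test_ids)

    def test_stratification_preserves_mix(self):
        ids, labels = imbalanced_ids(2000, fail=0.15)
        s = split_train_test(ids, labels, seed=2)
        lab = dict(zip(ids, labels))
        test_fail = 1 - np.mean([lab[i] for i in s.test_ids])
        overall_fail = 1 - labels.mean()
        assert abs(test_fail - overall_fail) < 0.01

    def test_deterministic(self):
        ids, labels = imbalanced_ids(200)
        a = split_train_test(ids, labels, seed=9)
        b = split_train_test(ids, labels, seed=9)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_single_class_raises(self):
        with pytest.raises(StratificationError):
            split_train_test(["a", "b", "c"], [1, 1, 1])


class TestUndersample:
    def test_exact_one_to_one(self):
        ids, labels = imbalanced_ids(1000, fail=0.15, seed=3)
        lab = dict(zip(ids, labels))
        kept = undersample(ids, lab, seed=0)
        counts = np.bincount([lab[i] for i in kept])
        assert counts[0] == counts[1]

    def test_every_minority_sample_kept(self):
        ids, labels = imbalanced_ids(500, seed=4)
        lab = dict(zip(ids, labels))
        kept = set(undersample(ids, lab, seed=0))
        minority = {i for i in ids if lab[i] == 0}
        assert minority <= kept

    def test_already_balanced_unchanged(self):
        ids = ["a", "b", "c", "d"]
        lab = {"a": 0, "b": 1, "c": 0, "d": 1}
        assert undersample(ids, lab, seed=0) == ids

    def test_seeded_determinism(self):
        ids, labels = imbalanced_ids(300, seed=5)
        lab = dict(zip(ids, labels))
        assert undersample(ids, lab, seed=7) == undersample(ids, lab, seed=7)

    def test_bad_ratio_raises(self):
        with pytest.raises(ValueError):
            undersample(["a", "b"], {"a": 0, "b": 1}, ratio=0.0)


class TestAnovaF:
    def test_equal_class_means_give_zero(self):
        X = np.array([[1.0], [2.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        r = anova_f_scores(X, y)
        assert r.scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_equals_squared_t_statistic(self, rng):
        X = rng.normal(size=(200, 8))
        y = rng.integers(0, 2, size=200)
        r = anova_f_scores(X, y)
        for j in range(8):
            t, _ = stats.ttest_ind(X[y == 0, j], X[y == 1, j], equal_var=True)
            assert r.scores[j] == pytest.approx(t**2, rel=1e-9)

    def test_constant_column_ranked_last(self):
        X = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)]])
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        r = anova_f_scores(X, y, ["const", "signal"])
        assert np.isnan(r.scores[0])
        assert r.feature_names[r.order[-1]] == "const"

    def test_affine_rescaling_invariance(self, rng):
        X = rng.normal(size=(100, 3))
        y = rng.integers(0, 2, size=100)
        a = anova_f_scores(X, y).scores
        b = anova_f_scores(X * 7.5 - 3.0, y).scores
        np.testing.assert_allclose(a, b, rtol=1e-8)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            anova_f_scores(np.ones((4, 2)), np.zeros(4, dtype=int))


class TestSelectKBest:
    def ranking(self, rng):
        X = rng.normal(size=(120, 6))
        y = rng.integers(0, 2, size=120)
        X[:, 2] += 3 * y  # make one feature clearly best
        return anova_f_scores(X, y, [f"c{j}" for j in range(6)])

    def test_k_all_is_identity(self, rng):
        r = self.ranking(rng)
        assert set(select_k_best(r, 6)) == set(r.feature_names)

    def test_k1_is_argmax(self, rng):
        r = self.ranking(rng)
        assert select_k_best(r, 1) == ["c2"]

    def test_nesting(self, rng):
        r = self.ranking(rng)
        for k1 in range(1, 6):
            assert set(select_k_best(r, k1)) <= set(select_k_best(r, k1 + 1))

    def test_tie_breaks_by_name(self):
        from trialterm.selection import FeatureRanking

        r = FeatureRanking(["zed", "alpha"], np.array([5.0, 5.0]))
        assert select_k_best(r, 1) == ["alpha"]

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValueError):
            select_k_best(self.ranking(rng), 0)


class TestElbow:
    def planted_curve(self, breakpoint=2000):
        k = [250, 500, 1000, breakpoint, 4000, 8000, 12000]
        err = [0.40 - 0.05 * i for i in range(k.index(breakpoint) + 1)]
        err += [err[-1] - 0.002 * (i + 1) for i in range(len(k) - len(err))]
        return k, err

    def test_planted_breakpoint_recovered(self):
        k, err = self.planted_curve()
        assert find_elbow(k, err) == 2000

    def test_linear_curve_gives_smallest_interior(self):
        assert find_elbow([1, 2, 3, 4], [4.0, 3.0, 2.0, 1.0]) == 2

    def test_matches_bruteforce_distance_scan(self, rng):
        for _ in range(20):
            k = np.sort(rng.choice(np.arange(10, 5000), size=8, replace=False))
            err = np.sort(rng.random(8))[::-1]
            kn = (k - k[0]) / (k[-1] - k[0])
            span = err.max() - err.min()
            en = (err - err.min()) / span
            dx, dy = kn[-1] - kn[0], en[-1] - en[0]
            dist = np.abs(dy * kn - dx * en - dy * kn[0] + dx * en[0]) / np.hypot(dx, dy)
            brute = int(k[1 + np.argmax(dist[1:-1])])
            assert find_elbow(list(k), list(err)) == brute

    def test_evaluate_called_on_grid(self):
        calls = []

        def ev(k):
            calls.append(k)
            return 1.0 / k

        curve = ablation_elbow([10, 100, 1000], ev)
        assert calls == [10, 100, 1000]
        assert curve.elbow_k in curve.k_grid

    def test_non_finite_error_propagates_offending_k(self):
        with pytest.raises(ValueError, match="17"):
            find_elbow([3, 17, 30], [1.0, np.nan, 0.1])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_undersample_never_touches_ids_outside_input(seed):
    ids, labels = imbalanced_ids(80, seed=6)
    lab = dict(zip(ids, labels))
    kept = undersample(ids, lab, seed=seed)
    assert set(kept) <= set(ids)
    counts = np.bincount([lab[i] for i in kept])
    assert counts[0] == counts[1]
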