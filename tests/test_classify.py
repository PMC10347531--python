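"""Feature selection, ROC and nested cross-validation."""

import numpy as np
import pytest

from freqec import (
    CVConfig,
    FeatureTable,
    combine_band_features,
    ec_feature_table,
    mrmr_select,
    nested_cv,
    roc_curve,
    svmrfe_select,
)


def _table(X, y, band="b"):
    ids = [(band, i, i + 1000) for i in range(X.shape[1])]
    return FeatureTable(X=X, feature_ids=ids, labels=y)


class TestMRMR:
    def test_label_copy_ranks_first(self):
        rng = np.random.default_rng(0)
        hits = 0
        for s in range(30):
            r = np.random.default_rng(s)
            y = r.integers(0, 2, 80)
            X = r.standard_normal((80, 20))
            X[:, 7] = y + 0.01 * r.standard_normal(80)
            hits += mrmr_select(X, y, 1)[0] == 7
        assert hits >= 29

    def test_duplicate_penalised_below_weak_feature(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200)
        strong = y + 0.1 * rng.standard_normal(200)
        weak = 0.6 * y + 1.2 * rng.standard_normal(200)
        noise = rng.standard_normal(200)
        X = np.column_stack([strong, strong.copy(), weak, noise])
        order = mrmr_select(X, y, 4)
        assert order[0] == 0
        assert order.index(2) < order.index(1)

    def test_k_zero_empty(self):
        assert mrmr_select(np.zeros((10, 3)), np.zeros(10, dtype=int), 0) == []

    def test_constant_feature_harmless(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 60)
        X = np.column_stack([np.ones(60), y + 0.1 * rng.standard_normal(60)])
        assert mrmr_select(X, y, 2) == [1, 0]


class TestSVMRFE:
    def test_removal_order_on_constructed_weights(self):
        rng = np.random.default_rng(3)
        n = 120
        y = np.r_[np.zeros(60), np.ones(60)].astype(int)
        # feature 0 separates strongly, 1 moderately, 2 is noise
        X = np.column_stack(
            [
                y * 4.0 + 0.3 * rng.standard_normal(n),
                y * 1.5 + 1.0 * rng.standard_normal(n),
                rng.standard_normal(n),
            ]
        )
        assert svmrfe_select(X, y, target_k=2) == [0, 1]
        assert svmrfe_select(X, y, target_k=1) == [0]

    def test_identity_when_target_equals_count(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 5))
        y = rng.integers(0, 2, 40)
        assert svmrfe_select(X, y, 5) == list(range(5))

    def test_tied_features_lowest_index_survives(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 50)
        f = (y + 0.5 * rng.standard_normal(50))[:, None]
        X = np.repeat(f, 4, axis=1)
        assert svmrfe_select(X, y, 1) == [0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            svmrfe_select(np.random.default_rng(0).standard_normal((20, 3)), np.zeros(20), 1)


class TestROC:
    def test_perfect_ordering(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        *_, auc = roc_curve(scores, labels)
        assert auc == 1.0

    def test_hand_case_pair_counting(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        *_, auc = roc_curve(scores, labels)
        assert auc == pytest.approx(0.75)

    def test_chance_level_large_n(self):
        rng = np.random.default_rng(6)
        scores = rng.standard_normal(10000)
        labels = rng.integers(0, 2, 10000)
        *_, auc = roc_curve(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_equals_mannwhitney_with_ties(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(7)
        scores = np.round(rng.standard_normal(200), 1)  # force ties
        labels = rng.integers(0, 2, 200)
        *_, auc = roc_curve(scores, labels)
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert auc == pytest.approx(u / ((labels == 1).sum() * (labels == 0).sum()), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        scores = rng.standard_normal(300)
        labels = (scores + rng.standard_normal(300) > 0).astype(int)
        *_, auc = roc_curve(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            roc_curve(np.arange(5.0), np.ones(5, dtype=int))


class TestCombine:
    def _tables(self):
        rng = np.random.default_rng(9)
        ec1 = np.abs(rng.standard_normal((20, 4, 4)))
        ec2 = np.abs(rng.standard_normal((20, 4, 4)))
        for e in (ec1, ec2):
            e[:, np.arange(4), np.arange(4)] = 0
        y = rng.integers(0, 2, 20)
        sids = [f"s{i}" for i in range(20)]
        return ec_feature_table(ec1, "F1", y, sids), ec_feature_table(ec2, "F2", y, sids)

    def test_single_band_identity(self):
        t1, _ = self._tables()
        combined = combine_band_features([t1])
        np.testing.assert_array_equal(combined.X, t1.X)

    def test_column_counts_and_unique_ids(self):
        t1, t2 = self._tables()
        combined = combine_band_features([t1, t2])
        assert combined.X.shape[1] == 2 * 12
        assert len(set(combined.feature_ids)) == 24

    def test_round_trip_slicing(self):
        t1, t2 = self._tables()
        combined = combine_band_features([t1, t2])
        np.testing.assert_array_equal(combined.X[:, :12], t1.X)
        np.testing.assert_array_equal(combined.X[:, 12:], t2.X)

    def test_subject_mismatch_rejected(self):
        t1, t2 = self._tables()
        t2.subject_ids = list(reversed(t2.subject_ids))
        with pytest.raises(ValueError):
            combine_band_features([t1, t2])


FAST_CV = CVConfig(folds=5, repeats=1, mrmr_floor=5, mrmr_frac=0.3,
                   k_grid=(5,), c_grid=(1.0,), inner_folds=3)


class TestNestedCV:
    def test_separable_classes_high_accuracy(self):
        rng = np.random.default_rng(10)
        mu = np.zeros(100)
        mu[:5] = 4.0
        X = np.vstack([rng.standard_normal((50, 100)),
                       rng.standard_normal((50, 100)) + mu])
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        cfg = CVConfig(folds=10, repeats=1, mrmr_floor=20,
                       k_grid=(10, 20), c_grid=(0.1, 1.0), inner_folds=3)
        res = nested_cv(_table(X, y), cfg, seed=0)
        assert res.accuracy >= 95.0

    def test_determinism(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((40, 20))
        y = rng.integers(0, 2, 40)
        a = nested_cv(_table(X, y), FAST_CV, seed=5)
        b = nested_cv(_table(X, y), FAST_CV, seed=5)
        assert a.metrics() == b.metrics()
        assert a.selection_frequency.equals(b.selection_frequency)

    def test_selection_frequency_finds_informative_features(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, 80)
        X = rng.standard_normal((80, 30))
        X[:, 3] += 2.0 * y
        X[:, 17] += 2.0 * y
        res = nested_cv(_table(X, y), FAST_CV, seed=1)
        top = set(res.selection_frequency.head(2)["source"])
        assert top == {3, 17}

    def test_leakage_guard_poisoned_test_fold_changes_nothing_trainside(self):
        """Corrupting the held-out fold must not alter training-time choices."""
        rng = np.random.default_rng(13)
        X = rng.standard_normal((60, 25))
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)[rng.permutation(60)]
        clean = nested_cv(_table(X, y), FAST_CV, seed=2)
        fold0 = clean.fold_assignments[0]
        X_poison = X.copy()
        X_poison[fold0] = 1e6 * rng.standard_normal((len(fold0), 25))
        poisoned = nested_cv(_table(X_poison, y), FAST_CV, seed=2)
        d_clean, d_pois = clean.fold_details[0], poisoned.fold_details[0]
        assert d_clean["selected"] == d_pois["selected"]
        assert d_clean["c"] == d_pois["c"]
        np.testing.assert_array_equal(d_clean["scaler_mean"], d_pois["scaler_mean"])
        np.testing.assert_array_equal(d_clean["scaler_sd"], d_pois["scaler_sd"])
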