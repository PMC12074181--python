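"""QC gates, feature ranking, and cross-validated LDA behavior."""

import numpy as np
import pandas as pd
import pytest

from doughnose.chemometrics import (
    classify_features,
    lda_loocv,
    outlier_mask,
    rank_features,
    uncertainty_filter,
)


def feature_table(minima_by_sample):
    """Minimal feature table with one sensor's minimum per replicate."""
    rows = []
    for sample_id, minima in minima_by_sample.items():
        for rep, m in enumerate(minima):
            rows.append(
                {
                    "sample_id": sample_id,
                    "replicate": rep,
                    "flour": "W250",
                    "phase": "PRE",
                    "S1__minimum": m,
                }
            )
    return pd.DataFrame(rows)


class TestUncertaintyFilter:
    def test_identical_replicates_pass(self):
        qc = uncertainty_filter(feature_table({"a": [0.5, 0.5, 0.5]}))
        assert qc.passed_samples == ["a"]
        assert qc.failed_samples == []
        assert (qc.table["rsd"] == 0).all()

    def test_spread_above_threshold_fails(self):
        # sd/mean of [0.5, 0.6] is ~12.9% > 10%
        qc = uncertainty_filter(feature_table({"a": [0.5, 0.6]}))
        assert qc.failed_samples == ["a"]
        rsd = qc.table["rsd"].iloc[0]
        assert rsd == pytest.approx(np.std([0.5, 0.6], ddof=1) / 0.55)

    def test_zero_threshold_fails_any_noise(self):
        qc = uncertainty_filter(
            feature_table({"a": [0.5, 0.5001], "b": [0.4, 0.4]}), threshold=0.0
        )
        assert qc.failed_samples == ["a"]
        assert qc.passed_samples == ["b"]

    def test_single_replicate_warns_and_passes(self):
        with pytest.warns(UserWarning, match="single replicate"):
            qc = uncertainty_filter(feature_table({"a": [0.5]}))
        assert qc.passed_samples == ["a"]


class TestOutlierMask:
    def test_injected_outlier_flagged(self, rng):
        X = rng.standard_normal((1000, 3))
        X[137, 1] = 10.0
        mask = outlier_mask(X)
        assert mask[137]
        assert mask.sum() <= 1 + int(0.01 * 1000 * 3)

    def test_infinite_threshold_flags_nothing(self, rng):
        X = rng.standard_normal((50, 4))
        assert not outlier_mask(X, k_sigma=np.inf).any()

    def test_within_class_not_pooled(self, rng):
        # two classes far apart: pooled z-scores would flag everything,
        # within-class z-scores nothing
        X = np.concatenate([rng.normal(0, 1, 50), rng.normal(100, 1, 50)])[:, None]
        y = np.array(["a"] * 50 + ["b"] * 50)
        assert not outlier_mask(X, y).any()

    def test_degenerate_class_warns(self):
        X = np.ones((5, 2))
        with pytest.warns(UserWarning, match="zero variance"):
            mask = outlier_mask(X)
        assert not mask.any()


class TestRankFeatures:
    def test_separating_feature_ranked_first(self, rng):
        n = 60
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        X = rng.standard_normal((n, 5))
        X[:, 2] = np.where(y == "a", 0.0, 5.0) + 0.1 * rng.standard_normal(n)
        ranked = rank_features(X, y, n_trees=200, seed=0)
        assert ranked[0] == "f2"

    def test_duplicated_feature_splits_importance(self, rng):
        n = 80
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        signal = np.where(y == "a", 0.0, 3.0) + 0.2 * rng.standard_normal(n)
        X = np.column_stack([signal, signal] + [rng.standard_normal(n) for _ in range(3)])
        ranked = rank_features(X, y, n_trees=200, seed=1)
        assert set(ranked[:2]) == {"f0", "f1"}

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((40, 6))
        y = np.array(["a", "b"] * 20)
        assert rank_features(X, y, seed=7, n_trees=50) == rank_features(
            X, y, seed=7, n_trees=50
        )

    def test_constant_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            rank_features(rng.standard_normal((10, 2)), np.zeros(10))

    def test_default_panel_size_is_seven(self):
        from doughnose.chemometrics import DEFAULT_K_FEATURES

        assert DEFAULT_K_FEATURES == 7


def separable_data(rng, n_per_class=20, p=6, gap=10.0):
    y = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    X = rng.standard_normal((2 * n_per_class, p))
    X[y == "b", 0] += gap
    return X, y


class TestLdaLoocv:
    def test_strong_separation_gives_perfect_accuracy(self, rng):
        X, y = separable_data(rng)
        res = lda_loocv(X, y, k_features=3, n_trees=100, seed=0)
        assert res.accuracy == 1.0
        assert res.confusion.to_numpy().sum() == 40

    def test_permuted_labels_fall_to_chance(self, rng):
        """Permutation null: mean LOOCV accuracy over 50 label shuffles of
        pure-noise two-class data stays near chance."""
        X = rng.standard_normal((40, 5))
        accs = []
        for seed in range(50):
            y = np.random.default_rng(seed).permutation(
                np.array(["a"] * 20 + ["b"] * 20)
            )
            res = lda_loocv(X, y, k_features=5, seed=seed)
            accs.append(res.accuracy)
        assert 0.2 <= np.mean(accs) <= 0.8

    def test_two_class_3d_has_one_genuine_axis(self, rng):
        X, y = separable_data(rng)
        res = lda_loocv(X, y, n_components=3, k_features=3, n_trees=100, seed=0)
        assert res.axis_names == ["LD1", "PC1(suppl)", "PC2(suppl)"]
        assert res.projections.shape[1] == 1 + 3  # label + 3 axes

    def test_three_class_has_two_axes(self, rng):
        y = np.repeat(["a", "b", "c"], 15)
        X = rng.standard_normal((45, 4))
        X[:, 0] += np.repeat([0.0, 8.0, 16.0], 15)
        X[:, 1] += np.repeat([0.0, 8.0, -8.0], 15)
        res = lda_loocv(X, y, n_components=2, k_features=4, seed=0)
        assert res.axis_names == ["LD1", "LD2"]
        assert res.accuracy == 1.0

    def test_no_leakage_from_held_out_label(self, rng):
        """Flipping one observation's label never changes its own fold's
        prediction: that label is invisible to the fold's training data."""
        X, y = separable_data(rng, n_per_class=10, gap=2.0)
        res_a = lda_loocv(X, y, k_features=2, n_trees=50, seed=0)
        y_flipped = y.copy()
        y_flipped[0] = "b"
        res_b = lda_loocv(X, y_flipped, k_features=2, n_trees=50, seed=0)
        assert res_a.loocv_predictions.iloc[0] == res_b.loocv_predictions.iloc[0]

    def test_fold_losing_class_is_explained(self, rng):
        X = rng.standard_normal((5, 3))
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError, match="more data|more samples"):
            lda_loocv(X, y, k_features=3, seed=0)

    def test_projection_invariant_to_feature_rescaling(self, rng):
        """With standardization, affine feature rescaling leaves the LDA
        projection unchanged up to axis sign."""
        X, y = separable_data(rng, n_per_class=12)
        res_a = lda_loocv(X, y, k_features=X.shape[1], seed=0)
        res_b = lda_loocv(X * np.array([10.0, 0.2, 3.0, 1.0, 7.0, 0.5]), y,
                          k_features=X.shape[1], seed=0)
        a = res_a.projections["LD1"].to_numpy()
        b = res_b.projections["LD1"].to_numpy()
        sign = np.sign(np.dot(a, b)) or 1.0
        np.testing.assert_allclose(a, sign * b, atol=1e-6)

    def test_grouped_folds_keep_replicates_together(self, prepost_features):
        from doughnose.features import impute_median

        df = impute_median(prepost_features)
        cols = [c for c in df.columns if "__" in c]
        res = lda_loocv(
            df[cols],
            df["phase"].to_numpy(),
            k_features=7,
            n_trees=100,
            seed=0,
            groups=df["sample_id"].to_numpy(),
        )
        assert res.accuracy == 1.0


class TestClassifyFeatures:
    def test_prepost_task_full_accuracy(self, prepost_features):
        res, qc, counts = classify_features(
            prepost_features, task="prepost", flour="W390", seed=42, n_trees=100
        )
        assert res.accuracy == 1.0
        assert counts["observations_in"] == 60
        assert (
            counts["observations_modelled"]
            == counts["observations_after_qc"] - counts["outliers_removed"]
        )

    def test_unknown_task_rejected(self, prepost_features):
        with pytest.raises(ValueError, match="unknown task"):
            classify_features(prepost_features, task="banana")

    def test_prepost_needs_flour(self, prepost_features):
        with pytest.raises(ValueError, match="requires a flour"):
            classify_features(prepost_features, task="prepost")
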