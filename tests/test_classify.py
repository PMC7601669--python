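"""SVM discrimination: standardization, CV evaluation, feature-set pairing."""

import numpy as np
import pandas as pd
import pytest

from porepulse import (
    SvmConfig,
    compare_feature_sets,
    permutation_null_accuracy,
    standardize,
    train_eval_svm,
)
from porepulse.stats import FEATURES_FIVE


def gaussian_table(n_per_class, centers, seed=0, sd=1.0):
    """Five iid-noise features with per-class mean offsets."""
    rng = np.random.default_rng(seed)
    parts = []
    for label, center in centers.items():
        X = rng.normal(0, sd, (n_per_class, 5)) + np.asarray(center)
        df = pd.DataFrame(X, columns=list(FEATURES_FIVE))
        df["label"] = label
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


WELL_SEPARATED = gaussian_table(
    100, {"a": np.zeros(5), "b": np.full(5, 5.0), "c": np.full(5, 10.0)}
)


class TestStandardize:
    def test_training_columns_become_zero_mean_unit_sd(self):
        X = np.random.default_rng(0).normal(3, 7, (200, 4))
        Z, _, _ = standardize(X)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(Z.std(axis=0), 1, atol=1e-9)

    def test_already_standardized_input_is_identity(self):
        X = np.random.default_rng(1).normal(0, 1, (5000, 3))
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        Z, means, scales = standardize(X)
        assert np.allclose(Z, X, atol=1e-9)
        assert np.allclose(means, 0, atol=1e-9)
        assert np.allclose(scales, 1, atol=1e-9)

    def test_no_leakage_from_held_out_outlier(self):
        # Scaling parameters fitted on training rows are unchanged by any
        # outlier in the held-out part.
        X = np.random.default_rng(2).normal(0, 1, (100, 2))
        _, means, scales = standardize(X[:80])
        test = X[80:].copy()
        test[0] = 1e6
        Z_test, m2, s2 = standardize(test, means, scales)
        assert np.array_equal(means, m2)
        assert np.array_equal(scales, s2)

    def test_constant_feature_error_names_feature(self):
        X = np.ones((50, 2))
        X[:, 0] = np.arange(50)
        with pytest.raises(ValueError, match="dwell_s"):
            standardize(X, feature_names=("rel_blockade", "dwell_s"))


class TestTrainEvalSvm:
    def test_well_separated_clusters_classified_almost_perfectly(self):
        rep = train_eval_svm(WELL_SEPARATED, "five", SvmConfig(seed=0))
        assert rep.accuracy >= 0.99

    def test_confusion_row_sums_equal_class_counts(self):
        rep = train_eval_svm(WELL_SEPARATED, "five", SvmConfig(seed=0))
        assert rep.confusion.sum(axis=1).tolist() == [100, 100, 100]
        assert rep.accuracy == pytest.approx(
            np.trace(rep.confusion) / rep.confusion.sum()
        )

    def test_reproducible_under_fixed_seed(self):
        r1 = train_eval_svm(WELL_SEPARATED, "two", SvmConfig(seed=3))
        r2 = train_eval_svm(WELL_SEPARATED, "two", SvmConfig(seed=3))
        assert np.array_equal(r1.confusion, r2.confusion)
        assert r1.accuracy == r2.accuracy

    def test_permuted_labels_give_chance_accuracy(self):
        # 95% binomial band around 1/3 at n = 300.
        acc = permutation_null_accuracy(
            WELL_SEPARATED, "five", SvmConfig(seed=0), n_permutations=1, seed=1
        )[0]
        half_width = 1.96 * np.sqrt((1 / 3) * (2 / 3) / len(WELL_SEPARATED))
        assert abs(acc - 1 / 3) <= half_width

    def test_class_smaller_than_folds_rejected(self):
        tiny = gaussian_table(3, {"a": np.zeros(5), "b": np.ones(5)})
        with pytest.raises(ValueError, match="folds"):
            train_eval_svm(tiny, "two", SvmConfig(folds=5))


class TestCompareFeatureSets:
    def test_signal_only_in_blockade_keeps_sets_comparable(self):
        # Extra uninformative features cost at most a few points.
        centers = {
            "a": [0, 0, 0, 0, 0],
            "b": [2.5, 0, 0, 0, 0],
            "c": [5.0, 0, 0, 0, 0],
        }
        reports = compare_feature_sets(gaussian_table(100, centers), SvmConfig(seed=0))
        assert abs(reports["five"].accuracy - reports["two"].accuracy) <= 0.05

    def test_no_signal_gives_chance_for_both(self):
        table = gaussian_table(
            80, {"a": np.zeros(5), "b": np.zeros(5), "c": np.zeros(5)}
        )
        reports = compare_feature_sets(table, SvmConfig(seed=0))
        half_width = 1.96 * np.sqrt((1 / 3) * (2 / 3) / len(table))
        for rep in reports.values():
            assert abs(rep.accuracy - 1 / 3) <= half_width

    def test_five_features_beat_two_on_benchmark(self, benchmark_reports):
        # Class signal sits mostly in the flank slopes, which only the
        # five-feature set sees; folds are shared so the gap is paired.
        assert (
            benchmark_reports["five"].accuracy
            >= benchmark_reports["two"].accuracy
        )
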