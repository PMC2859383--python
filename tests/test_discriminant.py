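"""Discriminant pipeline: z-scoring, balancing, eigen-DFA, CV, MI."""
import numpy as np
import pandas as pd
import pytest
from numpy.random import default_rng

from gigglekit.discriminant import (
    ConfusionMatrix,
    balance_notes,
    chance_level,
    cross_validate,
    fit_lda,
    mutual_information,
    predict_lda,
    zscore_table,
)
from gigglekit.features import FEATURE_COLUMNS


def _gaussian_classes(means, n_per_class, n_dim=4, seed=0, scale=1.0):
    rng = default_rng(seed)
    rows, labels = [], []
    for ci, mu in enumerate(means):
        X = rng.normal(0, scale, size=(n_per_class, n_dim))
        X[:, : len(mu)] += mu
        rows.append(X)
        labels += [f"c{ci}"] * n_per_class
    cols = [f"x{i}" for i in range(n_dim)]
    df = pd.DataFrame(np.vstack(rows), columns=cols)
    df["label"] = labels
    return df, cols


class TestZscore:
    def test_three_point_column(self):
        df = pd.DataFrame({"mean_f": [1.0, 2.0, 3.0]})
        z, center, scale = zscore_table(df, ["mean_f"])
        assert np.allclose(z["mean_f"], [-1, 0, 1])

    def test_idempotent_on_standardised(self):
        rng = default_rng(1)
        df = pd.DataFrame({"mean_f": rng.normal(size=200)})
        z1, *_ = zscore_table(df, ["mean_f"])
        z2, *_ = zscore_table(z1, ["mean_f"])
        assert np.allclose(z1["mean_f"], z2["mean_f"], atol=1e-12)

    def test_test_rows_use_training_parameters(self):
        rng = default_rng(2)
        train = pd.DataFrame({"mean_f": rng.normal(0, 1, 100)})
        test = pd.DataFrame({"mean_f": rng.normal(3, 1, 100)})
        _, center, scale = zscore_table(train, ["mean_f"])
        z_test = (test["mean_f"] - center["mean_f"]) / scale["mean_f"]
        assert abs(z_test.mean()) > 1  # shifted test set keeps its shift

    def test_zero_variance_named(self):
        df = pd.DataFrame({"mean_f": [1.0, 1.0, 1.0], "dur": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="mean_f"):
            zscore_table(df, ["mean_f", "dur"])


class TestBalance:
    def test_exact_sampling(self, twin_features):
        bal = balance_notes(twin_features, 20, seed=0)
        sizes = bal.groupby("animal_id").size()
        assert (sizes == 20).all()
        assert len(bal) == 17 * 20

    def test_animal_keeping_all_notes(self):
        df = pd.DataFrame(
            {"animal_id": ["a"] * 20 + ["b"] * 25, "mean_f": np.arange(45.0)}
        )
        bal = balance_notes(df, 20, seed=1)
        a_notes = set(bal[bal.animal_id == "a"]["mean_f"])
        assert a_notes == set(np.arange(20.0))

    def test_shortfall_error_lists_offenders(self):
        df = pd.DataFrame({"animal_id": ["a"] * 5 + ["b"] * 25, "mean_f": np.arange(30.0)})
        with pytest.raises(ValueError, match="a"):
            balance_notes(df, 20)

    def test_same_seed_same_subsample(self, twin_features):
        b1 = balance_notes(twin_features, 20, seed=9)
        b2 = balance_notes(twin_features, 20, seed=9)
        pd.testing.assert_frame_equal(b1, b2)


class TestFitLDA:
    def test_separated_classes_first_function(self):
        df, cols = _gaussian_classes([[0.0], [10.0]], 50, seed=3)
        model = fit_lda(df, "label", feature_columns=cols)
        w = np.abs(model.loadings[:, 0])
        assert np.argmax(w) == 0  # loads on the separating dimension
        assert model.wilks_p[0] < 1e-3
        assert model.n_significant >= 1

    def test_null_classes_rarely_significant(self):
        hits = 0
        for seed in range(40):
            df, cols = _gaussian_classes([[0.0], [0.0]], 40, seed=seed)
            model = fit_lda(df, "label", feature_columns=cols)
            hits += model.n_significant > 0
        assert hits <= 8  # alpha = 0.05: >= 90% of null fits non-significant

    def test_function_count_rank_bound(self, twin_features):
        model = fit_lda(twin_features, "animal_id")
        assert model.loadings.shape[1] <= min(17 - 1, 13)
        assert model.percent_variance.sum() <= 100 + 1e-9

    def test_within_class_variance_is_one(self):
        df, cols = _gaussian_classes([[0.0, 2.0], [3.0, 0.0], [0.0, -2.0]], 80, seed=5)
        model = fit_lda(df, "label", feature_columns=cols)
        Z = (df[cols].to_numpy() - model.center) / model.scale
        proj = Z @ model.loadings
        codes = pd.factorize(df["label"])[0]
        resid = proj - np.stack([proj[codes == c].mean(0) for c in range(3)])[codes]
        n, k = len(df), 3
        within_var = (resid**2).sum(0) / (n - k)
        assert np.allclose(within_var, 1.0, atol=1e-8)

    def test_agrees_with_sklearn_oracle(self):
        """Predictions match sklearn's LDA (independent implementation)
        on a well-separated problem."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        df, cols = _gaussian_classes(
            [[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]], 60, seed=8
        )
        model = fit_lda(df, "label", feature_columns=cols)
        ours = predict_lda(model, df)
        sk = LinearDiscriminantAnalysis().fit(df[cols], df["label"]).predict(df[cols])
        assert np.mean(ours == sk) > 0.98


class TestCrossValidate:
    def test_signatures_beat_chance(self, twin_features):
        bal = balance_notes(twin_features, 20, seed=0)
        cv = cross_validate(bal, "animal_id", n_iter=40, seed=1)
        assert cv.percent_correct > chance_level(17) + 5 * cv.standard_error

    def test_shuffled_labels_near_chance(self, twin_features):
        rng = default_rng(4)
        bal = balance_notes(twin_features, 20, seed=0)
        sh = bal.copy()
        sh["animal_id"] = rng.permutation(sh["animal_id"].to_numpy())
        sizes = sh.groupby("animal_id").size()
        sh = sh.groupby("animal_id").head(sizes.min())
        cv = cross_validate(sh, "animal_id", n_train=sizes.min() - 1, n_iter=40, seed=2)
        assert abs(cv.percent_correct - chance_level(17)) < 3 * max(
            cv.standard_error, 1.0
        )

    def test_deterministic_under_seed(self, twin_features):
        bal = balance_notes(twin_features, 20, seed=0)
        c1 = cross_validate(bal, "animal_id", n_iter=5, seed=3)
        c2 = cross_validate(bal, "animal_id", n_iter=5, seed=3)
        assert np.array_equal(c1.per_iteration, c2.per_iteration)
        assert c1.cumulative[0] == c2.cumulative[0]

    def test_se_shrinks_with_iterations(self, twin_features):
        bal = balance_notes(twin_features, 20, seed=0)
        c_small = cross_validate(bal, "animal_id", n_iter=10, seed=5)
        c_big = cross_validate(bal, "animal_id", n_iter=90, seed=5)
        assert c_big.standard_error < c_small.standard_error

    def test_insufficient_notes_error(self, twin_features):
        small = twin_features.groupby("animal_id").head(10)
        with pytest.raises(ValueError):
            cross_validate(small, "animal_id", n_iter=2, seed=0)


class TestChance:
    @pytest.mark.parametrize(
        "k,expected,rounded",
        [(17, 100 / 17, 6), (2, 50.0, 50), (4, 25.0, 25)],
    )
    def test_uniform_guessing(self, k, expected, rounded):
        assert np.isclose(chance_level(k), expected)
        assert round(chance_level(k)) == rounded


class TestMutualInformation:
    def test_identity_confusion_hits_ceiling(self):
        mi = mutual_information(np.eye(17) * 20, bias_correction=False)
        assert np.isclose(mi.bits, np.log2(17))  # 4.087...

    def test_uniform_confusion_zero(self):
        mi = mutual_information(np.full((5, 5), 10.0), bias_correction=False)
        assert np.isclose(mi.bits, 0.0, atol=1e-12)

    def test_binary_oracle(self):
        # 2 classes, p(correct) = 0.9: MI = 1 - H(0.9) = 0.531 bits
        counts = np.array([[90.0, 10.0], [10.0, 90.0]])
        mi = mutual_information(counts, bias_correction=False)
        h = -(0.9 * np.log2(0.9) + 0.1 * np.log2(0.1))
        assert np.isclose(mi.bits, 1 - h)

    def test_rate_conversion(self):
        counts = np.array([[90.0, 10.0], [10.0, 90.0]])
        mi = mutual_information(counts, bias_correction=False, mean_duration_s=0.069)
        assert np.isclose(mi.bits_per_second, mi.bits / 0.069)

    def test_bounds_on_random_confusions(self):
        rng = default_rng(6)
        for _ in range(50):
            k = rng.integers(2, 12)
            counts = rng.integers(0, 30, size=(k, k)).astype(float)
            counts += np.eye(k)  # ensure every column has mass
            mi = mutual_information(counts, bias_correction=False)
            assert -1e-12 <= mi.bits <= np.log2(k) + 1e-9

    def test_miller_madow_reduces_small_sample_estimate(self):
        rng = default_rng(7)
        counts = rng.integers(0, 4, size=(10, 10)).astype(float) + np.eye(10)
        raw = mutual_information(counts, bias_correction=False)
        corr = mutual_information(counts, bias_correction=True)
        assert corr.bits <= raw.bits

    def test_percent_correct_identity(self):
        counts = np.array([[3.0, 1.0], [1.0, 3.0]])
        cm = ConfusionMatrix(["a", "b"], counts)
        assert np.isclose(cm.percent_correct, 75.0)
        assert np.allclose(cm.p_conditional.sum(axis=0), 1.0)
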