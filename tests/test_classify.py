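import numpy as np
import pytest
from scipy import stats

import tivcompare as tc
from tivcompare.classify import (
    ClassificationError,
    ClassifierSpec,
    accuracy_profiles,
    default_specs,
)


def gaussian_classes(n=60, p=4, delta=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n, p)), rng.normal(delta / np.sqrt(p), 1, (n, p))])
    y = np.array(["F"] * n + ["M"] * n, dtype=object)
    return X, y


class TestKnnRule:
    @pytest.mark.parametrize("n, k", [(622, 25), (100, 10), (1, 1), (2, 1)])
    def test_values(self, n, k):
        assert tc.knn_k_rule(n) == k


class TestStandardizer:
    def test_fit_sample_is_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        X = rng.normal(5, 3, (40, 6))
        z, st_ = tc.standardize(X, X)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1, rtol=1e-12)

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            z, st_ = tc.standardize(X, X)
        assert z.shape[1] == 2

    def test_no_refit_on_transform(self):
        rng = np.random.default_rng(4)
        train = rng.normal(0, 1, (50, 3))
        test = rng.normal(1.5, 1, (50, 3))
        st_ = tc.FeatureStandardizer().fit(train)
        z_test = st_.transform(test)
        assert np.abs(z_test.mean(axis=0)).min() > 0.5  # shifted, not re-centred

    def test_all_constant_rejected(self):
        with pytest.raises(ClassificationError):
            tc.standardize(np.ones((10, 2)), np.ones((10, 2)))


class TestSvmTuning:
    def test_single_point_grid(self):
        X, y = gaussian_classes()
        c, g, acc = tc.tune_svm(X, y, "rbf", (1.0,), (0.1,), cv=5)
        assert (c, g) == (1.0, 0.1)

    def test_separable_data_reaches_perfect_cv(self):
        X, y = gaussian_classes(delta=10)
        c, g, acc = tc.tune_svm(X, y, "linear", (0.1, 1, 10), (0.1,), cv=5)
        assert acc == 1.0

    def test_tie_break_prefers_smaller_c(self):
        X, y = gaussian_classes(delta=10)
        c, g, acc = tc.tune_svm(X, y, "linear", (10, 0.5, 1), (0.1,), cv=5)
        assert c == 0.5  # all attain 100%: smallest C wins


class TestEvaluate:
    def test_all_correct(self):
        out = tc.evaluate(["M", "F"] * 10, ["M", "F"] * 10)
        assert out["accuracy"] == 100.0
        assert out["kappa"] == pytest.approx(1.0)

    def test_constant_prediction_on_balanced_labels(self):
        actual = np.array(["M"] * 20 + ["F"] * 20)
        out = tc.evaluate(np.array(["M"] * 40), actual)
        assert out["accuracy"] == 50.0
        assert out["kappa"] == pytest.approx(0.0)

    def test_exact_binomial_ci(self):
        out = tc.evaluate(
            np.r_[np.ones(200), np.zeros(66)], np.ones(266)
        )
        assert out["accuracy"] == pytest.approx(100 * 200 / 266, abs=1e-10)
        ci = stats.binomtest(200, 266).proportion_ci(method="exact")
        assert out["acc_lo"] == pytest.approx(100 * ci.low)
        assert out["acc_hi"] == pytest.approx(100 * ci.high)

    def test_kappa_is_two_acc_minus_one_when_balanced(self, classification_run):
        results, _ = classification_run
        sub = results[results["subsample"] == "test"]
        np.testing.assert_allclose(
            sub["kappa"], 2 * sub["accuracy"] / 100 - 1, atol=1e-10
        )


class TestFitPredict:
    @pytest.mark.parametrize("name", tc.classify.CLASSIFIER_NAMES)
    def test_separable_classes_learned_by_every_classifier(self, name):
        X, y = gaussian_classes(n=60, p=4, delta=6)
        Xt, yt = gaussian_classes(n=40, p=4, delta=6, seed=99)
        hyper = {}
        if name.startswith("SVM"):
            hyper = {"c_grid": (1.0,), "gamma_grid": (0.1,), "cv": 5}
        elif name == "LR_EN":
            hyper = {"cv": 5, "Cs": 3}
        preds = tc.fit_predict(ClassifierSpec(name, hyper), X, y, {"test": Xt}, seed=0)
        assert (preds["test"] == yt).mean() > 0.95

    def test_permuted_labels_score_at_chance(self):
        rng = np.random.default_rng(8)
        X, y = gaussian_classes(n=100, p=4, delta=6)
        y_perm = rng.permutation(y)
        Xt, yt = gaussian_classes(n=200, p=4, delta=6, seed=5)
        accs = []
        for name in ("LDA", "KNN", "TREE"):
            preds = tc.fit_predict(ClassifierSpec(name), X, y_perm, {"t": Xt}, seed=0)
            accs.append((preds["t"] == rng.permutation(yt)).mean())
        for acc in accs:
            assert abs(acc - 0.5) < 0.12  # ~3 binomial sds at n=400

    def test_unbalanced_training_rejected(self):
        X, y = gaussian_classes(n=30)
        with pytest.raises(ClassificationError, match="balanced"):
            tc.fit_predict(ClassifierSpec("LDA"), X[:-3], y[:-3], {})

    def test_qda_singular_error_advises_regularization(self):
        X, y = gaussian_classes(n=5, p=10, delta=6)
        with pytest.raises(ClassificationError, match="reg_param"):
            tc.fit_predict(ClassifierSpec("QDA"), X, y, {})


class TestRunSuite:
    def test_shape_and_determinism(self, classification_run):
        results, _ = classification_run
        assert len(results) == 6 * 6 * 3  # classifiers x datasets x subsamples
        assert set(results["subsample"]) == {"train", "test", "external"}
        assert results["accuracy"].between(0, 100).all()
        assert results["kappa"].between(-1, 1).all()

    def test_training_accuracy_exceeds_test_on_average(self, classification_run):
        results, _ = classification_run
        prof = results.pivot_table(index="subsample", values="accuracy", aggfunc="mean")
        assert prof.loc["train", "accuracy"] > prof.loc["test", "accuracy"]

    def test_raw_beats_residuals_on_test(self, classification_run):
        results, _ = classification_run
        prof = accuracy_profiles(results, "test")
        assert prof.loc["raw"].mean() > prof.loc["residuals"].mean()

    def test_per_subsample_standardization_flag(self):
        rng = np.random.default_rng(6)
        X = {"train": rng.normal(0, 1, (40, 3)), "test": rng.normal(2, 1, (30, 3))}
        y = {"train": np.array(["F", "M"] * 20), "test": np.array(["F", "M"] * 15)}
        res = tc.run_suite({"a": X}, y, [ClassifierSpec("LDA")],
                           standardize_per_subsample=True)
        assert len(res) == 2  # runs; the shifted test set is re-centred internally

    def test_dataset_ordering_matches_expected_ranks(self, classification_run):
        """External accuracy ordering: tiv/raw > scaling/proportions > pcp/residuals."""
        results, _ = classification_run
        prof = accuracy_profiles(results, "external").mean(axis=1)
        expected = {"tiv": 5.5, "raw": 5.5, "scaling_surrogate": 3.5,
                    "proportions": 3.5, "pcp": 1.5, "residuals": 1.5}
        rho, _ = stats.spearmanr(prof.to_numpy(), [expected[k] for k in prof.index])
        assert rho > 0.8


class TestClustering:
    def test_two_tight_groups_recovered(self):
        import pandas as pd

        profiles = pd.DataFrame(
            [[90, 91, 92], [91, 92, 90], [60, 61, 59], [59, 60, 61]],
            index=["a", "b", "c", "d"],
        )
        sol = tc.pam_cluster(profiles)
        assert sol.K == 2
        assert sol.labels["a"] == sol.labels["b"] != sol.labels["c"] == sol.labels["d"]
        assert sol.separation_ratio > 5

    def test_identical_profiles_flagged_degenerate(self):
        import pandas as pd

        profiles = pd.DataFrame([[1.0, 2.0]] * 4, index=list("abcd"))
        sol = tc.pam_cluster(profiles)
        assert sol.degenerate
        assert np.isnan(sol.average_silhouette)

    def test_two_datasets_single_merge(self):
        import pandas as pd

        profiles = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        order, heights, _ = tc.hierarchical_order(profiles)
        assert sorted(order) == ["a", "b"]
        np.testing.assert_allclose(heights, [5.0])

    def test_merge_heights_monotone(self, classification_run):
        results, _ = classification_run
        prof = accuracy_profiles(results, "test")
        _, heights, _ = tc.hierarchical_order(prof)
        assert (np.diff(heights) >= -1e-12).all()
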