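import numpy as np
import pytest

import tivcompare as tc
from tivcompare.adjustment import AdjustmentError, AdjustmentParams


def power_law_cohort(b=0.8, c=0.02, n=40, seed=0):
    """Noise-free V = c * TIV**b for one region."""
    rng = np.random.default_rng(seed)
    tiv = rng.uniform(1200, 1700, n)
    return tc.CohortTable(
        subject_id=np.array([f"s{i}" for i in range(n)]),
        sex=np.array(["F", "M"] * (n // 2), dtype=object),
        tiv=tiv,
        volumes=(c * tiv**b)[:, None],
        region_names=["r1"],
    )


class TestProportions:
    def test_hand_value(self, tiny_cohort):
        adj = tc.proportions_adjust(tiny_cohort)
        assert adj.values[0, 0] == pytest.approx(10.0 / 1200.0)

    def test_identical_tiv_preserves_d(self, tiny_cohort):
        flat = tc.CohortTable(
            tiny_cohort.subject_id, tiny_cohort.sex,
            np.full(6, 1400.0), tiny_cohort.volumes, tiny_cohort.region_names,
        )
        raw_d = tc.effect_table(tc.adjust(flat, "raw"))["d"]
        prop_d = tc.effect_table(tc.proportions_adjust(flat))["d"]
        np.testing.assert_allclose(prop_d, raw_d, rtol=1e-10)


class TestPCP:
    def test_noise_free_exponent_recovered_exactly(self):
        params = tc.pcp_fit(power_law_cohort(b=0.8))
        assert params.slopes[0] == pytest.approx(0.8, abs=1e-12)

    def test_constant_volume_gives_zero_slope(self):
        cohort = power_law_cohort(b=0.8)
        flat = tc.CohortTable(
            cohort.subject_id, cohort.sex, cohort.tiv,
            np.full_like(cohort.volumes, 7.5), cohort.region_names,
        )
        assert tc.pcp_fit(flat).slopes[0] == pytest.approx(0.0, abs=1e-14)

    def test_apply_cancels_power_law_exactly(self):
        cohort = power_law_cohort(b=0.8, c=0.02)
        adj = tc.pcp_apply(cohort, tc.pcp_fit(cohort))
        np.testing.assert_allclose(adj.values, 0.02, rtol=1e-10)

    def test_b_zero_is_identity_and_b_one_is_proportions(self, tiny_cohort):
        p0 = AdjustmentParams("pcp", slopes=np.zeros(2))
        np.testing.assert_allclose(
            tc.pcp_apply(tiny_cohort, p0).values, tiny_cohort.volumes, rtol=1e-12
        )
        p1 = AdjustmentParams("pcp", slopes=np.ones(2))
        np.testing.assert_allclose(
            tc.pcp_apply(tiny_cohort, p1).values,
            tc.proportions_adjust(tiny_cohort).values,
            rtol=1e-12,
        )

    def test_fitted_exponent_within_3_se_on_noisy_data(self):
        cfg = tc.GeneratorConfig(
            n_female=400, n_male=400, n_regions=1,
            allometric_exponent_range=(0.6, 0.6),
            noise_sd_range=(0.05, 0.05), sex_effect_sd=0.0, seed=6,
        )
        cohort = tc.generate_cohort(cfg)
        b_hat = tc.pcp_fit(cohort).slopes[0]
        # OLS se of the slope on the log-log scale
        log_t = np.log(cohort.tiv)
        se = 0.05 / (np.std(log_t) * np.sqrt(len(log_t)))
        assert abs(b_hat - 0.6) < 3 * se


class TestResiduals:
    def test_hand_example(self):
        cohort = tc.CohortTable(
            subject_id=np.array(["a", "b", "c"]),
            sex=np.array(["F", "M", "M"], dtype=object),
            tiv=np.array([1.0, 2.0, 3.0]),
            volumes=np.array([[2.0], [4.0], [6.0]]),
            region_names=["r1"],
        )
        params = tc.residuals_fit(cohort)
        assert params.slopes[0] == pytest.approx(2.0)
        assert params.tiv_mean == pytest.approx(2.0)
        adj = tc.residuals_apply(cohort, params)
        np.testing.assert_allclose(adj.values[:, 0], [4.0, 4.0, 4.0], rtol=1e-12)

    def test_orthogonality_and_mean_preservation(self, full_cohort):
        adj = tc.adjust(full_cohort, "residuals")
        reg = tc.tiv_regressions(adj)
        scale = np.abs(full_cohort.volumes).mean()
        assert np.abs(reg["slope"]).max() < 1e-10 * scale
        np.testing.assert_allclose(
            adj.values.mean(axis=0), full_cohort.volumes.mean(axis=0), rtol=1e-12
        )

    def test_uncorrelated_volume_left_untouched(self):
        rng = np.random.default_rng(0)
        n = 2000
        tiv = rng.uniform(1200, 1700, n)
        vol = np.full((n, 1), 9.0)
        cohort = tc.CohortTable(
            np.arange(n).astype(str), np.array(["F", "M"] * (n // 2), dtype=object),
            tiv, vol, ["r1"],
        )
        adj = tc.residuals_apply(cohort, tc.residuals_fit(cohort))
        np.testing.assert_allclose(adj.values, 9.0, rtol=1e-12)


class TestDispatch:
    def test_raw_is_identity(self, tiny_cohort):
        np.testing.assert_array_equal(tc.adjust(tiny_cohort, "raw").values, tiny_cohort.volumes)

    def test_fit_on_train_reused_for_test(self, full_cohort):
        split = tc.split_cohort(full_cohort, (0.7,), seed=0)
        train = full_cohort.subset(split.train_ids)
        test = full_cohort.subset(split.test_ids)
        adj_test = tc.adjust(test, "pcp", fit_cohort=train)
        np.testing.assert_array_equal(adj_test.params.slopes, tc.pcp_fit(train).slopes)

    def test_unknown_method_rejected(self, tiny_cohort):
        with pytest.raises(AdjustmentError, match="unknown"):
            tc.adjust(tiny_cohort, "ancova")

    def test_method_mismatch_rejected(self, tiny_cohort):
        with pytest.raises(AdjustmentError, match="pcp"):
            tc.pcp_apply(tiny_cohort, tc.residuals_fit(tiny_cohort))

    def test_sex_stratified_fit_uses_per_sex_slopes(self, full_cohort):
        params = tc.pcp_fit(full_cohort, by_sex=True)
        assert set(params.slopes_by_sex) == {"F", "M"}
        adj = tc.pcp_apply(full_cohort, params)
        # females adjusted with the female slope only
        f = full_cohort.mask("F")
        expected = full_cohort.volumes[f] / (
            full_cohort.tiv[f, None] ** params.slopes_by_sex["F"][None, :]
        )
        np.testing.assert_allclose(adj.values[f], expected, rtol=1e-12)

    def test_params_json_round_trip(self, tiny_cohort):
        params = tc.residuals_fit(tiny_cohort)
        back = AdjustmentParams.from_json(params.to_json())
        assert back.method == "residuals"
        assert back.tiv_mean == params.tiv_mean
        np.testing.assert_allclose(back.slopes, params.slopes, rtol=1e-15)


class TestTivDependenceOrdering:
    def test_proportions_inverts_when_b_below_one(self):
        """With b < 1 dividing by TIV over-corrects: adjusted volumes fall with TIV."""
        cfg = tc.GeneratorConfig(
            n_female=300, n_male=300, n_regions=8,
            allometric_exponent_range=(0.5, 0.8),
            noise_sd_range=(0.03, 0.06), sex_effect_sd=0.0, seed=12,
        )
        cohort = tc.generate_cohort(cfg)
        prop = tc.tiv_regressions(tc.adjust(cohort, "proportions"))
        assert (prop["slope"] < 0).all()
        for method in ("pcp", "residuals"):
            reg = tc.tiv_regressions(tc.adjust(cohort, method))
            assert (reg["r2"] < 0.01).all()

    def test_mean_abs_slope_ordering(self, full_cohort):
        slopes = {
            m: np.abs(tc.tiv_regressions(tc.adjust(full_cohort, m))["slope"]).mean()
            for m in ("raw", "scaling_surrogate", "pcp", "residuals")
        }
        assert slopes["raw"] > slopes["scaling_surrogate"]
        assert slopes["scaling_surrogate"] > 10 * slopes["pcp"]
        assert slopes["scaling_surrogate"] > 10 * slopes["residuals"]
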