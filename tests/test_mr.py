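import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitdmr.genetics import default_panel
from vitdmr.mr import (
    OneSampleMR,
    WaldRatioResult,
    egger_regression,
    f_statistic,
    grs_iv_wald,
    ivw_pool,
    two_stage_estimate,
    wald_ratio,
)
from vitdmr.regression import AssociationEstimate
from vitdmr.simulate import SimulationConfig, generate_cohort


class TestFStatistic:
    @pytest.mark.parametrize(
        "r2, n, expected",
        [(0.0, 100, 0.0), (0.5, 4, 2.0), (0.01, 1002, 0.01 * 1000 / 0.99)],
    )
    def test_closed_form(self, r2, n, expected):
        result = f_statistic(r2, n)
        assert result.f_statistic == pytest.approx(expected, abs=1e-9)

    def test_usable_threshold(self):
        assert f_statistic(0.01, 1002).usable_instrument  # F = 10.101 > 10
        assert not f_statistic(0.001, 1002).usable_instrument

    @pytest.mark.parametrize("r2, n", [(1.0, 100), (-0.1, 100), (0.5, 2)])
    def test_invalid_inputs_rejected(self, r2, n):
        with pytest.raises(ValueError):
            f_statistic(r2, n)


def _est(beta, se, label=""):
    return AssociationEstimate(beta=beta, se=se, label=label)


class TestWaldRatio:
    def test_simple_ratio(self):
        assert wald_ratio(_est(0.1, 0.05), _est(2.0, 0.2)).beta_iv == pytest.approx(0.05)

    def test_null_numerator(self):
        res = wald_ratio(_est(0.0, 0.1), _est(2.94, 0.3))
        assert res.beta_iv == 0.0
        assert res.se_iv == pytest.approx(0.1 / 2.94, abs=1e-12)

    def test_delta_method_se(self):
        # sqrt(0.05^2/2^2 + 0.1^2 * 0.2^2 / 2^4) = sqrt(0.000625 + 0.000025)
        res = wald_ratio(_est(0.1, 0.05), _est(2.0, 0.2))
        assert res.se_iv == pytest.approx(math.sqrt(0.00065), abs=1e-9)
        assert res.se_iv == pytest.approx(0.0254951, abs=1e-6)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(_est(0.1, 0.05), _est(0.0, 0.2))

    def test_mismatched_snps_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            wald_ratio(_est(0.1, 0.05, "rs1"), _est(2.0, 0.2, "rs2"))

    def test_variance_weight_is_inverse_variance(self):
        res = wald_ratio(_est(0.1, 0.05), _est(2.0, 0.2))
        assert res.variance_weight == pytest.approx(1 / res.se_iv**2)


class TestIvwPool:
    def test_single_ratio_is_identity(self):
        ratio = WaldRatioResult("rs1", 0.12, 0.03)
        pooled = ivw_pool([ratio])
        assert pooled.pooled_beta == pytest.approx(0.12)
        assert pooled.pooled_se == pytest.approx(0.03)

    def test_equal_weights(self):
        ratios = [WaldRatioResult("a", 0.1, 0.1), WaldRatioResult("b", 0.3, 0.1)]
        pooled = ivw_pool(ratios)
        assert pooled.pooled_beta == pytest.approx(0.2)
        assert pooled.pooled_se == pytest.approx(0.1 / math.sqrt(2), abs=1e-9)
        assert pooled.pooled_se == pytest.approx(0.070711, abs=1e-6)

    def test_unequal_weights_hand_computed(self):
        ratios = [WaldRatioResult("a", 0.1, 0.1), WaldRatioResult("b", 0.3, 0.2)]
        pooled = ivw_pool(ratios)  # (0.1/0.01 + 0.3/0.04) / (100 + 25)
        assert pooled.pooled_beta == pytest.approx(0.14, abs=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ivw_pool([])

    def test_identical_ratios_shrink_se_by_sqrt_k(self):
        k = 7
        ratios = [WaldRatioResult(f"s{i}", 0.2, 0.05) for i in range(k)]
        pooled = ivw_pool(ratios)
        assert pooled.pooled_beta == pytest.approx(0.2)
        assert pooled.pooled_se == pytest.approx(0.05 / math.sqrt(k), abs=1e-12)

    @given(
        betas=st.lists(st.floats(min_value=-1, max_value=1), min_size=1, max_size=6),
        seed=st.integers(min_value=0, max_value=1000),
    )
    @settings(deadline=None, max_examples=50)
    def test_matches_brute_force_weighted_mean(self, betas, seed):
        rng = np.random.default_rng(seed)
        ses = rng.uniform(0.01, 1.0, size=len(betas))
        ratios = [WaldRatioResult(f"s{i}", b, s) for i, (b, s) in enumerate(zip(betas, ses))]
        pooled = ivw_pool(ratios)
        # independent accumulation loop
        num = den = 0.0
        for b, s in zip(betas, ses):
            w = 1.0 / s**2
            num += w * b
            den += w
        assert pooled.pooled_beta == pytest.approx(num / den, abs=1e-12)
        assert min(betas) - 1e-12 <= pooled.pooled_beta <= max(betas) + 1e-12
        assert pooled.pooled_se <= min(ses) + 1e-12


class TestEggerRegression:
    def test_exact_line_recovered(self):
        bzx = np.array([1.0, 2.0, 3.0, 4.0])
        bzy = 0.02 + 0.05 * bzx
        res = egger_regression(bzx, bzy, np.full(4, 0.1))
        assert res.intercept == pytest.approx(0.02, abs=1e-10)
        assert res.slope == pytest.approx(0.05, abs=1e-10)

    def test_no_pleiotropy_zero_intercept(self):
        bzx = np.array([0.5, 1.0, 2.0, 3.5])
        res = egger_regression(bzx, 0.05 * bzx, np.full(4, 0.1))
        assert res.intercept == pytest.approx(0.0, abs=1e-10)

    def test_fewer_than_three_snps_undefined(self):
        res = egger_regression([1.0, 2.0], [0.1, 0.2], [0.1, 0.1])
        assert not res.defined
        assert np.isnan(res.intercept)

    def test_negative_beta_zx_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            egger_regression([1.0, -2.0, 3.0], [0.1, 0.2, 0.3], [0.1, 0.1, 0.1])

    def test_intercept_p_uses_t_reference_with_two_df(self):
        from scipy.stats import t as t_dist

        rng = np.random.default_rng(3)
        bzx = np.array([1.0, 1.5, 2.5, 3.0])
        bzy = 0.01 + 0.04 * bzx + rng.normal(0, 0.01, 4)
        res = egger_regression(bzx, bzy, np.full(4, 0.1))
        expected_p = 2 * t_dist.sf(abs(res.intercept / res.intercept_se), df=2)
        assert res.intercept_p == pytest.approx(expected_p, rel=1e-9)


class TestGrsIvWald:
    def test_null_or_zy_maps_to_null(self):
        assert grs_iv_wald(1.0, 12.5).or_iv == pytest.approx(1.0)

    def test_closed_form_decrease(self):
        # exp(-25 * ln(0.95) / 12.5) = exp(2 * 0.051293) = 1.10803
        assert grs_iv_wald(0.95, 12.5).or_iv == pytest.approx(1.108033, abs=1e-5)

    def test_closed_form_with_decreasing_score(self):
        assert grs_iv_wald(1.07, -17.756).or_iv == pytest.approx(1.1000, abs=1e-4)

    def test_reciprocal_symmetry(self):
        up = grs_iv_wald(1.3, 8.0, direction="increase").or_iv
        down = grs_iv_wald(1.3, 8.0, direction="decrease").or_iv
        assert up * down == pytest.approx(1.0, abs=1e-12)

    def test_ci_is_transformed_and_ordered(self):
        res = grs_iv_wald(0.95, 12.5, or_zy_ci=(0.90, 1.00))
        lo, hi = res.ci95
        assert lo <= res.or_iv <= hi
        assert lo == pytest.approx(math.exp(-25 * math.log(1.00) / 12.5))
        assert hi == pytest.approx(math.exp(-25 * math.log(0.90) / 12.5))

    @pytest.mark.parametrize("or_zy, beta", [(0.0, 1.0), (-1.0, 1.0), (1.1, 0.0)])
    def test_invalid_inputs_rejected(self, or_zy, beta):
        with pytest.raises(ValueError):
            grs_iv_wald(or_zy, beta)


class TestTwoStage:
    def test_null_effect_ci_covers_one(self):
        config = SimulationConfig(
            n_individuals=20_000, causal_log_or_per_nmol=0.0, seed=101
        )
        cohort = generate_cohort(config)
        res = two_stage_estimate(cohort, default_panel(), "outcome")
        lo, hi = res.ci95
        assert lo < 1.0 < hi

    def test_agrees_with_wald_type_on_same_cohort(self):
        from vitdmr.genetics import compute_grs
        from vitdmr.regression import build_design, linear_fit, logistic_fit

        cohort = generate_cohort(SimulationConfig(n_individuals=50_000, seed=103))
        panel = default_panel()
        ts = two_stage_estimate(cohort, panel, "outcome")
        grs = compute_grs(cohort, panel, "vitd_decreasing")
        X = build_design(cohort.assign(_grs=grs), ["_grs"])
        or_zy = logistic_fit(cohort["outcome"].to_numpy(dtype=float), X).estimate("_grs")
        beta = linear_fit(cohort["vitd_nmol_l"], X).params["_grs"]
        wt = grs_iv_wald(or_zy, beta)
        assert ts.or_iv == pytest.approx(wt.or_iv, rel=0.02)

    def test_weak_instrument_flagged_not_raised(self):
        config = SimulationConfig(
            n_individuals=2_000, vitd_noise_sd=60.0, seed=105
        )
        cohort = generate_cohort(config)
        res = two_stage_estimate(cohort, default_panel().subset("metabolism"), "outcome")
        assert res.weak_instrument
        assert res.instrument.f_statistic <= 10

    def test_confidence_interval_coverage(self):
        """The two-stage 95% CI covers the true causal OR in most replicates."""
        n_reps, covered = 200, 0
        truth = np.exp(0.1)
        for i in range(n_reps):
            config = SimulationConfig(
                n_individuals=10_000, causal_log_or_per_nmol=-0.004, seed=40_000 + i
            )
            cohort = generate_cohort(config)
            lo, hi = two_stage_estimate(cohort, default_panel(), "outcome").ci95
            covered += lo <= truth <= hi
        assert covered >= 0.90 * n_reps


class TestOneSampleMRModel:
    @pytest.fixture(scope="class")
    def results(self, phenotyped_cohort):
        data = phenotyped_cohort.assign(outcome=phenotyped_cohort["outcome"].astype(float))
        return OneSampleMR(data, "outcome").fit()

    def test_all_panels_and_estimators_present(self, results):
        assert set(results.grs_results) == {"synthesis", "metabolism", "combined"}
        for by_est in results.grs_results.values():
            assert set(by_est) == {"wald_type", "two_stage"}
            for r in by_est.values():
                assert r.or_iv > 0

    def test_per_snp_estimates_and_ivw(self, results):
        assert len(results.snp_associations) == 4
        ratios = [a.wald.beta_iv for a in results.snp_associations]
        assert min(ratios) <= results.ivw.pooled_beta <= max(ratios)
        assert results.ivw.pooled_se <= min(a.wald.se_iv for a in results.snp_associations)

    def test_summary_mentions_key_quantities(self, results):
        text = results.summary()
        assert "IVW" in text and "MR-Egger" in text and "GRS_synthesis" in text
        assert "rs12785878" in text

    def test_frames_are_tidy(self, results):
        snp = results.snp_frame()
        assert set(snp["rsid"]) == {"rs12785878", "rs10741657", "rs2282679", "rs6013897"}
        grs = results.grs_frame()
        assert len(grs) == 6  # 3 panels x 2 estimators
        assert (grs["or_iv"] > 0).all()

    def test_missing_column_rejected(self, phenotyped_cohort):
        with pytest.raises(KeyError):
            OneSampleMR(phenotyped_cohort.drop(columns=["snp_rs2282679"]), "outcome")
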