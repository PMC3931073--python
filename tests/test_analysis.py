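import math

import numpy as np
import pandas as pd
import pytest

from myokin import analysis as an


def hyperbola(c, kmax, khalf):
    return kmax * c / (c + khalf)


GRID = np.array([5.0, 10.0, 25.0, 50.0, 100.0, 150.0, 250.0, 400.0])


class TestHyperbola:
    def test_noiseless_series_recovered_exactly(self):
        series = an.KobsSeries("ATP", GRID, hyperbola(GRID, 88.0, 93.0))
        fit = an.fit_hyperbola(series)
        assert fit.k_max == pytest.approx(88.0, rel=1e-8)
        assert fit.k_half == pytest.approx(93.0, rel=1e-8)

    def test_initial_slope_is_derived_ratio(self):
        series = an.KobsSeries("ATP", GRID, hyperbola(GRID, 88.0, 93.0))
        fit = an.fit_hyperbola(series)
        assert fit.initial_slope == pytest.approx(fit.k_max / fit.k_half,
                                                  rel=1e-12)
        assert fit.initial_slope == pytest.approx(0.946, abs=5e-4)

    def test_constant_series_raises(self):
        series = an.KobsSeries("ATP", GRID, np.full(GRID.size, 50.0))
        with pytest.raises(an.SaturationError):
            an.fit_hyperbola(series)

    def test_no_saturation_in_range_raises(self):
        c = np.array([1.0, 2.0, 4.0, 8.0, 16.0])  # max << K_half
        series = an.KobsSeries("ATP", c, hyperbola(c, 100.0, 500.0))
        with pytest.raises(an.SaturationError, match="saturation"):
            an.fit_hyperbola(series)

    def test_kmax_not_below_largest_observation_on_noiseless_data(self):
        series = an.KobsSeries("ATP", GRID, hyperbola(GRID, 137.0, 91.0))
        fit = an.fit_hyperbola(series)
        assert fit.k_max >= series.kobs.max() - 2 * fit.se_k_max

    def test_requires_five_points(self):
        with pytest.raises(ValueError):
            an.HyperbolaFitter().fit(GRID[:4], hyperbola(GRID[:4], 88, 93))

    def test_unit_rescaling_invariance(self):
        # rescaling concentrations from uM to nM rescales K_half and the
        # slope consistently and leaves k_max untouched
        series_um = an.KobsSeries("ATP", GRID, hyperbola(GRID, 88.0, 93.0))
        series_nm = an.KobsSeries("ATP", GRID * 1000,
                                  hyperbola(GRID, 88.0, 93.0))
        f_um, f_nm = an.fit_hyperbola(series_um), an.fit_hyperbola(series_nm)
        assert f_nm.k_max == pytest.approx(f_um.k_max, rel=1e-8)
        assert f_nm.k_half == pytest.approx(1000 * f_um.k_half, rel=1e-8)
        assert f_nm.initial_slope == pytest.approx(f_um.initial_slope / 1000,
                                                   rel=1e-8)


class TestLinearLowConc:
    def test_points_on_line_recover_slope(self):
        c = np.array([2.0, 5.0, 10.0, 15.0])
        series = an.KobsSeries("ATP", c, 1.5 * c)
        slope, se = an.fit_linear_low_conc(series)
        assert slope == pytest.approx(1.5, rel=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_kobs_gives_zero_slope(self):
        c = np.array([2.0, 5.0, 10.0])
        slope, _ = an.fit_linear_low_conc(an.KobsSeries("ATP", c,
                                                        np.zeros(3)))
        assert slope == 0.0

    def test_truncated_hyperbola_slope_near_kmax_over_khalf(self):
        # the through-origin slope of hyperbolic data underestimates
        # k_max/K_half by roughly (3/4) * c_max/K_half (saturation
        # attenuation): ~15% at the 0.2*K_half cutoff, < 10% at 0.1
        kmax, khalf = 88.0, 93.0
        c = np.linspace(1.0, 400.0, 200)
        series = an.KobsSeries("ATP", c, hyperbola(c, kmax, khalf))
        slope_02, _ = an.fit_linear_low_conc(series, k_half=khalf)
        assert kmax / khalf * 0.8 < slope_02 < kmax / khalf
        slope_01, _ = an.fit_linear_low_conc(series, k_half=0.5 * khalf)
        assert slope_01 == pytest.approx(kmax / khalf, rel=0.10)

    def test_too_few_points_in_regime_raises(self):
        c = np.array([2.0, 50.0, 100.0, 200.0, 400.0])
        series = an.KobsSeries("ATP", c, hyperbola(c, 88.0, 93.0))
        with pytest.raises(ValueError, match="linear regime"):
            an.fit_linear_low_conc(series, k_half=93.0)


class TestAdpCompetition:
    ADP = np.array([0.0, 2.0, 5.0, 10.0, 20.0, 40.0, 80.0])

    def test_noiseless_curve_recovers_affinity(self):
        kobs = 28.0 / (1 + self.ADP / 13.0)
        series = an.KobsSeries("ADP", self.ADP, kobs)
        fit = an.fit_adp_competition(series, atp_conc_um=20.0,
                                     K1k2_prime=1.4)
        assert fit.K_AD == pytest.approx(13.0, rel=1e-8)
        assert fit.k0 == pytest.approx(28.0, rel=1e-8)
        assert fit.predicted_k0 == pytest.approx(28.0, rel=1e-6)

    def test_half_inhibition_at_the_affinity(self):
        est = an.AdpCompetitionFitter().fit(self.ADP,
                                            30.0 / (1 + self.ADP / 13.0))
        assert est.predict(13.0) == pytest.approx(est.k0_ / 2, rel=1e-9)

    def test_single_concentration_has_no_information(self):
        with pytest.raises(ValueError):
            an.AdpCompetitionFitter().fit(np.zeros(6), np.full(6, 28.0))

    def test_increasing_kobs_violates_model(self):
        with pytest.raises(an.ModelViolationError):
            an.AdpCompetitionFitter().fit(self.ADP, 10.0 + self.ADP)


class TestAmplitudeRatio:
    def test_printed_phase_amplitudes_give_conformer_constants(self):
        K_alpha, k_minus = an.k_minus_alpha_from_amplitudes(29.0, 4.7, 85.0)
        assert K_alpha == pytest.approx(6.17, abs=0.01)
        assert k_minus == pytest.approx(13.8, abs=0.05)

    def test_equal_amplitudes(self):
        K_alpha, k_minus = an.k_minus_alpha_from_amplitudes(5.0, 5.0, 49.0)
        assert K_alpha == 1.0
        assert k_minus == 49.0

    def test_vanishing_slow_phase_returns_sentinel(self):
        K_alpha, k_minus = an.k_minus_alpha_from_amplitudes(29.0, 0.0, 85.0)
        assert math.isinf(K_alpha)
        assert k_minus == 0.0


class TestOverallKAD:
    def test_isomer_absent_limit(self):
        assert an.overall_KAD(10.0, 1e12) == pytest.approx(10.0, rel=1e-9)
        assert an.overall_KAD(10.0, 1e12, "reciprocal") == pytest.approx(
            10.0, rel=1e-9)

    @pytest.mark.parametrize("convention", ["partition", "reciprocal"])
    def test_round_trip_with_inverse(self, convention):
        k_ad = an.overall_KAD(12.7, 3.7, convention)
        assert an.overall_KAD(
            an.implied_site_KADP(k_ad, 3.7, convention), 3.7, convention
        ) == pytest.approx(k_ad, rel=1e-12)

    def test_wild_type_pair_under_both_conventions(self):
        # observed overall K_AD = 10 uM with K_alphaD = 3.7: the implied
        # site constant differs between the two candidate algebraic forms
        partition = an.implied_site_KADP(10.0, 3.7, "partition")
        reciprocal = an.implied_site_KADP(10.0, 3.7, "reciprocal")
        assert partition == pytest.approx(10.0 * (1 + 1 / 3.7), rel=1e-12)
        assert reciprocal == pytest.approx(10.0 / (1 + 1 / 3.7), rel=1e-12)
        assert partition > 10.0 > reciprocal


class TestQuadraticTitration:
    GRID_NM = np.array([5.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0,
                        1600.0])

    def amplitudes(self, kd, a0=30.0, scale=34.0):
        return scale * an.bound_fraction_quadratic(self.GRID_NM, a0, kd)

    def test_noiseless_curve_recovers_affinity(self):
        curve = an.TitrationCurve(self.GRID_NM, self.amplitudes(190.0),
                                  a0_nm=30.0)
        fit = an.fit_quadratic_titration(curve)
        assert fit.K_D == pytest.approx(190.0, rel=1e-6)
        assert not fit.tight_binding

    @pytest.mark.parametrize("kd", [1.0, 10.0, 100.0, 1000.0])
    def test_recovery_across_three_decades(self, kd):
        curve = an.TitrationCurve(self.GRID_NM, self.amplitudes(kd),
                                  a0_nm=30.0)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", an.TightBindingWarning)
            fit = an.fit_quadratic_titration(curve)
        assert fit.K_D == pytest.approx(kd, rel=0.01)

    def test_stoichiometric_limit_flags_tight_binding(self):
        # K_D -> 0: amplitude is scale * min(M, A0)/A0, piecewise linear
        amp = 34.0 * np.minimum(self.GRID_NM, 30.0) / 30.0
        curve = an.TitrationCurve(self.GRID_NM, amp, a0_nm=30.0)
        with pytest.warns(an.TightBindingWarning):
            fit = an.fit_quadratic_titration(curve)
        assert fit.tight_binding
        assert fit.K_D < 30.0 / 50.0

    def test_weak_binding_reduces_to_hyperbola(self):
        # A0 = K_D/100: quadratic isotherm within 1% of M/(M + K_D)
        kd, a0 = 500.0, 5.0
        m = np.geomspace(5.0, 5000.0, 50)
        quad = an.bound_fraction_quadratic(m, a0, kd)
        hyp = m / (m + kd)
        assert np.max(np.abs(quad - hyp) / hyp) < 0.01

    def test_root_selection_is_physical(self):
        alpha = an.bound_fraction_quadratic(self.GRID_NM, 30.0, 50.0)
        assert np.all(alpha >= 0)
        assert np.all(alpha * 30.0 <= np.minimum(self.GRID_NM, 30.0) + 1e-9)

    def test_grid_must_bracket_actin_concentration(self):
        with pytest.raises(ValueError, match="bracket"):
            an.TitrationCurve(np.array([40.0, 80.0, 160.0]),
                              np.ones(3), a0_nm=30.0)


class TestAssignFastPhase:
    def test_discussion_numbers_diagnose_binding_limited(self):
        res = an.assign_fast_phase(102.0, 93.0, 1.1)
        assert res.half_max_rate == pytest.approx(51.0)
        assert res.hydrolysis_pred_um == pytest.approx(46.4, abs=0.1)
        assert res.binding_pred_um == pytest.approx(92.7, abs=0.1)
        assert res.diagnosis == "binding-limited"
        assert res.discrimination == pytest.approx(2.0, rel=0.01)
        assert not res.degenerate

    def test_derived_slope_is_flagged_degenerate(self):
        res = an.assign_fast_phase(88.0, 93.0, 88.0 / 93.0)
        assert res.degenerate
        assert res.binding_pred_um == pytest.approx(93.0, rel=1e-9)

    def test_observation_between_predictions_is_indeterminate(self):
        # observed half-max at the geometric mean of the two predictions
        res = an.assign_fast_phase(100.0, 100.0 / (1.1 * math.sqrt(2)), 1.1)
        assert res.diagnosis == "indeterminate"

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            an.assign_fast_phase(0.0, 93.0, 1.1)


class TestDerivedConstants:
    def test_table_style_derivations(self):
        out = an.derive_constants({"K1k2": 1.5, "k_plus2": 160.0,
                                   "k_slow": 14.0})
        assert out.one_over_K1_um == pytest.approx(106.7, abs=0.1)
        assert out.detached_lifetime_ms == pytest.approx(71.4, abs=0.1)

    def test_affinity_ratios(self):
        out = an.derive_constants({"K_A": 17.0, "K_DA": 229.0,
                                   "K_D": 1.0, "K_AD": 10.0})
        assert out.K_DA_over_K_A == pytest.approx(229.0 / 17.0, rel=1e-12)
        assert out.K_AD_over_K_D == pytest.approx(10.0, rel=1e-12)

    def test_missing_primaries_leave_fields_unset(self):
        out = an.derive_constants({"k_slow": 4.0})
        assert out.detached_lifetime_ms == pytest.approx(250.0)
        assert out.one_over_K1_um is None
        assert "one_over_K1_um" not in out.to_dict()


class TestCompareConstructs:
    def test_ratio_of_means_matches_table_convention(self):
        wt = pd.DataFrame({"K_alphaD": [3.5, 3.7, 3.9]})
        mut = pd.DataFrame({"K_alphaD": [7.6, 8.0, 8.4]})
        table = an.compare_constructs(wt, mut)
        assert table.loc["K_alphaD", "ratio_mut_over_wt"] == pytest.approx(
            8.0 / 3.7, rel=1e-9)
        assert table.loc["K_alphaD", "significant"]

    def test_identical_replicates_not_significant(self):
        df = pd.DataFrame({"k": [5.0, 5.0, 5.0]})
        table = an.compare_constructs(df, df.copy())
        assert table.loc["k", "p_value"] == 1.0
        assert table.loc["k", "ratio_mut_over_wt"] == 1.0
        assert not table.loc["k", "significant"]

    def test_single_replicate_reports_ratio_only(self):
        wt = pd.DataFrame({"k": [10.0]})
        mut = pd.DataFrame({"k": [20.0]})
        table = an.compare_constructs(wt, mut)
        assert table.loc["k", "ratio_mut_over_wt"] == 2.0
        assert math.isnan(table.loc["k", "p_value"])

    def test_power_to_detect_isomerisation_change(self):
        # n=3 per group with the summary-table SDs: the 160 -> 102 s^-1
        # change is detectable most of the time, and far more often than
        # a null comparison triggers falsely
        power = an.detection_power(160.0, 23.0, 102.0, 14.0, n=3,
                                   n_sim=1000, seed=1)
        null = an.detection_power(160.0, 23.0, 160.0, 23.0, n=3,
                                  n_sim=1000, seed=2)
        assert power > 0.5
        assert null < 0.15
        assert power > 3 * null
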