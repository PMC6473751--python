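"""Rate laws, velocity extraction, fitting, integrated conversion times."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import stiffsim as ss
from stiffsim import synth
from stiffsim.errors import (
    DesignError,
    FitError,
    InvalidInputError,
    LinearRangeWarning,
)


class TestRateLaws:
    def test_zero_substrate_gives_zero(self, cygggyc):
        assert ss.mm_velocity(cygggyc, 0.0, 3.0) == 0.0

    def test_half_saturation_identity(self, cygggyc):
        v = ss.mm_velocity(cygggyc, cygggyc.K_M, 0.6)
        assert v == pytest.approx(cygggyc.k_cat * 0.6 / 2)

    def test_ldopa_velocity_at_assay_conditions(self, ldopa):
        assert ss.mm_velocity(ldopa, 10.0, 0.6) == pytest.approx(4.70, abs=0.005)

    def test_ltyr_inhibited_velocity_at_assay_conditions(self, ltyr):
        v = ss.mm_inhibited_velocity(ltyr, 10.0, 0.6)
        assert v == pytest.approx(0.351, abs=0.001)

    def test_infinite_Ki_recovers_standard_law(self, cygggyc):
        inhibited = ss.KineticParams(cygggyc.k_cat, cygggyc.K_M, K_i=1e12)
        cs = np.linspace(0.1, 10, 20)
        v_inh = ss.mm_inhibited_velocity(inhibited, cs, 0.6)
        v_std = ss.mm_velocity(cygggyc, cs, 0.6)
        np.testing.assert_allclose(v_inh, v_std, rtol=1e-10)

    def test_inhibition_optimum_is_analytic_argmax(self, ltyr):
        opt = ss.inhibition_optimum(ltyr)
        assert opt == pytest.approx(np.sqrt(0.85 * 19.85), rel=1e-12)
        cs = np.linspace(0.01, 40, 4001)
        v = ss.mm_inhibited_velocity(ltyr, cs, 0.6)
        assert cs[np.argmax(v)] == pytest.approx(opt, abs=0.02)

    def test_negative_concentration_rejected(self, cygggyc):
        with pytest.raises(InvalidInputError):
            ss.mm_velocity(cygggyc, -1.0, 0.6)

    @given(cs=st.floats(0.01, 50.0))
    @settings(derandomize=True, max_examples=60)
    def test_inhibited_never_exceeds_standard(self, cs):
        std = ss.KineticParams(0.93, 0.85)
        inh = ss.KineticParams(0.93, 0.85, K_i=19.85)
        assert ss.mm_inhibited_velocity(inh, cs, 0.6) < ss.mm_velocity(
            std, cs, 0.6)

    @given(cs=st.floats(0.01, 50.0), factor=st.floats(1.01, 3.0))
    @settings(derandomize=True, max_examples=60)
    def test_standard_law_strictly_increasing_concave(self, cs, factor, cygggyc):
        lo = ss.mm_velocity(cygggyc, cs, 0.6)
        mid = ss.mm_velocity(cygggyc, cs * (1 + factor) / 2, 0.6)
        hi = ss.mm_velocity(cygggyc, cs * factor, 0.6)
        assert hi > lo
        assert mid >= (lo + hi) / 2 - 1e-12   # concavity along the chord


class TestLinearLimit:
    def test_linear_in_enzyme(self, cygggyc):
        v1 = ss.linear_limit_velocity(cygggyc, 1.5, 10.0)
        v2 = ss.linear_limit_velocity(cygggyc, 3.0, 10.0)
        assert v2 == pytest.approx(2 * v1)
        assert ss.linear_limit_velocity(cygggyc, 0.0, 10.0) == 0.0

    def test_uninhibited_value(self, cygggyc):
        assert ss.linear_limit_velocity(cygggyc, 3.0, 10.0) == pytest.approx(1.8)

    def test_warns_below_validity_range(self, cygggyc):
        with pytest.warns(LinearRangeWarning):
            ss.linear_limit_velocity(cygggyc, 3.0, 1.0)

    def test_table_constants_justify_linearization(self):
        # every substrate was assayed at 10 mM >= ~10x its K_M
        for p in ss.TABLE_KINETICS.values():
            assert 10.0 / p.K_M >= 9.8


class TestVelocityFromTimecourse:
    def test_linear_signal_slope_times_calibration(self):
        df = synth.generate_timecourse(2e-3, duration_s=300, dt_s=10)
        tc = ss.TimeCourse(df.t_s.values, df.absorbance.values,
                           calibration_uM_per_au=50.0)
        assert ss.velocity_from_timecourse(tc) == pytest.approx(0.1, rel=1e-9)

    def test_constant_signal_has_zero_velocity(self):
        tc = ss.TimeCourse(np.arange(10.0), np.ones(10), 1.0)
        assert ss.velocity_from_timecourse(tc) == pytest.approx(0.0, abs=1e-15)

    def test_saturating_signal_recovers_initial_rate(self):
        # A(t) = A_inf (1 - e^(-t/tau)); initial rate = A_inf / tau
        df = synth.generate_timecourse(1e-3, saturation_au=0.6,
                                       duration_s=600, dt_s=5)
        tc = ss.TimeCourse(df.t_s.values, df.absorbance.values, 1.0)
        v = ss.velocity_from_timecourse(tc)
        assert v == pytest.approx(1e-3, rel=0.05)

    def test_explicit_window(self):
        t = np.arange(20.0)
        y = np.where(t < 10, t, 10 + 5 * (t - 10))   # kink at t = 10
        tc = ss.TimeCourse(t, y, 1.0)
        assert ss.velocity_from_timecourse(tc, window=slice(0, 10)) == \
            pytest.approx(1.0)

    def test_degenerate_times_rejected(self):
        with pytest.raises(InvalidInputError):
            ss.TimeCourse(np.array([1.0, 1.0, 2.0]), np.zeros(3), 1.0)


class TestFitting:
    @pytest.mark.parametrize("name, model", [
        ("cygggyc", "standard"),
        ("l-dopa", "standard"),
        ("l-tyr", "substrate_inhibited"),
    ])
    def test_noiseless_round_trip(self, name, model):
        truth = ss.TABLE_KINETICS[name]
        df = synth.generate_velocity_data(truth, enzyme_uM=0.6, noise_sd=0.0)
        res = ss.fit_kinetics(df, model)
        assert res.params.k_cat == pytest.approx(truth.k_cat, rel=1e-4)
        assert res.params.K_M == pytest.approx(truth.K_M, rel=1e-4)
        if truth.K_i is not None:
            assert res.params.K_i == pytest.approx(truth.K_i, rel=1e-4)
        assert res.rsquared == pytest.approx(1.0, abs=1e-10)

    def test_auto_selects_inhibited_only_when_real(self, ltyr, cygggyc):
        df_inh = synth.generate_velocity_data(ltyr, enzyme_uM=0.6, noise_sd=0)
        df_std = synth.generate_velocity_data(cygggyc, enzyme_uM=0.6, noise_sd=0)
        assert ss.fit_kinetics(df_inh, "auto").model_label == "substrate_inhibited"
        assert ss.fit_kinetics(df_std, "auto").model_label == "standard"

    def test_noisy_recovery_study_is_accurate(self, cygggyc):
        """Median recovered constants over seeded 5%-noise datasets."""
        k_cats, K_Ms = [], []
        for seed in range(20):
            df = synth.generate_velocity_data(
                cygggyc, enzyme_uM=0.6, replicates=3, noise_sd=0.05, seed=seed)
            res = ss.fit_kinetics(df, "standard")
            k_cats.append(res.params.k_cat)
            K_Ms.append(res.params.K_M)
        assert np.median(k_cats) == pytest.approx(cygggyc.k_cat, rel=0.10)
        assert np.median(K_Ms) == pytest.approx(cygggyc.K_M, rel=0.10)

    def test_insufficient_design_rejected(self, cygggyc):
        df = synth.generate_velocity_data(
            cygggyc, substrate_levels_mM=(1.0, 2.0, 4.0), enzyme_uM=0.6)
        with pytest.raises(DesignError):
            ss.fit_kinetics(df, "standard")

    def test_summary_mentions_model_and_r2(self, cygggyc):
        df = synth.generate_velocity_data(cygggyc, enzyme_uM=0.6)
        text = ss.fit_kinetics(df, "standard").summary()
        assert "standard" in text and "R-squared" in text


class TestIntegratedTime:
    def test_vanishing_conversion_limit(self, cygggyc):
        assert ss.integrated_mm_time(cygggyc, 3.0, 10.0, 1e-9) < 1e-2

    def test_zero_order_limit_small_KM(self):
        p = ss.KineticParams(k_cat=0.6, K_M=1e-9)
        t = ss.integrated_mm_time(p, 3.0, 10.0, 0.5)
        assert t == pytest.approx(0.5 * 10.0 / (0.6 * 3.0e-3), rel=1e-6)

    def test_peptide_conversion_takes_about_two_hours(self, cygggyc):
        t = ss.integrated_mm_time(cygggyc, 3.0, 10.0, 0.99)
        assert t == pytest.approx(6.98e3, rel=1e-3)
        assert t / 3600.0 == pytest.approx(2.0, abs=0.1)

    def test_complete_conversion_rejected(self, cygggyc):
        with pytest.raises(InvalidInputError):
            ss.integrated_mm_time(cygggyc, 3.0, 10.0, 1.0)

    @pytest.mark.parametrize("conversion", [0.01, 0.1, 0.5, 0.9, 0.999])
    def test_agrees_with_ode_integration(self, cygggyc, conversion):
        t_closed = ss.integrated_mm_time(cygggyc, 3.0, 10.0, conversion)

        def rhs(t, cs):
            return -cygggyc.k_cat * 3.0e-3 * cs / (cygggyc.K_M + cs)

        sol = solve_ivp(rhs, (0, t_closed), [10.0], rtol=1e-12, atol=1e-14)
        cs_end = sol.y[0, -1]
        assert cs_end == pytest.approx((1 - conversion) * 10.0, rel=1e-6)


class TestConversionSurface:
    def test_hyperbolic_in_enzyme(self, cygggyc):
        df = ss.conversion_time_surface(cygggyc, [0.3, 3.0], [10.0], 0.99)
        t_low = df.loc[df.C_E_uM == 0.3, "t_s"].item()
        t_high = df.loc[df.C_E_uM == 3.0, "t_s"].item()
        assert t_low / t_high == pytest.approx(10.0, rel=1e-12)

    def test_single_cell_equals_integrated_time(self, cygggyc):
        df = ss.conversion_time_surface(cygggyc, [3.0], [10.0], 0.99)
        assert df.t_s.item() == pytest.approx(
            ss.integrated_mm_time(cygggyc, 3.0, 10.0, 0.99), rel=1e-12)

    def test_halving_enzyme_doubles_all_entries(self, cygggyc):
        full = ss.conversion_time_surface(cygggyc, [2.0], [2.0, 5.0, 10.0])
        half = ss.conversion_time_surface(cygggyc, [1.0], [2.0, 5.0, 10.0])
        np.testing.assert_allclose(half.t_s.values, 2 * full.t_s.values,
                                   rtol=1e-12)
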