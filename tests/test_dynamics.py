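"""Forward-model tests: correlation function, spectral density, relaxation
times and the DP/CP/INEPT intensity surfaces."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from ptssnmr.dynamics import (EfficiencyTriplet, ExperimentSettings, MotionModel,
                              RegimeThresholds, RelaxationSet, SpinSegment,
                              classify_regime, correlation_function, cp_intensity,
                              dp_intensity, efficiency_map, efficiency_triplet,
                              inept_intensity, relaxation_parameters,
                              spectral_density)

motion_st = st.builds(
    MotionModel,
    order_parameter=st.floats(0.0, 1.0),
    tau_c=st.floats(1e-12, 1e-3),
    tau_s=st.just(1.0),
)


class TestCorrelationFunction:
    def test_normalized_at_zero(self):
        assert correlation_function(MotionModel(0.0, 1e-9), 0.0) == 1.0

    def test_rigid_limit_no_decay(self):
        m = MotionModel(1.0, 1e-9, tau_s=math.inf)
        for t in (0.0, 1e-9, 1e-3, 10.0):
            assert correlation_function(m, t) == pytest.approx(1.0)

    def test_two_exponential_value(self):
        # frozen from direct evaluation of the two-exponential sum:
        # 0.75*exp(-10) + 0.25*exp(-1e-5)
        m = MotionModel(0.5, 1e-9, 1e-3)
        assert correlation_function(m, 1e-8) == pytest.approx(
            0.25003154995982182, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            correlation_function(MotionModel(0.5, 1e-9), -1e-9)

    @given(motion_st)
    def test_starts_at_one_and_non_increasing(self, m):
        t = np.logspace(-12, 1, 200)
        c = correlation_function(m, t)
        assert correlation_function(m, 0.0) == pytest.approx(1.0)
        assert np.all(np.diff(c) <= 1e-12)


class TestSpectralDensity:
    def test_zero_frequency_single_lorentzian(self):
        m = MotionModel(0.0, 3.7e-9)
        assert spectral_density(m, 0.0) == pytest.approx(0.4 * 3.7e-9, rel=1e-12)

    @given(motion_st, st.floats(1e2, 1e9))
    def test_even_function(self, m, w):
        assert spectral_density(m, w) == pytest.approx(spectral_density(m, -w))

    @given(motion_st)
    def test_non_increasing_in_frequency_magnitude(self, m):
        w = np.logspace(2, 10, 100)
        j = spectral_density(m, w)
        assert np.all(np.diff(j) <= 1e-30)

    def test_matches_cosine_transform_quadrature(self):
        """J(w) equals 0.4x the numeric cosine transform of C(t) to < 1e-6
        relative error on a 100-point random parameter set."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            s = rng.uniform(0.0, 1.0)
            tau_c = 10 ** rng.uniform(-10, -6)
            tau_s = tau_c * 10 ** rng.uniform(0, 2)
            w = 10 ** rng.uniform(-3, 2.4) / tau_s
            m = MotionModel(s, tau_c, tau_s)
            # dimensionless time keeps the quadrature well conditioned
            f = lambda u: correlation_function(m, abs(u) * tau_s)
            val, _ = quad(f, 0, np.inf, weight="cos", wvar=w * tau_s,
                          limlst=400, limit=800, epsabs=1e-12, epsrel=1e-10)
            oracle = 0.4 * tau_s * val
            assert spectral_density(m, w) == pytest.approx(oracle, rel=1e-6)


class TestRelaxationParameters:
    def test_extreme_narrowing_long_t2h(self, ch2, default_settings):
        relax = relaxation_parameters(MotionModel(0.0, 1e-11), ch2, default_settings)
        assert relax.t2_h > 0.1

    def test_rigid_cp_buildup_fast(self, ch2, default_settings):
        relax = relaxation_parameters(MotionModel(1.0, 1e-9, 1.0), ch2, default_settings)
        assert relax.t_ch < default_settings.t_cp / 5
        assert relax.t2_h < default_settings.inept_tau / 10

    def test_isotropic_fast_limits(self, ch2, default_settings):
        s = default_settings
        relax = relaxation_parameters(MotionModel(0.0, 1e-10), ch2, s)
        assert relax.t2_h > 10 * (s.inept_tau + s.inept_tau_prime)
        assert relax.t2_c > 10 * (s.inept_tau + s.inept_tau_prime)
        assert relax.t_ch > 100 * s.t_cp

    def test_t2h_minimum_in_slow_microsecond_regime(self, ch2, default_settings):
        """MAS/motion interference puts the T2H minimum near 1/omega_R."""
        taus = np.logspace(-9, -2, 120)
        t2 = [relaxation_parameters(MotionModel(1.0, t), ch2, default_settings).t2_h
              for t in taus]
        t_min = taus[int(np.argmin(t2))]
        assert 1e-6 <= t_min <= 1e-4

    def test_all_times_positive(self, ch2, default_settings):
        for s in (0.0, 0.1, 1.0):
            for tau in (1e-12, 1e-9, 1e-6, 1e-3):
                r = relaxation_parameters(MotionModel(s, tau), ch2, default_settings)
                assert min(r.t2_h, r.t2_c, r.t1rho_h, r.t_ch) > 0

    def test_invalid_multiplicity_rejected(self):
        with pytest.raises(ValueError):
            SpinSegment(multiplicity=4)


class TestSchemeIntensities:
    def test_cp_rigid_slow_limit(self, default_settings):
        relax = RelaxationSet(t2_h=1e-5, t2_c=1e-5, t1rho_h=1.0, t_ch=50e-6)
        assert cp_intensity(relax, default_settings) >= 0.9 * default_settings.gamma_ratio

    def test_cp_no_transfer_without_coupling(self, default_settings):
        relax = RelaxationSet(t2_h=1.0, t2_c=1.0, t1rho_h=1.0, t_ch=1e6)
        assert cp_intensity(relax, default_settings) < 1e-3

    def test_cp_killed_by_fast_t1rho(self, default_settings):
        relax = RelaxationSet(t2_h=1e-4, t2_c=1e-4, t1rho_h=50e-6, t_ch=50e-6)
        assert cp_intensity(relax, default_settings) < 0.1 * default_settings.gamma_ratio

    def test_cp_equal_time_constants_limit(self, default_settings):
        t = 3e-4
        relax = RelaxationSet(t2_h=1e-4, t2_c=1e-4, t1rho_h=t, t_ch=t)
        expected = (default_settings.gamma_ratio * default_settings.t_cp / t
                    * math.exp(-default_settings.t_cp / t))
        assert cp_intensity(relax, default_settings) == pytest.approx(expected, rel=1e-6)

    def test_inept_lossless_at_optimal_delays(self):
        # for a CH segment the optimal refocusing delay is also 1/(4J)
        s = ExperimentSettings(inept_tau=1.8e-3, inept_tau_prime=1.8e-3)
        j = 1.0 / (4.0 * s.inept_tau)
        seg = SpinSegment(multiplicity=1, j_ch=j)
        relax = RelaxationSet(t2_h=math.inf, t2_c=math.inf, t1rho_h=1.0, t_ch=1e-4)
        assert inept_intensity(relax, seg, s) == pytest.approx(s.gamma_ratio, rel=1e-9)

    def test_inept_killed_by_short_t2h(self, ch2, default_settings):
        relax = RelaxationSet(t2_h=1e-5, t2_c=1.0, t1rho_h=1.0, t_ch=1e-4)
        assert inept_intensity(relax, ch2, default_settings) < 1e-3

    def test_inept_ch2_product_formula(self, default_settings):
        # scalar oracle: gamma * sin(pi J 3.6ms) * sin(pi J 2.4ms) * cos(pi J 2.4ms)
        seg = SpinSegment(multiplicity=2, j_ch=139.0)
        relax = RelaxationSet(t2_h=math.inf, t2_c=math.inf, t1rho_h=1.0, t_ch=1e-4)
        j = 139.0
        expected = (4.0 * math.sin(math.pi * j * 3.6e-3)
                    * math.sin(math.pi * j * 2.4e-3) * math.cos(math.pi * j * 2.4e-3))
        assert inept_intensity(relax, seg, default_settings) == pytest.approx(
            expected, rel=1e-12)

    def test_dp_unit_reference(self):
        relax = RelaxationSet(t2_h=1e-5, t2_c=1e-5, t1rho_h=1e-3, t_ch=1e-4)
        assert dp_intensity(relax) == 1.0
        mobile = RelaxationSet(t2_h=1.0, t2_c=1.0, t1rho_h=1.0, t_ch=1e3)
        assert dp_intensity(mobile) == 1.0

    def test_dp_visibility_option(self):
        relax = RelaxationSet(t2_h=1e-5, t2_c=5e-6, t1rho_h=1e-3, t_ch=1e-4)
        assert dp_intensity(relax, visibility_linewidth_hz=30.0) < 1.0


class TestEfficiencyTriplet:
    def test_mobile_isotropic_regime(self, ch2, default_settings):
        t = efficiency_triplet(MotionModel(0.005, 1e-9), ch2, default_settings)
        thr = RegimeThresholds.for_segment(ch2, default_settings)
        assert t.i_inept > 0.9 * thr.inept_max
        assert t.i_cp < 0.05 * thr.cp_max

    def test_rigid_anisotropic_regime(self, ch2, default_settings):
        t = efficiency_triplet(MotionModel(0.95, 1e-9), ch2, default_settings)
        assert t.i_cp > 0.9 * default_settings.gamma_ratio
        assert t.i_inept < 1e-3

    def test_intermediate_regime_both_reduced(self, ch2, default_settings):
        t = efficiency_triplet(MotionModel(1.0, 1e-6), ch2, default_settings)
        assert t.i_cp < 0.5 * default_settings.gamma_ratio
        assert t.i_inept < 0.05

    def test_no_superphysical_enhancement(self, ch2, default_settings):
        g = default_settings.gamma_ratio
        for s in np.logspace(-3, 0, 8):
            for tau in np.logspace(-12, 0, 10):
                t = efficiency_triplet(MotionModel(s, tau), ch2, default_settings)
                assert 0.0 <= t.i_cp <= g + 1e-9
                assert 0.0 <= t.i_inept <= g + 1e-9

    def test_monotone_in_order_parameter_at_fast_tau(self, ch2, default_settings):
        s_grid = np.logspace(-3, 0, 40)
        trips = [efficiency_triplet(MotionModel(s, 1e-9), ch2, default_settings)
                 for s in s_grid]
        inept = np.array([t.i_inept for t in trips])
        cp = np.array([t.i_cp for t in trips])
        assert np.all(np.diff(inept) <= 1e-5 * inept.max())
        assert np.all(np.diff(cp) >= -1e-9)

    def test_crossing_near_s_0p1(self, ch2, default_settings):
        """CP/INEPT equality contour at tau_c = 1 ns crosses near S ~ 0.1."""
        lo, hi = 0.001, 1.0
        f = lambda s: (efficiency_triplet(MotionModel(s, 1e-9), ch2, default_settings).i_cp
                       - efficiency_triplet(MotionModel(s, 1e-9), ch2, default_settings).i_inept)
        for _ in range(50):
            mid = math.sqrt(lo * hi)
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        assert abs(math.sqrt(lo * hi) - 0.1) <= 0.05


class TestEfficiencyMap:
    def test_shape_and_orientation(self, ch2, default_settings):
        tau = np.logspace(-12, 0, 7)
        s = np.logspace(-3, 0, 5)
        out = efficiency_map(tau, s, ch2, default_settings)
        assert out["i_cp"].shape == (5, 7)
        # top row (S = 1): CP maximal at both tau extremes, dipping between
        top = out["i_cp"][-1]
        assert top[0] > 0.9 * default_settings.gamma_ratio
        assert top[-1] > 0.9 * default_settings.gamma_ratio
        assert top.min() < top[0]

    def test_rejects_empty_and_out_of_range_grids(self, ch2, default_settings):
        with pytest.raises(ValueError):
            efficiency_map(np.array([]), np.array([0.1]), ch2, default_settings)
        with pytest.raises(ValueError):
            efficiency_map(np.array([10.0]), np.array([0.1]), ch2, default_settings)


class TestClassifyRegime:
    @pytest.mark.parametrize("triplet,expected", [
        ((1.0, 0.0, 3.5), "mobile_isotropic"),
        ((1.0, 1.8, 1.7), "mobile_anisotropic"),
        ((1.0, 3.6, 0.0), "rigid_slow"),
        ((1.0, 0.01, 0.01), "intermediate"),
        ((0.0, 0.0, 0.0), "ambiguous"),
    ])
    def test_rule_table(self, triplet, expected):
        dp, cp, inept = triplet
        assert classify_regime(EfficiencyTriplet(dp, cp, inept)) == expected

    @given(st.floats(0, 1), st.floats(0, 4), st.floats(0, 4))
    def test_never_raises(self, dp, cp, inept):
        assert classify_regime(EfficiencyTriplet(dp, cp, inept)) in {
            "mobile_isotropic", "mobile_anisotropic", "rigid_slow",
            "intermediate", "ambiguous"}


class TestValidation:
    def test_motion_model_invariants(self):
        with pytest.raises(ValueError):
            MotionModel(1.5, 1e-9)
        with pytest.raises(ValueError):
            MotionModel(0.5, -1e-9)
        with pytest.raises(ValueError):
            MotionModel(0.5, 1e-3, tau_s=1e-9)

    def test_settings_defaults_match_experiment(self, default_settings):
        s = default_settings
        assert (s.b0, s.mas_rate, s.t_cp) == (11.74, 5000.0, 1e-3)
        assert (s.nut_h_start, s.nut_h_end, s.nut_c) == (72e3, 88e3, 80e3)
        assert (s.inept_tau, s.inept_tau_prime) == (1.8e-3, 1.2e-3)
        assert s.gamma_ratio == pytest.approx(4.0)

    def test_segment_invariants(self):
        with pytest.raises(ValueError):
            SpinSegment(multiplicity=2, j_ch=50.0)
        with pytest.raises(ValueError):
            SpinSegment(multiplicity=2, r_ch=2.0e-10)
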