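"""CF normalization, beta profiles, VO kernel coefficients, CF-FF integral."""

import math

import numpy as np
import pytest

from cfglucose import (ConfigurationError, DomainError, FractionalOrderSpec,
                       beta_derivative, beta_eval, bhat, cf_ff_integral,
                       g_term, kappa, t_pow_beta_rate)
from cfglucose.operators import PROFILES


class TestBhat:
    def test_endpoints_are_one_exactly(self):
        assert bhat(0.0) == 1.0
        assert bhat(1.0) == 1.0

    def test_interior_value_against_gamma_oracle(self):
        import sympy
        expected = float(1 - sympy.Rational(85, 100)
                         + sympy.Rational(85, 100) / sympy.gamma(sympy.Rational(85, 100)))
        assert bhat(0.85) == pytest.approx(expected, rel=1e-14)

    @pytest.mark.parametrize("bad", [-0.1, 1.1, math.nan])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(DomainError):
            bhat(bad)


class TestBetaProfiles:
    def test_worked_example_value(self):
        spec = FractionalOrderSpec(alpha=0.85, beta="cos_fast")
        assert round(beta_eval(spec, 1.0), 5) == 0.96081

    def test_constant_profile(self):
        spec = FractionalOrderSpec(alpha=0.5, beta="const:1")
        for t in (0.0, 1.0, 17.3):
            assert beta_eval(spec, t) == 1.0
        assert spec.constant_beta() == 1.0

    def test_cos_slow_boundary_at_zero(self):
        spec = FractionalOrderSpec(alpha=0.5, beta="cos_slow")
        assert beta_eval(spec, 0.0) == 1.0

    def test_unknown_profile_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown beta profile"):
            FractionalOrderSpec(alpha=0.5, beta="nope")

    @pytest.mark.parametrize("name", sorted(PROFILES))
    def test_all_profiles_in_unit_interval_on_window(self, name):
        spec = FractionalOrderSpec(alpha=0.5, beta=name)
        t = np.linspace(0.0, 120.0, 2401)
        vals = np.array([beta_eval(spec, ti) for ti in t])
        assert np.all(vals > 0.0) and np.all(vals <= 1.0)

    def test_alpha_bounds_enforced(self):
        with pytest.raises(ConfigurationError):
            FractionalOrderSpec(alpha=1.5)
        with pytest.raises(ConfigurationError):
            FractionalOrderSpec(alpha=0.0)


class TestBetaDerivative:
    def test_worked_example_analytic(self):
        spec = FractionalOrderSpec(alpha=0.85, beta="cos_fast",
                                   beta_derivative_mode="analytic")
        assert round(beta_derivative(spec, 1.0), 5) == -0.01683

    def test_constant_profile_zero_in_both_modes(self):
        for mode in ("analytic", "forward_difference"):
            spec = FractionalOrderSpec(alpha=0.5, beta="const:0.9",
                                       beta_derivative_mode=mode)
            assert beta_derivative(spec, 2.0, dt=0.01) == 0.0

    def test_forward_difference_first_order_convergence(self):
        exact = -0.02 * math.sin(2.0)
        spec = FractionalOrderSpec(alpha=0.5, beta="cos_fast")
        errs = [abs(beta_derivative(spec, 2.0, dt=dt) - exact)
                for dt in (1e-2, 1e-3, 1e-4)]
        # O(dt): each refinement shrinks the error ~10x
        assert errs[0] / errs[1] == pytest.approx(10, rel=0.2)
        assert errs[1] / errs[2] == pytest.approx(10, rel=0.2)

    def test_forward_difference_needs_dt(self):
        spec = FractionalOrderSpec(alpha=0.5, beta="cos_fast")
        with pytest.raises(DomainError):
            beta_derivative(spec, 1.0)


class TestTPowBetaRate:
    def test_constant_beta_reduces_to_power_rule(self):
        spec = FractionalOrderSpec(alpha=0.5, beta=0.7,
                                   beta_derivative_mode="analytic")
        for t in (0.5, 1.0, 3.0, 50.0):
            assert t_pow_beta_rate(spec, t) == pytest.approx(
                0.7 * t ** (-0.3), rel=1e-13)

    @pytest.mark.parametrize("name", sorted(PROFILES))
    def test_t_equal_one_gives_beta_of_one(self, name):
        spec = FractionalOrderSpec(alpha=0.5, beta=name,
                                   beta_derivative_mode="analytic")
        assert t_pow_beta_rate(spec, 1.0) == pytest.approx(
            beta_eval(spec, 1.0), rel=1e-13)

    @pytest.mark.parametrize("name", sorted(PROFILES))
    def test_matches_central_difference(self, name):
        spec = FractionalOrderSpec(alpha=0.5, beta=name,
                                   beta_derivative_mode="analytic")
        t, h = 2.5, 1e-5
        fn = spec.beta_function()
        fd = ((t + h) ** fn(t + h) - (t - h) ** fn(t - h)) / (2 * h)
        assert t_pow_beta_rate(spec, t) == pytest.approx(fd, abs=1e-6)

    def test_singular_at_origin(self):
        spec = FractionalOrderSpec(alpha=0.5, beta="cos_fast")
        with pytest.raises(DomainError):
            t_pow_beta_rate(spec, 0.0)


class TestKappa:
    def test_worked_example(self):
        spec = FractionalOrderSpec(alpha=0.85, beta="cos_fast")
        assert round(kappa(spec, 1.0, 0.1), 5) == 0.96081

    def test_constant_beta_reduces_to_fixed_scale(self):
        spec = FractionalOrderSpec(alpha=0.85, beta=0.9)
        for t in np.logspace(-2, 2, 9):
            assert kappa(spec, float(t), 0.01) == pytest.approx(
                0.9 * t ** (-0.1), rel=1e-12)

    @pytest.mark.parametrize("name", sorted(PROFILES))
    def test_t_equal_one_gives_beta(self, name):
        spec = FractionalOrderSpec(alpha=0.85, beta=name)
        assert kappa(spec, 1.0, 0.05) == pytest.approx(
            beta_eval(spec, 1.0), rel=1e-13)

    def test_origin_rejected(self):
        spec = FractionalOrderSpec(alpha=0.85, beta="cos_fast")
        with pytest.raises(DomainError):
            kappa(spec, 0.0, 0.1)


class TestGTerm:
    def test_worked_example_with_rounding_slack(self):
        spec = FractionalOrderSpec(alpha=0.85, beta="cos_fast")
        assert g_term(spec, 1.0, 0.1, 2.5) == pytest.approx(2.40203, abs=1e-4)

    def test_zero_rhs_gives_zero(self):
        spec = FractionalOrderSpec(alpha=0.85, beta="cos_fast")
        assert g_term(spec, 1.7, 0.1, 0.0) == 0.0

    def test_equals_h_times_kappa_in_forward_mode(self):
        spec = FractionalOrderSpec(alpha=0.85, beta="cos_slow")
        for t in (0.3, 1.0, 2.5, 40.0):
            for dt in (0.1, 0.001):
                assert g_term(spec, t, dt, 1.7) == pytest.approx(
                    1.7 * kappa(spec, t, dt), rel=1e-13)


class TestCFFFIntegral:
    def test_zero_function(self):
        assert cf_ff_integral(np.zeros(11), 0.5, 0.5, 1.0) == 0.0

    def test_constant_against_quad_oracle(self):
        from scipy.integrate import quad
        alpha = beta = 0.5
        t = 1.0
        f = np.ones(2001)
        got = cf_ff_integral(f, alpha, beta, t)
        integral, _ = quad(lambda mu: mu ** (alpha - 1.0), 0.0, t)
        expected = (alpha * beta / bhat(alpha) * integral
                    + beta * (1 - alpha) * t ** (beta - 1) / bhat(alpha))
        assert got == pytest.approx(expected, rel=1e-4)

    def test_smooth_function_against_quad_oracle(self):
        from scipy.integrate import quad
        alpha, beta, t = 0.7, 0.9, 2.0
        grid = np.linspace(0, t, 4001)
        f = np.cos(grid)
        got = cf_ff_integral(f, alpha, beta, t)
        integral, _ = quad(lambda mu: mu ** (alpha - 1.0) * math.cos(mu), 0, t)
        expected = (alpha * beta / bhat(alpha) * integral
                    + beta * (1 - alpha) * t ** (beta - 1) / bhat(alpha)
                    * math.cos(t))
        assert got == pytest.approx(expected, rel=1e-4)

    def test_alpha_one_limit_drops_local_term(self):
        # at alpha=1 only the plain integral survives
        t = 1.0
        grid = np.linspace(0, t, 1001)
        f = grid ** 2
        got = cf_ff_integral(f, 1.0, 0.8, t)
        assert got == pytest.approx(0.8 * (1.0 / 3.0), rel=1e-5)

    def test_empty_sample_rejected(self):
        with pytest.raises(DomainError):
            cf_ff_integral([], 0.5, 0.5, 1.0)
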