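"""Fixed-order CF-FF Newton-interpolation integrator."""

import math

import numpy as np
import pytest

from cfglucose import (ConfigurationError, ControlGains, FractionalOrderSpec,
                       ModelParameters, SolverConfig, bhat, bootstrap_steps,
                       find_equilibrium, newton_poly, scale_rhs,
                       simulate_fixed, step_fixed)
from cfglucose.fixed_order import integrate_fixed

DECAY = lambda t, y1, y2, y3: (-y1, -y2, -y3)


class TestScaleRHS:
    def test_short_memory_zero_at_origin_for_fractal_beta(self):
        assert scale_rhs(7.3, 0.0, 0.95) == 0.0

    def test_identity_for_classical_beta(self):
        assert scale_rhs(7.3, 0.0, 1.0) == 7.3
        assert scale_rhs(7.3, 2.4, 1.0) == 7.3

    def test_hand_arithmetic(self):
        # 0.5 * 4**(-0.5) * 2 = 0.5
        assert scale_rhs(2.0, 4.0, 0.5) == pytest.approx(0.5, rel=1e-14)


class TestNewtonPoly:
    def test_reproduces_constants(self):
        assert newton_poly(3.7, 3.7, 3.7) == pytest.approx(3.7, rel=1e-15)

    def test_basis_vector(self):
        assert newton_poly(1.0, 0.0, 0.0) == pytest.approx(5.0 / 12.0)

    def test_linear_sequence_integrates_exactly(self):
        # f_k = k: P_n = n + 1/2, the exact mean of the interpolant over
        # [t_n, t_{n+1}] (third-order quadrature is exact on degree <= 2)
        assert newton_poly(0.0, 1.0, 2.0) == pytest.approx(2.5, rel=1e-15)
        assert newton_poly(5.0, 6.0, 7.0) == pytest.approx(7.5, rel=1e-15)


class TestStepFixed:
    def test_hand_evaluated_update(self):
        # synthetic scaled samples (1, 2, 3), alpha=0.85, dt=0.1
        alpha, dt = 0.85, 0.1
        bh = bhat(alpha)
        expected = (1.0 + (0.15 / bh) * (3.0 - 2.0)
                    + (0.85 / bh) * (5.0 / 12.0 - 4.0 / 3.0 * 2.0
                                     + 23.0 / 12.0 * 3.0) * dt)
        got = step_fixed([1.0] * 3, [1.0] * 3, [2.0] * 3, [3.0] * 3, alpha, dt)
        np.testing.assert_allclose(got, expected, rtol=1e-14)

    def test_classical_limit_is_ab3_identity(self, rng):
        # alpha=beta=1: update must equal y + dt*(23/12 f_n - 4/3 f_{n-1}
        # + 5/12 f_{n-2}) to machine precision on arbitrary samples
        for _ in range(20):
            y, f2, f1, f0 = rng.standard_normal((4, 3))
            got = step_fixed(y, f2, f1, f0, 1.0, 0.05)
            expected = y + 0.05 * (23 / 12 * f0 - 4 / 3 * f1 + 5 / 12 * f2)
            np.testing.assert_allclose(got, expected, rtol=1e-14, atol=1e-15)

    def test_zero_rhs_is_fixed_point(self):
        z = [0.0] * 3
        np.testing.assert_array_equal(
            step_fixed([1.0, 2.0, 3.0], z, z, z, 0.7, 0.01), [1.0, 2.0, 3.0])


def _ab3_error_with_exact_seeds(dt, T=2.0):
    """Global error at T of the order-3 stepper on y' = -y with exact
    starting values (isolates the stepper from the bootstrap)."""
    N = int(round(T / dt))
    u = [-math.exp(0.0), -math.exp(-dt), -math.exp(-2 * dt)]
    y = math.exp(-2 * dt)
    for n in range(2, N):
        y = y + newton_poly(u[n - 2], u[n - 1], u[n]) * dt
        u.append(-y)
    return abs(y - math.exp(-T))


class TestConvergenceOrders:
    def test_stepper_is_third_order_on_linear_decay(self):
        errs = [_ab3_error_with_exact_seeds(dt) for dt in (0.02, 0.01, 0.005)]
        orders = [math.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert all(o > 2.7 for o in orders)

    def test_bootstrap_composite_is_at_least_second_order(self):
        errs = []
        for dt in (0.02, 0.01, 0.005):
            cfg = SolverConfig(dt=dt, T=2.0, stop_delta=0.0)
            traj = integrate_fixed(DECAY, (1.0, 1.0, 1.0), 1.0, 1.0, cfg)
            errs.append(abs(traj.states[-1, 0] - math.exp(-2.0)))
        orders = [math.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert all(o > 1.9 for o in orders)

    def test_self_convergence_under_step_halving(self, params, default_gains):
        # endpoint differences under halving shrink at the composite's
        # second order, and reach rel_tol once the chaotic amplification
        # over T=10 is resolved
        ends = {}
        for dt in (5e-4, 2.5e-4, 1.25e-4, 6.25e-5):
            cfg = SolverConfig(dt=dt, T=10.0, stop_delta=0.0)
            traj = simulate_fixed((0.0, 1.5, 1.0), params, default_gains,
                                  FractionalOrderSpec(1.0, 1.0), cfg)
            ends[dt] = traj.states[-1]
        scale = np.max(np.abs(ends[6.25e-5]))
        diffs = [np.max(np.abs(ends[a] - ends[b])) / scale
                 for a, b in ((5e-4, 2.5e-4), (2.5e-4, 1.25e-4),
                              (1.25e-4, 6.25e-5))]
        orders = [math.log2(diffs[i] / diffs[i + 1]) for i in range(2)]
        assert all(o > 1.7 for o in orders)
        assert diffs[-1] < 1e-6


class TestBootstrap:
    def test_two_point_reduces_to_ab2_in_classical_limit(self):
        # n=1 step on y'=-y, alpha=beta=1: y2 = y1 + dt*(3/2 f1 - 1/2 f0)
        dt = 0.1
        cfg = SolverConfig(dt=dt, T=2 * dt, stop_delta=0.0)
        traj = integrate_fixed(DECAY, (1.0, 1.0, 1.0), 1.0, 1.0, cfg)
        y1e = 1.0 + dt * (-1.0)                      # Euler
        y2e = y1e + dt * (1.5 * (-y1e) - 0.5 * (-1.0))  # AB2
        np.testing.assert_allclose(traj.states[1], [y1e] * 3, rtol=1e-14)
        np.testing.assert_allclose(traj.states[2], [y2e] * 3, rtol=1e-14)

    def test_bootstrap_steps_match_simulation_prefix(self, params,
                                                     default_gains):
        orders = FractionalOrderSpec(0.9, 0.95)
        cfg = SolverConfig(dt=0.01, T=1.0, stop_delta=0.0)
        y1, y2 = bootstrap_steps((0.0, 1.5, 1.0), params, default_gains,
                                 orders, cfg)
        traj = simulate_fixed((0.0, 1.5, 1.0), params, default_gains,
                              orders, cfg)
        np.testing.assert_array_equal(y1, traj.states[1])
        np.testing.assert_array_equal(y2, traj.states[2])

    def test_zero_rhs_keeps_state(self):
        p = ModelParameters(**{f"a{i}": 0.0 for i in range(1, 22)})
        y1, y2 = bootstrap_steps((0.4, -0.2, 1.0), p=p,
                                 orders=FractionalOrderSpec(0.9, 0.95),
                                 cfg=SolverConfig(dt=0.01, T=120.0))
        np.testing.assert_array_equal(y1, [0.4, -0.2, 1.0])
        np.testing.assert_array_equal(y2, [0.4, -0.2, 1.0])


class TestSimulateFixed:
    def test_zero_field_constant_trajectory(self):
        p = ModelParameters(**{f"a{i}": 0.0 for i in range(1, 22)})
        cfg = SolverConfig(dt=0.01, T=1.0, stop_delta=0.0)
        traj = simulate_fixed((0.3, -0.1, 2.0), p, None,
                              FractionalOrderSpec(0.9, 0.95), cfg)
        assert len(traj) == 101
        np.testing.assert_array_equal(traj.states,
                                      np.tile([0.3, -0.1, 2.0], (101, 1)))

    def test_equilibrium_start_triggers_stopping(self, params, default_gains):
        eq = find_equilibrium(params, default_gains, (0.5, 1.0, 1.0))
        assert eq.converged
        cfg = SolverConfig(dt=0.001, T=120.0)
        traj = simulate_fixed(eq.state, params, default_gains,
                              FractionalOrderSpec(1.0, 1.0), cfg)
        assert traj.termination == "converged"
        assert len(traj) < 100

    def test_grid_and_metadata_invariants(self, params, default_gains):
        cfg = SolverConfig(dt=0.01, T=5.0)
        traj = simulate_fixed((0.0, 1.5, 1.0), params, default_gains,
                              FractionalOrderSpec(0.98, 1.0), cfg)
        assert len(traj.times) == len(traj.states)
        assert np.all(np.diff(traj.times) > 0)
        assert traj.metadata["scheme"] == "fixed"
        assert traj.metadata["gains"] == {"d1": 0.2, "d3": 0.1}
        assert "config_hash" in traj.metadata

    def test_blowup_is_flagged_and_truncated(self, params):
        # these printed gains genuinely destabilize the field: the run
        # must fail loudly with a finite truncated trajectory
        cfg = SolverConfig(dt=0.001, T=30.0)
        traj = simulate_fixed((0.0, 1.5, 1.0), params, ControlGains(0.25, 0.15),
                              FractionalOrderSpec(1.0, 1.0), cfg)
        assert traj.diverged
        assert traj.times[-1] < 30.0
        assert np.all(np.isfinite(traj.states))

    def test_variable_profile_rejected(self, params):
        with pytest.raises(ConfigurationError, match="time-varying"):
            simulate_fixed((0, 1.5, 1), params, None,
                           FractionalOrderSpec(0.98, "cos_slow"),
                           SolverConfig(dt=0.01, T=1.0))


class TestSolverConfig:
    @pytest.mark.parametrize("kw", [
        {"dt": -0.1}, {"T": 0.0}, {"dt": 0.3, "T": 1.0},
        {"scheme": "magic"}, {"bootstrap": "rk4"}, {"poly_order": 5},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            SolverConfig(**kw)

    def test_n_steps(self):
        assert SolverConfig(dt=0.001, T=120.0).n_steps == 120000
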