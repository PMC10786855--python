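"""Mean-field model: closed forms against independent ODE/quadrature oracles."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

import micc
from micc import HazardScale, ModelParams, RegimeWarning


def rk4(rhs, y0, t_end, n_steps):
    """Fixed-step RK4 oracle, independent of scipy's adaptive integrators."""
    y, t = float(y0), 0.0
    h = t_end / n_steps
    for _ in range(n_steps):
        k1 = rhs(t, y)
        k2 = rhs(t + h / 2, y + h * k1 / 2)
        k3 = rhs(t + h / 2, y + h * k2 / 2)
        k4 = rhs(t + h, y + h * k3)
        y += h * (k1 + 2 * k2 + 2 * k3 + k4) / 6
        t += h
    return y


class TestLogisticFailedCount:
    def test_initial_condition_and_inflection(self, danish_mf):
        params, _ = danish_mf
        assert micc.logistic_failed_count(params, 0.0) == pytest.approx(params.f0)
        assert micc.logistic_failed_count(params, params.tau) == pytest.approx(
            params.N / 2, rel=1e-12
        )

    def test_matches_stiff_ode_oracle(self, danish_mf):
        params, _ = danish_mf
        sol = solve_ivp(
            lambda _t, F: params.r * F * (params.N - F),
            (0, 100.0),
            [params.f0],
            method="Radau",
            rtol=1e-11,
            atol=1e-12,
        )
        oracle = sol.y[0, -1]
        value = micc.logistic_failed_count(params, 100.0)
        assert value == pytest.approx(oracle, rel=1e-6)
        assert value == pytest.approx(25.193, rel=1e-4)

    def test_bounds_and_monotonicity(self, danish_mf):
        params, _ = danish_mf
        t = np.linspace(0, 2000, 400)
        F = micc.logistic_failed_count(params, t)
        assert np.all(F >= params.f0)
        assert np.all(F < params.N)
        assert np.all(np.diff(F) > 0)

    def test_degenerate_and_errors(self):
        with pytest.warns(RegimeWarning):
            frozen = ModelParams(N=100, r=0.01, f0=0)
        with pytest.warns(RegimeWarning):
            assert micc.logistic_failed_count(frozen, 5.0) == 0.0
        params = ModelParams(N=100, r=0.01, f0=1)
        with pytest.raises(ValueError):
            micc.logistic_failed_count(params, -1.0)
        with pytest.raises(ValueError):
            micc.logistic_failed_count(params.with_(epsilon=0.1), 1.0)


class TestInflectionTime:
    def test_half_capacity_start_gives_zero(self):
        params = ModelParams(N=100, r=0.01, f0=50)
        with pytest.warns(RegimeWarning):
            assert micc.inflection_time(params) == pytest.approx(0.0, abs=1e-12)

    def test_value_against_bisection(self, danish_mf):
        from scipy.optimize import brentq

        params, _ = danish_mf
        tau = micc.inflection_time(params)
        assert tau == pytest.approx(1246.0, abs=0.5)
        root = brentq(
            lambda t: micc.logistic_failed_count(params, t) - params.N / 2, 1.0, 5000.0,
            xtol=1e-9,
        )
        assert tau == pytest.approx(root, rel=1e-9)

    def test_monotone_decreasing_in_f0(self):
        taus = [
            ModelParams(N=1e6, r=9.24e-9, f0=f0).tau for f0 in (5, 10, 20, 40)
        ]
        assert np.all(np.diff(taus) < 0)


class TestMortalityRate:
    def test_scale_convention(self, danish_mf):
        params, scale = danish_mf
        assert micc.mortality_rate(params, scale, 0.0) == pytest.approx(
            scale.r0(params), rel=1e-12
        )
        assert scale.r0(params) == pytest.approx(4.2e-5, rel=1e-12)
        # logistic saturation: hazard plateaus at k
        assert micc.mortality_rate(params, scale, 1e5) == pytest.approx(scale.k, rel=1e-9)

    def test_agrees_with_gompertz_oracle_at_100(self, danish_mf):
        params, scale = danish_mf
        mu = micc.mortality_rate(params, scale, 100.0)
        gomp = micc.gompertz_rate(4.2e-5, 9.24e-3, 100.0)
        assert gomp == pytest.approx(1.058e-4, rel=1e-3)
        assert mu == pytest.approx(gomp, rel=1e-4)

    def test_gompertz_limit_bound(self, danish_mf):
        """Within the small-fraction regime the relative deviation from the
        Gompertz curve is bounded by the failed fraction itself."""
        params, scale = danish_mf
        t = np.linspace(0, 480, 200)  # F(480)/N just under 1e-3
        F = micc.logistic_failed_count(params, t)
        keep = F / params.N < 1e-3
        mu = micc.mortality_rate(params, scale, t[keep])
        gomp = micc.gompertz_rate(scale.r0(params), params.b, t[keep])
        assert np.all(np.abs(mu / gomp - 1) < 2e-3)
        assert np.all(np.abs(mu / gomp - 1) <= F[keep] / params.N * 1.01)


def test_gompertz_rate_identities():
    r0, b = 3e-4, 0.08
    assert micc.gompertz_rate(r0, b, 0.0) == r0
    assert micc.gompertz_rate(r0, b, np.log(2) / b) == pytest.approx(2 * r0, rel=1e-12)
    with pytest.raises(ValueError):
        micc.gompertz_rate(-1.0, b, 1.0)


class TestSurvivalAndDensity:
    def test_boundary_values(self, danish_mf):
        params, scale = danish_mf
        t = np.arange(0.0, 151.0)
        S, p = micc.survival_and_density(params, scale, t)
        assert S[0] == 1.0
        assert p[0] == pytest.approx(scale.r0(params), rel=1e-12)
        assert np.all(np.diff(S) < 0)

    def test_matches_gompertz_closed_form(self, danish_mf):
        params, scale = danish_mf
        t = np.arange(0.0, 101.0)
        S, _ = micc.survival_and_density(params, scale, t)
        S_gomp = micc.gompertz_survival(scale.r0(params), params.b, t)
        # identical to 6 digits over the human age range
        assert np.allclose(S, S_gomp, rtol=2e-6, atol=0)

    def test_cumulative_hazard_matches_quadrature(self, danish_mf):
        params, scale = danish_mf
        for t_end in (10.0, 100.0, 800.0):
            oracle, err = quad(
                lambda s: micc.mortality_rate(params, scale, s), 0, t_end, epsrel=1e-11
            )
            assert micc.cumulative_hazard(params, scale, t_end) == pytest.approx(
                oracle, rel=1e-8
            )

    def test_density_integrates_to_death_mass(self, danish_mf):
        params, scale = danish_mf
        t = np.linspace(0, 1500.0, 30_001)
        t[0] = 0.0
        S, p = micc.survival_and_density(params, scale, t)
        assert np.trapezoid(p, t) == pytest.approx(1 - S[-1], rel=1e-6)

    def test_zero_hazard_limit_and_grid_validation(self, danish_mf):
        params, _ = danish_mf
        S, p = micc.survival_and_density(params, HazardScale(k=0.0), np.arange(0.0, 10.0))
        assert np.all(S == 1.0) and np.all(p == 0.0)
        with pytest.raises(ValueError):
            micc.survival_and_density(params, HazardScale(1.0), np.array([0.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            micc.survival_and_density(params, HazardScale(1.0), np.array([1.0, 2.0]))


class TestSpontaneousFailure:
    def test_reduces_to_logistic_without_epsilon(self, danish_mf):
        params, _ = danish_mf
        t = np.array([0.0, 50.0, 120.0])
        assert np.allclose(
            micc.spontaneous_failed_count(params, t),
            micc.logistic_failed_count(params, t),
        )

    def test_matches_rk4_oracle(self):
        # epsilon*N comparable to f0: both driving terms active
        params = ModelParams(N=1e6, r=9.24e-9, f0=10, epsilon=1e-5)
        eps_n = params.epsilon * params.N

        def rhs(_t, F):
            return params.r * (F + eps_n) * (params.N - F)

        for t_end in (50.0, 150.0):
            oracle = rk4(rhs, params.f0, t_end, 20_000)
            assert micc.spontaneous_failed_count(params, t_end) == pytest.approx(
                oracle, rel=1e-8
            )

    def test_matches_shifted_logistic_closed_form(self):
        # G = F + eps*N is logistic with capacity N(1+eps)
        params = ModelParams(N=1e4, r=1e-5, f0=5, epsilon=2e-3)
        eps_n = params.epsilon * params.N
        t = np.array([3.0, 30.0, 300.0])
        g0 = params.f0 + eps_n
        cap = params.N * (1 + params.epsilon)
        G = cap * g0 / (g0 + (cap - g0) * np.exp(-params.r * cap * t))
        assert np.allclose(micc.spontaneous_failed_count(params, t), G - eps_n, rtol=1e-7)

    def test_dominant_spontaneous_term_grows_linearly(self):
        # eps*N >> f0: early growth ~ r*eps*N^2*t, not exponential
        params = ModelParams(N=1e6, r=9.24e-9, f0=10, epsilon=1e-2)
        t = np.array([0.5, 1.0, 2.0])
        growth = np.asarray(micc.spontaneous_failed_count(params, t)) - params.f0
        linear = params.r * params.epsilon * params.N**2 * t
        assert np.allclose(growth, linear, rtol=0.06)
        # and clearly non-exponential: doubling t roughly doubles the increment
        assert growth[2] / growth[1] == pytest.approx(2.0, rel=0.1)


class TestRepair:
    def test_identity_without_repair(self, danish_mf):
        params, _ = danish_mf
        assert micc.apply_repair(params) == params

    def test_capacity_substitution_arithmetic(self):
        params = ModelParams(N=1e6, r=9.24e-9, f0=10, alpha=9.24e-9 * 1e5)
        eff = micc.apply_repair(params)
        assert eff.N == pytest.approx(9e5, rel=1e-12)
        assert eff.alpha == 0.0

    def test_repair_ode_equals_effective_logistic(self):
        params = ModelParams(N=1e4, r=5e-5, f0=4, alpha=5e-5 * 2000)
        eff = micc.apply_repair(params)

        def rhs(_t, F):
            return params.r * F * (params.N - F) - params.alpha * F

        t_grid = np.linspace(0, eff.tau, 40)[1:]
        sol = solve_ivp(rhs, (0, eff.tau), [params.f0], t_eval=t_grid,
                        method="Radau", rtol=1e-12, atol=1e-13)
        F_eff = micc.logistic_failed_count(eff, t_grid)
        assert np.max(np.abs(sol.y[0] / F_eff - 1)) <= 1e-8

    def test_subcritical_flagged(self):
        params = ModelParams(N=100, r=0.01, f0=2, alpha=1.5)  # alpha/r = 150 > N
        with pytest.warns(RegimeWarning, match="sub-critical"):
            assert micc.apply_repair(params) is None


class TestConstantRateNullModel:
    def test_boundary_values(self):
        assert micc.constant_rate_failed_count(1e6, 10, 0.01, 0.0) == 10
        assert micc.constant_rate_failed_count(1e6, 10, 0.01, 1e5) == pytest.approx(
            1e6, rel=1e-12
        )

    def test_matches_rk4_oracle(self):
        N, f0, C = 1e6, 10, 0.01
        oracle = rk4(lambda _t, F: C * (N - F), f0, 50.0, 40_000)
        assert micc.constant_rate_failed_count(N, f0, C, 50.0) == pytest.approx(
            oracle, rel=1e-8
        )

    def test_log_hazard_slope_strictly_decreasing(self):
        """The null model's hazard decelerates everywhere: anti-Gompertz."""
        t = np.linspace(0.5, 300, 600)
        F = micc.constant_rate_failed_count(1e6, 10, 0.01, t)
        log_slope = np.diff(np.log(F)) / np.diff(t)
        assert np.all(np.diff(log_slope) < 0)
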