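import math

import numpy as np
import pytest
from scipy import integrate

from liquidnet.meanfield import (GrowthLaw, MeanFieldModel, atp_rate,
                                 catastrophe_steady_state, closure_time,
                                 critical_catastrophe_rate, drift,
                                 hex_steady_state, steady_state_distribution,
                                 survival_time)


class TestHexSteadyState:
    def test_reference_parameters(self):
        # measured spawning rate and fitted density coefficient give the
        # mean polygon area of the source cells ≈ 1 µm²
        lam, area = hex_steady_state(b=0.03, k=0.0085, gamma=0.29)
        assert math.isclose(area, 0.29 * 0.03 / 0.0085, rel_tol=1e-12)
        assert math.isclose(area, 1.02, abs_tol=0.01)

    def test_proportionalities(self):
        _, a0 = hex_steady_state(0.02, 0.005)
        _, a_b2 = hex_steady_state(0.04, 0.005)
        _, a_k2 = hex_steady_state(0.02, 0.01)
        assert math.isclose(a_b2, 2 * a0)
        assert math.isclose(a_k2, 0.5 * a0)

    def test_hexagon_identity(self):
        lam, area = hex_steady_state(0.02, 0.005)
        assert math.isclose(area / (1.5 * math.sqrt(3)), lam**2,
                            rel_tol=1e-12)


class TestCatastropheSteadyState:
    B, K, G, V = 0.02, 0.005, 0.29, 1.0

    def test_zero_rate_reduces_to_hexagonal(self):
        lam0, _ = hex_steady_state(self.B, self.K, self.G)
        lam, diverged = catastrophe_steady_state(self.B, self.K, self.G,
                                                 self.V, 0.0)
        assert not diverged
        assert math.isclose(lam, lam0, rel_tol=1e-12)

    def test_root_against_dense_scan(self):
        ac = critical_catastrophe_rate(self.B, self.K, self.G, self.V)
        alpha = 0.9 * ac
        lam, diverged = catastrophe_steady_state(self.B, self.K, self.G,
                                                 self.V, alpha)
        assert not diverged
        lam0, _ = hex_steady_state(self.B, self.K, self.G)
        assert lam > lam0
        # oracle: dense scan of the transcendental left-hand side
        C = 2 * self.G * self.B / (3 * math.sqrt(3) * self.K)
        grid = np.linspace(1e-4, 2 * self.V / (math.sqrt(3) * alpha), 400_000)
        f = grid**2 * np.exp(-math.sqrt(3) * alpha * grid / self.V) - C
        scan_root = grid[np.argmax(f > 0)]
        assert abs(lam - scan_root) < grid[1] - grid[0] + 1e-9

    def test_divergence_above_critical(self):
        ac = critical_catastrophe_rate(self.B, self.K, self.G, self.V)
        lam, diverged = catastrophe_steady_state(self.B, self.K, self.G,
                                                 self.V, 1.01 * ac)
        assert diverged and math.isnan(lam)

    def test_lambda_increases_with_alpha(self):
        ac = critical_catastrophe_rate(self.B, self.K, self.G, self.V)
        lams = [catastrophe_steady_state(self.B, self.K, self.G, self.V, a)[0]
                for a in np.linspace(0, 0.95 * ac, 12)]
        assert np.all(np.diff(lams) > 0)


class TestCriticalRate:
    def test_reference_value(self):
        ac = critical_catastrophe_rate(0.02, 0.005, 0.29, 1.0)
        assert math.isclose(ac, 0.64, abs_tol=0.01)
        # closed form: (1/e)·sqrt(2√3·k·v²/(γb))
        assert math.isclose(
            ac, math.sqrt(2 * math.sqrt(3) * 0.005 / (0.29 * 0.02)) / math.e,
            rel_tol=1e-12)

    def test_scaling_structure(self):
        ac = critical_catastrophe_rate(0.02, 0.005, 0.29, 1.0)
        assert math.isclose(critical_catastrophe_rate(0.02, 0.02, 0.29, 1.0),
                            2 * ac, rel_tol=1e-12)      # α_c ∝ √k
        assert math.isclose(critical_catastrophe_rate(0.08, 0.005, 0.29, 1.0),
                            ac / 2, rel_tol=1e-12)      # α_c ∝ 1/√b
        assert math.isclose(critical_catastrophe_rate(0.02, 0.005, 0.29, 3.0),
                            3 * ac, rel_tol=1e-12)      # α_c ∝ v

    def test_matches_numeric_loss_of_root(self):
        ac = critical_catastrophe_rate(0.02, 0.005, 0.29, 1.0)
        lo, hi = 0.5 * ac, 2.0 * ac
        for _ in range(60):  # bisection on the divergence flag
            mid = 0.5 * (lo + hi)
            _, diverged = catastrophe_steady_state(0.02, 0.005, 0.29, 1.0, mid)
            lo, hi = (lo, mid) if diverged else (mid, hi)
        assert abs(0.5 * (lo + hi) - ac) / ac < 1e-6


class TestDrift:
    def test_zero_at_cutoff(self):
        model = MeanFieldModel()
        xc = model.law.x_cutoff
        assert math.isclose(xc, 1.38, abs_tol=0.01)
        assert abs(drift(xc * model.mean_area, model)) < 1e-12

    def test_signs(self):
        model = MeanFieldModel()
        assert drift(0.1 * model.mean_area, model) < 0
        assert drift(5.0 * model.mean_area, model) > 0


class TestClosureTime:
    def test_zero_initial_area(self):
        assert closure_time(0.0, MeanFieldModel()) == 0.0

    def test_pure_shrinkage_closed_form(self):
        # g → 0: t* = 2τ·√(x0)/h, quadrature to 1e-6 relative
        law = GrowthLaw(g=1e-300, h=1.85, beta=0.78)
        model = MeanFieldModel(law=law)
        for x0 in (0.04, 0.25, 1.0):
            expect = 2 * math.sqrt(x0) / 1.85
            assert abs(closure_time(x0, model) - expect) / expect < 1e-6

    def test_growing_polygons_never_close(self):
        model = MeanFieldModel()
        assert closure_time(2.0 * model.law.x_cutoff, model) == math.inf


class TestSurvivalTime:
    def test_no_splitting_equals_closure_time(self):
        model = MeanFieldModel(khat_nd=0.0)
        for x0 in (0.1, 0.5, 1.0):
            assert math.isclose(survival_time(x0, model),
                                closure_time(x0, model), rel_tol=1e-4)

    def test_no_splitting_growing_is_infinite(self):
        model = MeanFieldModel(khat_nd=0.0)
        assert survival_time(3.0, model) == math.inf

    def test_interior_maximum(self):
        sol = steady_state_distribution()
        model = MeanFieldModel(khat_nd=sol.khat_nd)
        xs = np.array([0.05, 0.2, 0.5, 1.0, 1.4, 2.5, 5.0, 10.0])
        ts = np.array([survival_time(x, model) for x in xs])
        peak = int(np.argmax(ts))
        assert 0 < peak < len(xs) - 1
        # longest-lived polygons sit near the drift cutoff
        assert 0.5 <= xs[peak] <= 3.0


class TestSteadyStateDistribution:
    def test_matching_area_and_mean(self):
        sol = steady_state_distribution()
        assert math.isclose(sol.a_star_bk, 0.12, abs_tol=0.015)
        assert math.isclose(sol.mean_bk, 0.23, abs_tol=0.015)

    def test_normalization_mean_and_flux(self):
        sol = steady_state_distribution()
        norm, _ = integrate.quad(sol.pdf, 0, np.inf, limit=200)
        mean, _ = integrate.quad(lambda x: x * sol.pdf(x), 0, np.inf,
                                 limit=200)
        assert abs(norm - 1.0) < 1e-7
        assert abs(mean - 1.0) < 1e-7
        assert abs(sol.j0 - sol.j_split) / sol.j0 < 1e-8

    def test_branches_continuous_at_matching_point(self):
        sol = steady_state_distribution()
        eps = 1e-9
        lo = sol.pdf(sol.x_star - eps)
        hi = sol.pdf(sol.x_star + eps)
        assert abs(lo - hi) / lo < 1e-6

    def test_large_branch_solves_transport_equation(self):
        # oracle: the large-area branch is the stationary solution of
        # d/dx[v(x)P] = −k̂√x·P with the large-x drift v = g·x^β; integrate
        # that ODE numerically and compare with the closed form
        sol = steady_state_distribution()
        law = sol.law

        def rhs(x, y):
            v = law.g * x**law.beta
            dv = law.g * law.beta * x ** (law.beta - 1)
            return [(-sol.khat_nd * math.sqrt(x) * y[0] - dv * y[0]) / v]

        x_hi = 6.0
        x0 = sol.x_star * 1.5
        out = integrate.solve_ivp(rhs, (x0, x_hi), [float(sol.pdf(x0))],
                                  rtol=1e-10, atol=1e-14, dense_output=True)
        assert out.success
        for x in (2.0, 3.0, 5.0):
            ode_val = float(out.sol(x)[0])
            closed = float(sol.pdf(x))
            assert abs(ode_val - closed) / closed < 1e-3

    def test_small_branch_has_inverse_sqrt_rise(self):
        sol = steady_state_distribution()
        x = np.array([1e-4, 1e-3, 1e-2])
        ratio = sol.pdf(x) * np.sqrt(x)
        assert np.allclose(ratio, ratio[0], rtol=1e-12)


class TestAtpRate:
    def test_order_of_magnitude(self):
        # thousands of ATP per second for a cell-scale network
        rate = atp_rate(L=3000.0, k=0.0085, b=0.03)
        assert 1e3 < rate < 1e4

    def test_halving_step_size_doubles_cost(self):
        r1 = atp_rate(3000, 0.0085, 0.03, ds=0.008)
        r2 = atp_rate(3000, 0.0085, 0.03, ds=0.016)
        assert math.isclose(r1, 2 * r2, rel_tol=1e-12)

    def test_vanishes_without_sliding(self):
        assert atp_rate(3000, 0.0085, 0.03, gamma=0.0) == 0.0
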