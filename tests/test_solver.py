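"""Caputo integrator against analytic solutions and a classical reference."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.special import erfc

import fracprey as fp
from fracprey.solver import SolverSettings, integrate_caputo, mittag_leffler


def _decay(t, u):
    return -u


class TestMittagLeffler:
    def test_classical_exponential(self):
        assert mittag_leffler(1.0, -1.0) == pytest.approx(math.exp(-1), abs=1e-12)

    def test_half_order_erfc_identity(self):
        # E_{1/2}(-x) = exp(x^2) * erfc(x)
        assert mittag_leffler(0.5, -1.0) == pytest.approx(math.e * erfc(1.0), abs=1e-12)

    def test_two_parameter_at_origin(self):
        for theta in (0.3, 0.7, 1.0):
            assert mittag_leffler(theta, 0.0, beta=2.0) == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mittag_leffler(1.5, -1.0)
        with pytest.raises(ValueError):
            mittag_leffler(0.5, -100.0)


class TestScalarCaputo:
    def test_half_order_linear_decay(self):
        t, u, _ = integrate_caputo(_decay, [1.0], 0.5, SolverSettings(h=1 / 2048, t_end=1.0))
        assert abs(u[-1, 0] - math.e * erfc(1.0)) < 2e-4

    def test_constant_forcing_power_law(self):
        # D^theta u = 1, u(0) = 0 has u(t) = t^theta / Gamma(theta + 1)
        t, u, _ = integrate_caputo(
            lambda t, u: np.ones_like(u), [0.0], 0.5, SolverSettings(h=1 / 2048, t_end=1.0)
        )
        assert abs(u[-1, 0] - 1 / math.gamma(1.5)) < 1e-4

    def test_classical_limit_exponential(self):
        t, u, _ = integrate_caputo(_decay, [1.0], 1.0, SolverSettings(h=1e-3, t_end=1.0))
        assert abs(u[-1, 0] - math.exp(-1)) < 1e-6

    @pytest.mark.parametrize("theta", [0.5, 0.78, 0.9])
    def test_convergence_order_at_least_one(self, theta):
        exact = mittag_leffler(theta, -1.0)
        errs = []
        for h in (1 / 512, 1 / 1024):
            _, u, _ = integrate_caputo(_decay, [1.0], theta, SolverSettings(h=h, t_end=1.0))
            errs.append(abs(u[-1, 0] - exact))
        assert math.log2(errs[0] / errs[1]) >= 1.0

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            integrate_caputo(_decay, [1.0], 1.2, SolverSettings(h=0.1, t_end=1.0))

    def test_nonfinite_blowup_reported(self):
        with pytest.raises(ArithmeticError, match="step"), np.errstate(over="ignore", invalid="ignore"):
            integrate_caputo(lambda t, u: u * u, [5.0], 0.9, SolverSettings(h=0.5, t_end=40.0))


class TestModelTrajectories:
    def test_grid_and_initial_state(self, ex71):
        traj = fp.integrate(ex71, 0.78, (0.3, 0.15), SolverSettings(h=0.05, t_end=10.0))
        assert traj.t[0] == 0.0
        assert np.allclose(np.diff(traj.t), 0.05, atol=1e-12)
        assert tuple(traj.states[0]) == (0.3, 0.15)
        assert (traj.states >= 0).all()

    def test_equilibrium_fidelity(self, ex71):
        # starting exactly at coexistence the path must stay there
        eq = fp.interior_equilibrium(ex71)
        for theta in (0.5, 0.9, 1.0):
            traj = fp.integrate(ex71, theta, eq.as_tuple(), SolverSettings(h=0.05, t_end=100.0))
            dev = np.abs(traj.states - np.array(eq.as_tuple())).max()
            assert dev < 1e-6
            assert traj.clamped_count == 0

    def test_classical_limit_matches_reference(self, ex71):
        # theta = 1 against a tight adaptive RK reference over [0, 50]
        traj = fp.integrate(ex71, 1.0, (0.3, 0.15), SolverSettings(h=1e-3, t_end=50.0))
        sol = solve_ivp(
            lambda t, u: fp.rhs(ex71, (max(u[0], 0.0), max(u[1], 0.0))),
            [0, 50],
            [0.3, 0.15],
            rtol=1e-10,
            atol=1e-12,
            dense_output=True,
        )
        idx = np.arange(0, traj.t.size, 50)
        ref = sol.sol(traj.t[idx]).T
        assert np.abs(traj.states[idx] - ref).max() < 1e-3

    def test_negative_initial_state_rejected(self, ex71):
        with pytest.raises(ValueError):
            fp.integrate(ex71, 0.8, (-0.1, 0.2))

    def test_no_clamping_on_resolved_example_run(self, ex71):
        # within the coexistence basin and adequately resolved, positivity
        # holds without the guard firing
        traj = fp.integrate(ex71, 0.78, (0.3, 0.3), SolverSettings(h=0.0125, t_end=200.0))
        assert traj.clamped_count == 0

    def test_biomass_bound_eventually_holds(self, ex71):
        traj = fp.integrate(ex71, 0.9, (0.3, 0.15), SolverSettings(h=0.05, t_end=500.0))
        biomass = ex71.gamma4 * traj.u1 + traj.u2
        tail = biomass[traj.t > 250]
        assert tail.max() <= fp.asymptotic_bound(ex71, "corrected") * 1.05


class TestOscillationStats:
    def _fake(self, t, u1, u2, theta=0.9):
        return fp.Trajectory(
            t=t,
            states=np.column_stack([u1, u2]),
            theta=theta,
            settings=SolverSettings(h=float(t[1] - t[0]), t_end=float(t[-1])),
        )

    def test_constant_trajectory_is_steady(self):
        t = np.linspace(0, 100, 2001)
        st = fp.oscillation_stats(self._fake(t, np.full_like(t, 0.4), np.full_like(t, 0.1)))
        assert st.amp_u1 == 0.0 and st.amp_u2 == 0.0
        assert st.label == "damped/steady"

    def test_recovers_injected_sinusoid(self):
        t = np.linspace(0, 200, 8001)
        u1 = 0.4 + 0.3 * np.sin(2 * np.pi * t / 17.0)
        st = fp.oscillation_stats(self._fake(t, u1, np.full_like(t, 0.1)))
        assert st.amp_u1 == pytest.approx(0.3, rel=0.02)
        assert st.period == pytest.approx(17.0, rel=0.02)
        assert st.label == "oscillatory"

    def test_short_trajectory_rejected(self):
        t = np.linspace(0, 1, 5)
        with pytest.raises(ValueError):
            fp.oscillation_stats(self._fake(t, t, t))

    def test_amplitude_contrast_across_critical_order(self):
        # a Hopf-capable set rings up above theta0 and settles below it
        from fracprey.scenarios import ScenarioSpec, generate

        s = generate(ScenarioSpec(regime="hopf_capable", seed=29), 1)[0]
        eq = fp.interior_equilibrium(s.params)
        u0 = (eq.u1 * 1.05, eq.u2 * 1.05)
        cfg = SolverSettings(h=0.05, t_end=400.0)
        lo = fp.oscillation_stats(fp.integrate(s.params, s.theta0 - 0.05, u0, cfg))
        hi = fp.oscillation_stats(fp.integrate(s.params, s.theta0 + 0.05, u0, cfg))
        assert hi.amp_u1 > 10 * lo.amp_u1
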