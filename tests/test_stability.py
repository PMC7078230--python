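"""Jacobian evaluation and fractional stability classification."""

import math

import numpy as np
import pytest

import fracprey as fp
from fracprey.model import ModelParams
from fracprey.scenarios import ScenarioSpec, generate
from fracprey.stability import JacobianEval, matignon_classify, theorem_classify


class TestJacobian:
    def test_extinction_limit_matrix(self, ex71):
        J = fp.jacobian(ex71, (0.0, 0.0))
        assert J.a11 == pytest.approx(1 - 0.2 / 0.3)
        assert J.a22 == pytest.approx(-0.2)
        assert J.a12 == J.a21 == 0.0

    def test_predator_entry_vanishes_at_coexistence(self, ex71):
        eq = fp.interior_equilibrium(ex71)
        J = fp.jacobian(ex71, eq.as_tuple())
        assert J.a22 == pytest.approx(0.0, abs=1e-15)

    def test_first_example_trace_determinant(self, ex71):
        eq = fp.interior_equilibrium(ex71)
        J = fp.jacobian(ex71, eq.as_tuple())
        assert J.alpha == pytest.approx(-0.015496, abs=2e-6)
        assert J.beta == pytest.approx(0.015428, abs=2e-6)

    def test_singular_axis_refused(self, ex71):
        with pytest.raises(ValueError):
            fp.jacobian(ex71, (0.0, 0.5))


class TestMatignon:
    @pytest.mark.parametrize(
        "J, theta, label",
        [
            (JacobianEval(-1, 0, 0, -1), 0.5, "asymptotically_stable"),
            (JacobianEval(0, 1, -1, 0), 0.9, "asymptotically_stable"),  # pure rotation
            (JacobianEval(1, 0, 0, -1), 0.5, "saddle"),
            (JacobianEval(1, 0, 0, 2), 0.5, "unstable"),
        ],
    )
    def test_canonical_matrices(self, J, theta, label):
        assert matignon_classify(J, theta).label == label

    def test_critical_ray_is_inconclusive(self):
        # eigenvalues 1 +/- i have |arg| = pi/4 = theta*pi/2 at theta = 1/2
        J = JacobianEval(1, -1, 1, 1)
        assert matignon_classify(J, 0.5).label == "inconclusive"

    def test_zero_eigenvalue_is_inconclusive(self):
        assert matignon_classify(JacobianEval(0, 0, 0, -1), 0.7).label == "inconclusive"

    def test_nonfinite_entries_rejected(self):
        with pytest.raises(ValueError):
            matignon_classify(JacobianEval(math.nan, 0, 0, -1), 0.5)

    def test_agreement_with_theorem_route(self):
        # the two independent classification routes agree away from
        # measure-zero boundaries, which must return inconclusive
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            J = JacobianEval(*rng.uniform(-2, 2, size=4))
            theta = rng.uniform(0.02, 1.0)
            m = matignon_classify(J, theta).label
            t = theorem_classify(J, theta)
            assert m == t or "inconclusive" in (m, t)


class TestEquilibriumClassifiers:
    def test_extinction_saddle_when_growth_beats_harvest(self, ex71):
        rep = fp.classify_zero_eq(ex71, 0.78)
        assert rep.label == "saddle"
        assert "gamma1 - rho1/rho3 > 0" in rep.theorem_branch

    def test_extinction_stable_under_heavy_harvest(self):
        p = ModelParams(1.0, 1.0, 0.2, 0.25, 1.0, 0.25, 1.0, 1.0, 0.5, 1.0)
        assert fp.classify_zero_eq(p, 0.5).label == "asymptotically_stable"

    def test_extinction_marginal_case(self):
        p = ModelParams(1.0, 1.0, 0.2, 0.25, 1.0, 0.25, 0.3, 1.0, 0.3, 1.0)
        assert fp.classify_zero_eq(p, 0.5).label == "inconclusive"

    def test_boundary_saddle_in_first_example(self, ex71):
        eqs = fp.boundary_equilibria(ex71)
        rep = fp.classify_boundary_eq(ex71, eqs[0], 0.78)
        assert rep.label == "saddle"
        # lambda2 = -gamma3 + gamma2*gamma4*u1^sigma > 0 lets the predator invade
        J = fp.jacobian(ex71, eqs[0].as_tuple())
        assert J.a11 < 0 < J.a22

    def test_boundary_wrong_class_rejected(self, ex71):
        eq = fp.interior_equilibrium(ex71)
        with pytest.raises(ValueError):
            fp.classify_boundary_eq(ex71, eq, 0.78)

    def test_interior_stable_in_first_example(self, ex71):
        rep = fp.classify_interior_eq(ex71, 0.78)
        assert rep.label == "asymptotically_stable"
        assert "alpha < 0" in rep.theorem_branch

    def test_interior_flips_across_critical_order(self):
        sets = generate(ScenarioSpec(regime="hopf_capable", seed=9), 10)
        for s in sets:
            below = fp.classify_interior_eq(s.params, s.theta0 - 0.01).label
            above = fp.classify_interior_eq(s.params, s.theta0 + 0.01).label
            assert below == "asymptotically_stable"
            assert above == "unstable"

    def test_wrappers_match_matignon(self):
        for s in generate(ScenarioSpec(regime="stable_focus", seed=21), 20):
            p = s.params
            theta = 0.7
            assert (
                fp.classify_zero_eq(p, theta).label
                == matignon_classify(fp.jacobian(p, (0, 0)), theta).label
            )
            eq = fp.interior_equilibrium(p)
            assert (
                fp.classify_interior_eq(p, theta).label
                == matignon_classify(fp.jacobian(p, eq.as_tuple()), theta).label
            )


class TestInteriorIdentities:
    def test_determinant_closed_form(self):
        # at coexistence a22 = 0, so beta = -a12*a21 =
        # sigma*gamma2^2*gamma4*u1*^(2 sigma - 1)*u2* > 0: never a saddle
        for regime in ("stable_focus", "stable_node", "hopf_capable"):
            for s in generate(ScenarioSpec(regime=regime, seed=13), 30):
                p = s.params
                eq = fp.interior_equilibrium(p)
                J = fp.jacobian(p, eq.as_tuple())
                closed = (
                    p.sigma * p.gamma2**2 * p.gamma4 * eq.u1 ** (2 * p.sigma - 1) * eq.u2
                )
                assert abs(J.a22) < 1e-12
                assert J.beta == pytest.approx(closed, abs=1e-12, rel=1e-9)
                assert J.beta > 0
                assert fp.classify_interior_eq(p, 0.5).label != "saddle"
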