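"""Linearised stability under the Matignon criterion.

For a Caputo system of order theta, an equilibrium is locally
asymptotically stable iff every Jacobian eigenvalue satisfies
|arg(lambda)| > theta*pi/2; it is a saddle when the arguments straddle
that ray, and unstable when some eigenvalue falls strictly inside it.
The classical Routh-Hurwitz picture is recovered at theta = 1.

Two independent routes are provided: :func:`matignon_classify` compares
eigenvalue arguments directly, while :func:`theorem_classify` runs the
sign/discriminant case analysis phrased in terms of the trace ``alpha``
and determinant ``beta``.  They agree away from measure-zero boundaries,
where both return ``"inconclusive"``.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

from .equilibria import Equilibrium, interior_equilibrium
from .model import ModelParams

__all__ = [
    "JacobianEval",
    "StabilityReport",
    "jacobian",
    "matignon_classify",
    "theorem_classify",
    "classify_zero_eq",
    "classify_boundary_eq",
    "classify_interior_eq",
]

ARG_TOL = 1e-10  # tolerance on |arg(lambda)| - theta*pi/2 comparisons
ZERO_EIG_TOL = 1e-12

LABELS = ("asymptotically_stable", "stable", "unstable", "saddle", "inconclusive")


@dataclass(frozen=True)
class JacobianEval:
    """A 2x2 Jacobian with trace/determinant derived on demand."""

    a11: float
    a12: float
    a21: float
    a22: float

    @property
    def alpha(self) -> float:
        """Trace."""
        return self.a11 + self.a22

    @property
    def beta(self) -> float:
        """Determinant."""
        return self.a11 * self.a22 - self.a12 * self.a21

    def eigenvalues(self) -> tuple[complex, complex]:
        """Closed-form eigenvalues (alpha +/- sqrt(alpha^2 - 4 beta))/2."""
        disc = complex(self.alpha * self.alpha - 4.0 * self.beta)
        sq = cmath.sqrt(disc)
        return ((self.alpha + sq) / 2.0, (self.alpha - sq) / 2.0)


@dataclass(frozen=True)
class StabilityReport:
    eigenvalues: tuple[complex, complex]
    args: tuple[float, float]  # principal arguments in (-pi, pi]
    threshold: float  # theta*pi/2
    label: str
    theorem_branch: str | None = None


def jacobian(params: ModelParams, state) -> JacobianEval:
    """Jacobian of the vector field at a state with u1 > 0, or at (0, 0).

    At the extinction state the matrix is the explicit limit
    diag(gamma1 - rho1/rho3, -gamma3).  For u1 = 0 with u2 > 0 the entry
    u1^(sigma-1) is singular (sigma < 1) and evaluation is refused.
    """
    u1, u2 = float(state[0]), float(state[1])
    p = params
    if u1 == 0.0 and u2 == 0.0:
        return JacobianEval(p.gamma1 - p.rho1 / p.rho3, 0.0, 0.0, -p.gamma3)
    if u1 <= 0.0:
        raise ValueError(
            "Jacobian requires u1 > 0 (u1^(sigma-1) is singular at u1 = 0)"
        )
    den = p.h_den0 + p.rho4 * u1
    a11 = (
        p.gamma1
        - 2.0 * p.gamma1 * u1 / p.kappa
        - p.gamma2 * p.sigma * u1 ** (p.sigma - 1.0) * u2
        - p.h_num * p.h_den0 / (den * den)
    )
    a12 = -p.gamma2 * u1**p.sigma
    a21 = p.sigma * p.c_pred_gain * u1 ** (p.sigma - 1.0) * u2
    a22 = -p.gamma3 + p.c_pred_gain * u1**p.sigma
    return JacobianEval(a11, a12, a21, a22)


def matignon_classify(
    J: JacobianEval, theta: float, theorem_branch: str | None = None
) -> StabilityReport:
    """Classify by direct comparison of eigenvalue arguments with theta*pi/2.

    Ties within ``ARG_TOL`` of the critical ray, and eigenvalues within
    ``ZERO_EIG_TOL`` of the origin (where the argument is undefined),
    yield ``"inconclusive"``.
    """
    _check_theta(theta)
    for entry in (J.a11, J.a12, J.a21, J.a22):
        if not math.isfinite(entry):
            raise ValueError("Jacobian entries must be finite")
    lam = J.eigenvalues()
    args = tuple(cmath.phase(v) for v in lam)
    thr = theta * math.pi / 2.0
    if any(abs(v) < ZERO_EIG_TOL for v in lam) or any(
        abs(abs(a) - thr) <= ARG_TOL for a in args
    ):
        label = "inconclusive"
    else:
        outside = [abs(a) > thr for a in args]
        if all(outside):
            label = "asymptotically_stable"
        elif not any(outside):
            label = "unstable"
        else:
            label = "saddle"
    return StabilityReport(lam, args, thr, label, theorem_branch)


def theorem_classify(J: JacobianEval, theta: float) -> str:
    """Trace/determinant case analysis equivalent to the Matignon test.

    Real-eigenvalue branches (alpha^2 - 4 beta >= 0) classify by the
    signs of the two real roots; the complex-pair branch compares theta
    with theta_c = (2/pi)*arctan(psi/vartheta) where vartheta = alpha/2,
    psi = sqrt(4 beta - alpha^2)/2.  Boundary cases (zero eigenvalue,
    theta exactly critical) return "inconclusive".
    """
    _check_theta(theta)
    alpha, beta = J.alpha, J.beta
    disc = alpha * alpha - 4.0 * beta
    if disc >= 0.0:
        sq = math.sqrt(disc)
        lam1, lam2 = (alpha + sq) / 2.0, (alpha - sq) / 2.0
        if abs(lam1) < ZERO_EIG_TOL or abs(lam2) < ZERO_EIG_TOL:
            return "inconclusive"
        if lam1 < 0 and lam2 < 0:
            return "asymptotically_stable"
        if lam1 > 0 and lam2 > 0:
            return "unstable"
        return "saddle"
    # complex-conjugate pair: |arg| = arctan2(psi, vartheta), never zero
    if abs(alpha) < ZERO_EIG_TOL:
        # pure imaginary pair: |arg| = pi/2 > theta*pi/2 for theta < 1
        if abs(theta - 1.0) * math.pi / 2.0 <= ARG_TOL:
            return "inconclusive"
        return "asymptotically_stable"
    psi = math.sqrt(-disc) / 2.0
    theta_c = (2.0 / math.pi) * math.atan2(psi, alpha / 2.0)
    if alpha < 0:
        return "asymptotically_stable"  # |arg| > pi/2
    if abs(theta - theta_c) * math.pi / 2.0 <= ARG_TOL:
        return "inconclusive"
    return "asymptotically_stable" if theta < theta_c else "unstable"


def classify_zero_eq(params: ModelParams, theta: float) -> StabilityReport:
    """Stability of the extinction state (0, 0).

    Asymptotically stable iff gamma1 - rho1/rho3 < 0 (harvest pressure
    exceeds intrinsic growth at low density); a saddle when positive.
    """
    delta = params.gamma1 - params.rho1 / params.rho3
    if delta < 0:
        branch = "extinction-stable: gamma1 - rho1/rho3 < 0"
    elif delta > 0:
        branch = "extinction-saddle: gamma1 - rho1/rho3 > 0"
    else:
        branch = "extinction-marginal: gamma1 - rho1/rho3 = 0"
    return matignon_classify(jacobian(params, (0.0, 0.0)), theta, branch)


def classify_boundary_eq(
    params: ModelParams, eq: Equilibrium, theta: float
) -> StabilityReport:
    """Stability of a predator-free state via the triangular Jacobian.

    The eigenvalues are the diagonal entries lambda1 = a11 and
    lambda2 = -gamma3 + gamma2*gamma4*u1^sigma.  Both negative gives
    asymptotic stability for every theta (the source case analysis pairs
    stability with lambda2 > 0, which a positive real eigenvalue rules
    out under Matignon; the sign-consistent generalisation is used and
    the sign pattern is recorded in ``theorem_branch``).
    """
    if eq.klass != "boundary":
        raise ValueError(f"expected a boundary equilibrium, got klass={eq.klass!r}")
    J = jacobian(params, eq.as_tuple())
    lam1, lam2 = J.a11, J.a22
    branch = f"boundary diag signs: lambda1 {_sign_word(lam1)}, lambda2 {_sign_word(lam2)}"
    return matignon_classify(J, theta, branch)


def classify_interior_eq(params: ModelParams, theta: float) -> StabilityReport:
    """Stability of the coexistence state via the (alpha, beta) case analysis.

    Stable whenever alpha <= 0; for alpha > 0 with a complex pair the
    fractional order decides, the flip occurring at
    theta_c = (2/pi)*arctan(sqrt(4 beta - alpha^2)/alpha).
    """
    eq = interior_equilibrium(params)
    if eq is None:
        raise ValueError("no interior equilibrium exists for these parameters")
    J = jacobian(params, eq.as_tuple())
    alpha, beta = J.alpha, J.beta
    disc = alpha * alpha - 4.0 * beta
    if alpha == 0.0:
        branch = "interior (i): alpha = 0, pure imaginary pair"
    elif alpha < 0 and disc >= 0:
        branch = "interior (ii): alpha < 0, real pair"
    elif alpha < 0:
        branch = "interior (iii): alpha < 0, complex pair"
    elif disc >= 0:
        branch = "interior unstable: alpha > 0, real pair"
    else:
        branch = "interior theta-dependent: alpha > 0, complex pair vs tan(theta*pi/2)"
    report = matignon_classify(J, theta, branch)
    # the theorem-style route must agree away from boundaries
    assert report.label == theorem_classify(J, theta) or report.label == "inconclusive"
    return report


def _sign_word(x: float) -> str:
    return "negative" if x < 0 else ("positive" if x > 0 else "zero")


def _check_theta(theta: float) -> None:
    if not (0.0 < theta <= 1.0):
        raise ValueError(f"fractional order theta must lie in (0, 1], got {theta}")
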