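"""Critical fractional order and Hopf machinery.

In a Caputo system the fractional order theta itself acts as a
bifurcation parameter: when the Jacobian at the coexistence state has a
complex-conjugate pair lambda = vartheta +/- i*psi with vartheta > 0,
the stability ray |arg(lambda)| = theta*pi/2 sweeps past the pair as
theta grows, and the crossing order

    theta0 = (2/pi) * arctan(psi / vartheta),
    vartheta = alpha/2,  psi = sqrt(4*beta - alpha^2)/2,

plays the role of the Hopf point.  The crossing function
p(theta) = theta*pi/2 - min_i |arg(lambda_i)| is affine in theta with
slope pi/2, so transversality holds identically.

A complex pair requires alpha^2 - 4*beta < 0; the positive-real-part
requirement is alpha > 0.  (The source theorem prints the discriminant
inequality with the opposite sign, contradicted by its own proof, which
takes a conjugate pair; the complex-pair reading is implemented and the
report records both conditions.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .equilibria import interior_equilibrium
from .model import ModelParams
from .stability import JacobianEval, ZERO_EIG_TOL, jacobian

__all__ = [
    "HopfAnalysis",
    "p_value",
    "transversality",
    "critical_order",
    "critical_order_from_trace_det",
    "scan_theta",
]


@dataclass(frozen=True)
class HopfAnalysis:
    """Trace/determinant data and the critical order, when one exists."""

    alpha: float
    beta: float
    disc: float  # alpha^2 - 4*beta
    vartheta_re: float  # alpha/2, real part of the pair
    psi: float  # sqrt(|alpha^2 - 4*beta|)/2, imaginary part magnitude
    applicable: bool  # complex pair with positive real part
    theta0: float | None  # critical order in (0, 1) when defined
    reason: str | None  # why not applicable / out of range
    condition_note: str = (
        "implemented condition: alpha > 0 and alpha^2 - 4*beta < 0 "
        "(complex pair, per the proof); printed condition states "
        "alpha^2 - 4*beta > 0"
    )


def p_value(theta: float, J: JacobianEval) -> float:
    """Crossing function p(theta) = theta*pi/2 - min_i |arg(lambda_i)|.

    Negative while every eigenvalue lies outside the stability ray,
    zero exactly at the critical order, positive beyond it.
    """
    if not (0.0 < theta <= 1.0):
        raise ValueError(f"fractional order theta must lie in (0, 1], got {theta}")
    lam = J.eigenvalues()
    if any(abs(v) < ZERO_EIG_TOL for v in lam):
        raise ValueError("p(theta) undefined for a zero eigenvalue")
    return theta * math.pi / 2.0 - min(abs(math.atan2(v.imag, v.real)) for v in lam)


def transversality(J: JacobianEval) -> float:
    """dp/dtheta at the crossing: identically pi/2 for any fixed Jacobian.

    Returned explicitly so the nondegeneracy condition of the fractional
    Hopf lemma is inspectable rather than implicit.
    """
    return math.pi / 2.0


def critical_order_from_trace_det(alpha: float, beta: float) -> HopfAnalysis:
    """Hopf analysis from a trace/determinant pair alone."""
    disc = alpha * alpha - 4.0 * beta
    psi = math.sqrt(abs(disc)) / 2.0
    vartheta = alpha / 2.0
    if disc >= 0.0:
        return HopfAnalysis(
            alpha, beta, disc, vartheta, psi, False, None,
            "eigenvalues are real (alpha^2 - 4*beta >= 0): no rotating pair",
        )
    if alpha <= 0.0:
        return HopfAnalysis(
            alpha, beta, disc, vartheta, psi, False, None,
            "complex pair has nonpositive real part (alpha <= 0): "
            "stable for every admissible order",
        )
    theta0 = (2.0 / math.pi) * math.atan2(psi, vartheta)
    if theta0 >= 1.0:
        # atan2 < pi/2 for vartheta > 0, so this is unreachable; kept as a guard
        return HopfAnalysis(
            alpha, beta, disc, vartheta, psi, True, None,
            "critical order outside admissible range (theta0 >= 1)",
        )
    return HopfAnalysis(alpha, beta, disc, vartheta, psi, True, theta0, None)


def critical_order(params: ModelParams) -> HopfAnalysis:
    """Hopf analysis at the coexistence equilibrium of a parameter set."""
    eq = interior_equilibrium(params)
    if eq is None:
        raise ValueError("no interior equilibrium exists for these parameters")
    J = jacobian(params, eq.as_tuple())
    return critical_order_from_trace_det(J.alpha, J.beta)


def scan_theta(J: JacobianEval, grid_step: float = 0.005, tol: float = 1e-9) -> float | None:
    """Numerical root of p(theta) on (0, 1) by grid search plus bisection.

    Serves as the independent oracle for the closed-form critical order.
    Returns None when p keeps one sign on the whole interval.
    """
    if not (0.0 < grid_step <= 0.01):
        raise ValueError(f"grid_step must lie in (0, 0.01], got {grid_step}")
    lo = grid_step
    p_lo = p_value(lo, J)
    if p_lo > 0.0:
        # root may already have passed: p -> -min|arg| <= 0 as theta -> 0+
        if p_value(1e-12, J) >= 0.0:
            return None  # min|arg| = 0: p positive on all of (0, 1)
        return float(brentq(lambda t: p_value(t, J), 1e-12, lo, xtol=tol))
    theta = lo
    while theta < 1.0 - 1e-12:
        nxt = min(theta + grid_step, 1.0)
        p_nxt = p_value(nxt, J)
        if p_lo == 0.0:
            return theta
        if p_lo * p_nxt < 0.0:
            return float(brentq(lambda t: p_value(t, J), theta, nxt, xtol=tol))
        theta, p_lo = nxt, p_nxt
    return None
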