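"""Closed-form equilibria of the harvested group-defense system.

Setting the vector field to zero gives three families of steady states:

* the extinction state (0, 0), always present;
* boundary states (u1, 0) with u1 > 0 solving the prey nullcline with no
  predators, a quadratic in u1;
* the coexistence (interior) state, whose prey coordinate comes from the
  predator nullcline ``u1* = (gamma3/(gamma2*gamma4))**(1/sigma)`` and
  whose predator coordinate follows by substitution into the prey
  nullcline.  It is admissible iff the resulting u2* is positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import ModelParams, rhs

__all__ = [
    "Equilibrium",
    "ExistenceReport",
    "boundary_equilibria",
    "interior_equilibrium",
    "all_equilibria",
    "existence_report",
    "printed_boundary_roots",
]

_RESIDUAL_TOL = 1e-9


@dataclass(frozen=True)
class Equilibrium:
    """A steady state with its class and existence provenance."""

    u1: float
    u2: float
    klass: str  # "zero" | "boundary" | "interior"
    admissible: bool
    provenance: str

    def as_tuple(self) -> tuple[float, float]:
        return (self.u1, self.u2)


@dataclass(frozen=True)
class ExistenceReport:
    """Existence bookkeeping for all equilibrium families.

    ``discriminant`` and ``branch`` follow the printed case analysis of
    the boundary-root quadratic normalised by gamma1*rho4*kappa;
    ``boundary_count`` counts the positivity-filtered roots actually
    admitted, which can differ from what the branch alone would suggest
    when a root is negative.
    """

    has_zero: bool
    boundary_count: int
    has_interior: bool
    discriminant: float
    threshold: float  # rho2*rho3/(rho4*kappa), compared against 1
    branch: int | None  # 2, 3 or 4 (boundary cases); None when outside them


def _verify(params: ModelParams, u1: float, u2: float) -> bool:
    f1, f2 = rhs(params, (u1, u2))
    return max(abs(f1), abs(f2)) < _RESIDUAL_TOL


def boundary_equilibria(params: ModelParams) -> list[Equilibrium]:
    """Predator-free steady states (u1, 0) with u1 > 0.

    Solves gamma1*(1 - u1/kappa) = rho1*rho2/(rho2*rho3 + rho4*u1),
    i.e. the monic quadratic (general kappa retained)

        u1**2 - (kappa - h_den0/rho4)*u1 - kappa*(h_den0 - h_num/gamma1)/rho4 = 0.

    Only real roots with u1 > 0 are returned, each verified to satisfy
    the vector field to 1e-9.
    """
    p = params
    b = -(p.kappa - p.h_den0 / p.rho4)
    c = -p.kappa * (p.h_den0 - p.h_num / p.gamma1) / p.rho4
    disc = b * b - 4.0 * c
    out: list[Equilibrium] = []
    if disc < 0:
        return out
    sq = math.sqrt(disc)
    roots = ((-b + sq) / 2.0, (-b - sq) / 2.0) if disc > 0 else ((-b / 2.0),)
    if disc == 0:
        roots = (-b / 2.0,)
    for i, r in enumerate(roots):
        if r > 0 and _verify(p, r, 0.0):
            out.append(
                Equilibrium(
                    u1=r,
                    u2=0.0,
                    klass="boundary",
                    admissible=True,
                    provenance=f"prey-nullcline quadratic root {'+-'[i]}",
                )
            )
    return out


def interior_equilibrium(params: ModelParams) -> Equilibrium | None:
    """Coexistence steady state, or None when the predator cannot persist.

    The prey coordinate solves the predator nullcline
    -gamma3 + gamma2*gamma4*u1^sigma = 0; the predator coordinate follows
    from the prey nullcline.  Admissible iff u2* > 0.
    """
    p = params
    u1 = (p.gamma3 / p.c_pred_gain) ** (1.0 / p.sigma)
    growth = p.gamma1 * (1.0 - u1 / p.kappa)
    harvest = p.h_num / (p.h_den0 + p.rho4 * u1)
    u2 = u1 ** (1.0 - p.sigma) * (growth - harvest) / p.gamma2
    if u2 <= 0:
        return None
    return Equilibrium(
        u1=u1,
        u2=u2,
        klass="interior",
        admissible=True,
        provenance="predator nullcline root substituted into prey nullcline",
    )


def zero_equilibrium() -> Equilibrium:
    return Equilibrium(0.0, 0.0, "zero", True, "extinction state (always present)")


def all_equilibria(params: ModelParams) -> list[Equilibrium]:
    """Every admissible equilibrium: zero, boundary, then interior."""
    out = [zero_equilibrium()]
    out.extend(boundary_equilibria(params))
    eq = interior_equilibrium(params)
    if eq is not None:
        out.append(eq)
    return out


def printed_boundary_roots(params: ModelParams) -> tuple[float, float]:
    """Boundary roots by the printed closed form (valid as printed at kappa=1).

    Kept as a regression oracle against :func:`boundary_equilibria`'s
    first-principles quadratic; the two agree identically when kappa = 1.
    """
    p = params
    s = 1.0 - p.h_den0 / (p.rho4 * p.kappa)
    disc = s * s - 4.0 * (p.h_num / (p.gamma1 * p.rho4 * p.kappa) - p.h_den0 / (p.rho4 * p.kappa))
    sq = math.sqrt(disc) if disc >= 0 else float("nan")
    return ((s + sq) / 2.0, (s - sq) / 2.0)


def existence_report(params: ModelParams, zero_tol: float = 1e-12) -> ExistenceReport:
    """Case analysis of which equilibrium families exist.

    The discriminant and the threshold h_den0/(rho4*kappa) < 1 assign the
    boundary-existence branch (2: none, 3: tangency/double root, 4: two
    roots); the count of positivity-filtered admissible boundary roots is
    reported alongside and may disagree with the branch when a formal
    root is nonpositive.
    """
    p = params
    s = 1.0 - p.h_den0 / (p.rho4 * p.kappa)
    disc = s * s - 4.0 * (p.h_num / (p.gamma1 * p.rho4 * p.kappa) - p.h_den0 / (p.rho4 * p.kappa))
    threshold = p.h_den0 / (p.rho4 * p.kappa)
    if disc < -zero_tol:
        branch: int | None = 2
    elif abs(disc) <= zero_tol:
        branch = 3 if threshold < 1.0 else None
    else:
        branch = 4 if threshold < 1.0 else None
    boundary = boundary_equilibria(p)
    return ExistenceReport(
        has_zero=True,
        boundary_count=len(boundary),
        has_interior=interior_equilibrium(p) is not None,
        discriminant=disc,
        threshold=threshold,
        branch=branch,
    )
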