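"""Model definition: parameters, vector field, and analytic constants.

The system describes a prey population ``u1`` with logistic growth and a
saturating (Michaelis-Menten) harvest, preyed upon by a predator ``u2``
whose functional response carries a group-defense exponent ``sigma``::

    D^theta u1 = gamma1*(1 - u1/kappa)*u1 - gamma2*u1^sigma*u2
                 - rho1*rho2*u1 / (rho2*rho3 + rho4*u1)
    D^theta u2 = -gamma3*u2 + gamma2*gamma4*u1^sigma*u2

where ``D^theta`` is the Caputo derivative of order ``theta`` in (0, 1].
With ``sigma < 1`` per-capita predation weakens at high prey density,
modelling collective anti-predator behaviour.

All harvesting behaviour enters only through the composite products
``rho1*rho2`` (numerator), ``rho2*rho3`` (half-saturation offset) and
``rho4``; :meth:`ModelParams.from_composites` exploits this to encode
parameterisations given directly in composite form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

__all__ = [
    "ModelParams",
    "rhs",
    "lipschitz_bound",
    "asymptotic_bound",
]

_PARAM_NAMES = (
    "gamma1",
    "gamma2",
    "gamma3",
    "gamma4",
    "kappa",
    "sigma",
    "rho1",
    "rho2",
    "rho3",
    "rho4",
)


@dataclass(frozen=True)
class ModelParams:
    """The ten positive model constants.

    Attributes
    ----------
    gamma1 : intrinsic prey growth rate (per time).
    gamma2 : predator search efficiency (per time per prey^sigma density).
    gamma3 : predator mortality (per time).
    gamma4 : biomass conversion coefficient (dimensionless).
    kappa : environmental carrying capacity (prey density).
    sigma : group-defense / aggregation exponent (dimensionless); any
        positive value is accepted, the worked examples use 0 < sigma < 1.
    rho1 : catchability.
    rho2 : harvesting effort.
    rho3, rho4 : harvesting shape constants.
    """

    gamma1: float
    gamma2: float
    gamma3: float
    gamma4: float
    kappa: float
    sigma: float
    rho1: float
    rho2: float
    rho3: float
    rho4: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)):
                raise TypeError(f"parameter {f.name!r} must be a real number")
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name!r} must be finite, got {v!r}")
            if v <= 0:
                raise ValueError(
                    f"parameter {f.name!r} must be strictly positive, got {v!r}"
                )
            object.__setattr__(self, f.name, float(v))

    # -- composite coefficients (read-only) ---------------------------------
    @property
    def c_pred_gain(self) -> float:
        """Predator gain coefficient gamma2*gamma4 on u1^sigma*u2."""
        return self.gamma2 * self.gamma4

    @property
    def h_num(self) -> float:
        """Harvest numerator product rho1*rho2."""
        return self.rho1 * self.rho2

    @property
    def h_den0(self) -> float:
        """Harvest half-saturation offset rho2*rho3."""
        return self.rho2 * self.rho3

    @classmethod
    def from_composites(
        cls,
        a: float,
        b: float,
        c_pred: float,
        c_gain: float,
        m: float,
        sigma: float,
        h_num: float,
        h_den0: float,
        rho4: float,
    ) -> "ModelParams":
        """Build from composite coefficients.

        ``a`` and ``b`` are the linear and quadratic prey-growth
        coefficients (``a = gamma1``, ``b = gamma1/kappa``), ``c_pred`` the
        predation coefficient gamma2, ``c_gain`` the predator gain
        gamma2*gamma4, ``m`` the predator mortality gamma3, ``h_num`` and
        ``h_den0`` the harvest products rho1*rho2 and rho2*rho3.  Since
        the dynamics depend on the rho's only through those products and
        rho4, the representative choice rho2 = 1 is used internally.
        """
        return cls(
            gamma1=a,
            gamma2=c_pred,
            gamma3=m,
            gamma4=c_gain / c_pred,
            kappa=a / b,
            sigma=sigma,
            rho1=h_num,
            rho2=1.0,
            rho3=h_den0,
            rho4=rho4,
        )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _PARAM_NAMES}


def _pow_sigma(u1: float, sigma: float) -> float:
    # continuous extension u1^sigma -> 0 as u1 -> 0+ (valid for any sigma > 0)
    if u1 == 0.0:
        return 0.0
    return u1**sigma


def rhs(params: ModelParams, state) -> tuple[float, float]:
    """Vector field (du1/dt, du2/dt) at a nonnegative state.

    ``state`` is any 2-sequence ``(u1, u2)``.  At ``u1 = 0`` the group-
    defense term ``u1^sigma`` is evaluated as 0 (continuous extension),
    so the whole closed nonnegative quadrant is admissible.
    """
    u1, u2 = float(state[0]), float(state[1])
    if u1 < 0:
        raise ValueError(f"prey density u1 must be nonnegative, got {u1}")
    if u2 < 0:
        raise ValueError(f"predator density u2 must be nonnegative, got {u2}")
    p = params
    u1s = _pow_sigma(u1, p.sigma)
    du1 = (
        p.gamma1 * (1.0 - u1 / p.kappa) * u1
        - p.gamma2 * u1s * u2
        - p.h_num * u1 / (p.h_den0 + p.rho4 * u1)
    )
    du2 = -p.gamma3 * u2 + p.c_pred_gain * u1s * u2
    return (du1, du2)


def lipschitz_bound(params: ModelParams, K: float) -> float:
    """Lipschitz constant of the vector field on the box max(|u1|,|u2|) < K.

    Computed term-by-term as

        |gamma1*(1 + K/kappa) + gamma2*K^sigma - rho1*rho2/(rho2*rho3 + rho4*K)|
        + K*(gamma1/kappa + gamma2*K^(sigma-1) + rho1*rho4/rho4)
        + 2*gamma2*gamma4*K^(sigma+1)

    The middle term's ``rho1*rho4/rho4`` factor is carried literally (it
    equals rho1); the constant is reported as-is and is never used by the
    solver or the stability analysis.
    """
    if K <= 0:
        raise ValueError(f"box radius K must be positive, got {K}")
    p = params
    term1 = abs(
        p.gamma1 * (1.0 + K / p.kappa)
        + p.gamma2 * K**p.sigma
        - p.h_num / (p.h_den0 + p.rho4 * K)
    )
    term2 = K * (
        p.gamma1 / p.kappa + p.gamma2 * K ** (p.sigma - 1.0) + p.rho1 * p.rho4 / p.rho4
    )
    term3 = 2.0 * p.c_pred_gain * K ** (p.sigma + 1.0)
    return term1 + term2 + term3


def asymptotic_bound(params: ModelParams, variant: str = "corrected") -> float:
    """Asymptotic bound on the weighted biomass U = gamma4*u1 + u2.

    variant="corrected" (default) returns

        gamma4*kappa*(gamma1 + gamma3)**2 / (4*gamma1*gamma3),

    the constant obtained by completing the square in the differential
    inequality D^theta U + gamma3*U <= M and dividing the forcing constant
    M = gamma4*kappa*(gamma1+gamma3)^2/(4*gamma1) by the decay rate gamma3
    (the standard Mittag-Leffler comparison limit M/gamma3).

    variant="as_printed" returns gamma4*(gamma1 + gamma3)**2/(4*kappa*gamma1),
    kept for fidelity with the source derivation even though it can fall
    below the equilibrium biomass itself and therefore cannot be an
    attracting bound; only the corrected variant is asserted against
    trajectories.
    """
    p = params
    if variant == "corrected":
        return p.gamma4 * p.kappa * (p.gamma1 + p.gamma3) ** 2 / (4.0 * p.gamma1 * p.gamma3)
    if variant == "as_printed":
        return p.gamma4 * (p.gamma1 + p.gamma3) ** 2 / (4.0 * p.kappa * p.gamma1)
    raise ValueError(f"unknown variant {variant!r}; use 'corrected' or 'as_printed'")
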