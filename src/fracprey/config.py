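"""Config parsing/writing and structured analysis reports.

Parameter configs are flat JSON or YAML documents in one of two styles:

* ten-constant style: keys gamma1..gamma4, kappa, sigma, rho1..rho4;
* composite style: keys a, b, c_pred, c_gain, m, sigma, h_num, h_den0,
  rho4 (linear/quadratic growth coefficients, predation coefficient,
  predator gain product, mortality, exponent, harvest products) --
  needed to encode parameterisations stated only in composite form.

Reports are deterministic, self-describing JSON: full-precision floats
(via Python repr, 17 significant digits) with 4-dp roundings alongside,
no timestamps in the payload.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .equilibria import all_equilibria, existence_report
from .hopf import critical_order
from .model import ModelParams
from .stability import (
    classify_boundary_eq,
    classify_interior_eq,
    classify_zero_eq,
    jacobian,
)

__all__ = ["load_params", "save_params", "run_report", "write_report"]

SCHEMA_VERSION = "1"

_TEN_KEYS = (
    "gamma1", "gamma2", "gamma3", "gamma4", "kappa",
    "sigma", "rho1", "rho2", "rho3", "rho4",
)
_COMPOSITE_KEYS = ("a", "b", "c_pred", "c_gain", "m", "sigma", "h_num", "h_den0", "rho4")


class ConfigError(ValueError):
    """Raised for malformed or incomplete parameter configs."""


def _read_document(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
    else:
        try:
            doc = json.loads(text)
        except json.JSONDecodeError:
            doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a flat key/value mapping")
    return doc


def params_from_dict(doc: dict) -> ModelParams:
    """Build ModelParams from either config style, naming missing keys."""
    keys = set(doc)
    if keys & set(_COMPOSITE_KEYS) - {"sigma", "rho4"}:
        missing = [k for k in _COMPOSITE_KEYS if k not in keys]
        if missing:
            raise ConfigError(f"composite-style config missing keys: {', '.join(missing)}")
        vals = {k: _as_number(doc, k) for k in _COMPOSITE_KEYS}
        return ModelParams.from_composites(**vals)
    missing = [k for k in _TEN_KEYS if k not in keys]
    if missing:
        raise ConfigError(f"config missing keys: {', '.join(missing)}")
    vals = {k: _as_number(doc, k) for k in _TEN_KEYS}
    try:
        return ModelParams(**vals)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def _as_number(doc: dict, key: str) -> float:
    v = doc[key]
    if not isinstance(v, (int, float)) or isinstance(v, bool):
        raise ConfigError(f"key {key!r} must be a number, got {v!r}")
    return float(v)


def load_params(path: str | Path) -> ModelParams:
    """Read a parameter config file (JSON or YAML, either style)."""
    return params_from_dict(_read_document(path))


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write a ten-constant config; format chosen by file extension."""
    path = Path(path)
    doc = params.as_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
    else:
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def _num(x: float) -> dict:
    return {"value": x, "rounded_4dp": round(x, 4)}


def _complex_pair(values) -> list[dict]:
    return [{"re": v.real, "im": v.imag} for v in values]


def run_report(params: ModelParams, theta: float) -> dict:
    """Full analysis bundle: existence, per-equilibrium stability, Hopf.

    The resolved parameter set is embedded so composite-style inputs
    stay auditable.
    """
    ex = existence_report(params)
    entries = []
    for eq in all_equilibria(params):
        if eq.klass == "zero":
            rep = classify_zero_eq(params, theta)
        elif eq.klass == "boundary":
            rep = classify_boundary_eq(params, eq, theta)
        else:
            rep = classify_interior_eq(params, theta)
        J = jacobian(params, eq.as_tuple())
        entries.append(
            {
                "class": eq.klass,
                "u1": _num(eq.u1),
                "u2": _num(eq.u2),
                "provenance": eq.provenance,
                "jacobian": {"a11": J.a11, "a12": J.a12, "a21": J.a21, "a22": J.a22},
                "trace": J.alpha,
                "determinant": J.beta,
                "eigenvalues": _complex_pair(rep.eigenvalues),
                "args": list(rep.args),
                "threshold": rep.threshold,
                "label": rep.label,
                "theorem_branch": rep.theorem_branch,
            }
        )
    hopf_block = None
    if ex.has_interior:
        ha = critical_order(params)
        hopf_block = {
            "alpha": ha.alpha,
            "beta": ha.beta,
            "disc": ha.disc,
            "vartheta_re": ha.vartheta_re,
            "psi": ha.psi,
            "applicable": ha.applicable,
            "theta0": ha.theta0,
            "reason": ha.reason,
            "condition_note": ha.condition_note,
        }
    return {
        "schema_version": SCHEMA_VERSION,
        "theta": theta,
        "params": params.as_dict(),
        "existence": {
            "has_zero": ex.has_zero,
            "boundary_count": ex.boundary_count,
            "has_interior": ex.has_interior,
            "discriminant": ex.discriminant,
            "threshold": ex.threshold,
            "branch": ex.branch,
        },
        "equilibria": entries,
        "hopf": hopf_block,
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
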