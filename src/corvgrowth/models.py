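"""Length-at-age growth models.

Five classic fish growth curves, each predicting total length (mm TL) at a
real-valued age (years): the specialised von Bertalanffy, Gompertz, logistic,
Schnute (the a != 0, b != 0 family) and Schnute-Richards models.  The first
three are asymptotic three-parameter curves; the Schnute model is a flexible
two-free-parameter curve pinned exactly to the observed age/length extremes;
the Schnute-Richards model adds enough shape freedom to describe biphasic
(two-phase) growth.

Parameterisations
-----------------
von Bertalanffy:    L(t) = L_inf * (1 - exp(-K (t - t0)))
Gompertz (printed): L(t) = L_inf * exp(-(1/K) * exp(-K (t - t0)))
Gompertz (standard):L(t) = L_inf * exp(-exp(-K (t - t0)))
logistic:           L(t) = L_inf / (1 + exp(-K (t - t_infl)))
Schnute:            L(t) = [L1^b + (L2^b - L1^b) *
                            (1 - exp(-a (t - T1))) / (1 - exp(-a (T2 - T1)))]^(1/b)
Schnute-Richards:   L(t) = L_inf * (1 + alpha * exp(-a t^c))^(1/b)

The Gompertz curve is offered in two algebraically distinct forms.  The
"printed" form carries a 1/K factor inside the outer exponential, so that
L(t0) = L_inf * exp(-1/K); the "standard" form is the textbook Gompertz with
L(t0) = L_inf / e.  The printed form is the default.  Which form to use is a
per-call flag because the parameter record is identical for both.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, fields, asdict
from typing import Union

import numpy as np

from .errors import ParameterError, UnsupportedCaseError

__all__ = [
    "GrowthModel",
    "VBParams",
    "GompertzParams",
    "LogisticParams",
    "SchnuteParams",
    "SRParams",
    "GrowthParams",
    "predict_length",
    "asymptotic_length",
    "make_params",
    "free_param_names",
    "criteria_k",
]


class GrowthModel(str, enum.Enum):
    """Enumerated identifiers for the five supported growth models."""

    VON_BERTALANFFY = "von_bertalanffy"
    GOMPERTZ = "gompertz"
    LOGISTIC = "logistic"
    SCHNUTE = "schnute"
    SCHNUTE_RICHARDS = "schnute_richards"

    @classmethod
    def coerce(cls, value: "GrowthModel | str") -> "GrowthModel":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            names = ", ".join(m.value for m in cls)
            raise ParameterError(
                f"unknown growth model {value!r}; admissible values: {names}"
            ) from None


@dataclass(frozen=True)
class VBParams:
    """von Bertalanffy parameters: asymptotic length L_inf (mm), growth rate
    K (1/y) and theoretical age at zero length t0 (y)."""

    L_inf: float
    K: float
    t0: float


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz parameters: L_inf (mm), rate K (1/y) and location t0 (y)."""

    L_inf: float
    K: float
    t0: float


@dataclass(frozen=True)
class LogisticParams:
    """Logistic parameters: L_inf (mm), rate K (1/y) and inflection age
    t_infl (y), where the curve passes through L_inf / 2."""

    L_inf: float
    K: float
    t_infl: float


@dataclass(frozen=True)
class SchnuteParams:
    """Schnute (a, b != 0) parameters.

    ``a`` (1/y) and ``b`` (dimensionless) are the free shape parameters;
    (T1, L1) and (T2, L2) are fixed endpoint constraints, conventionally the
    minimum and maximum observed age and length, through which the curve
    passes exactly.
    """

    a: float
    b: float
    T1: float
    T2: float
    L1: float
    L2: float


@dataclass(frozen=True)
class SRParams:
    """Schnute-Richards parameters: asymptote L_inf (mm), dimensionless
    alpha, b and c, and rate a (units y^-b)."""

    L_inf: float
    alpha: float
    a: float
    b: float
    c: float


GrowthParams = Union[VBParams, GompertzParams, LogisticParams, SchnuteParams, SRParams]

_PARAM_TYPES = {
    GrowthModel.VON_BERTALANFFY: VBParams,
    GrowthModel.GOMPERTZ: GompertzParams,
    GrowthModel.LOGISTIC: LogisticParams,
    GrowthModel.SCHNUTE: SchnuteParams,
    GrowthModel.SCHNUTE_RICHARDS: SRParams,
}

# Structural parameters estimated by least squares (Schnute's endpoints are
# data-derived constants, not free parameters).
_FREE_PARAMS = {
    GrowthModel.VON_BERTALANFFY: ("L_inf", "K", "t0"),
    GrowthModel.GOMPERTZ: ("L_inf", "K", "t0"),
    GrowthModel.LOGISTIC: ("L_inf", "K", "t_infl"),
    GrowthModel.SCHNUTE: ("a", "b"),
    GrowthModel.SCHNUTE_RICHARDS: ("L_inf", "alpha", "a", "b", "c"),
}


def free_param_names(model: GrowthModel | str) -> tuple[str, ...]:
    """Names of the structural parameters estimated for ``model``."""
    return _FREE_PARAMS[GrowthModel.coerce(model)]


def criteria_k(model: GrowthModel | str) -> int:
    """Parameter count used by the information criteria.

    Counts the free structural parameters plus one for the residual variance,
    giving k = 4 for von Bertalanffy / Gompertz / logistic, 3 for Schnute and
    6 for Schnute-Richards.
    """
    return len(free_param_names(model)) + 1


def param_type(model: GrowthModel | str):
    return _PARAM_TYPES[GrowthModel.coerce(model)]


def make_params(model: GrowthModel | str, **values: float) -> GrowthParams:
    """Build the typed parameter record for ``model`` from keyword values."""
    cls = param_type(model)
    names = {f.name for f in fields(cls)}
    extra = set(values) - names
    missing = names - set(values)
    if extra or missing:
        raise ParameterError(
            f"{GrowthModel.coerce(model).value} expects parameters "
            f"{sorted(names)}; got extra {sorted(extra)}, missing {sorted(missing)}"
        )
    return cls(**values)


def _check(model: GrowthModel, params: GrowthParams) -> None:
    expected = _PARAM_TYPES[model]
    if not isinstance(params, expected):
        raise ParameterError(
            f"model {model.value} requires {expected.__name__}, "
            f"got {type(params).__name__}"
        )
    if model is GrowthModel.SCHNUTE and (params.a == 0 or params.b == 0):
        raise UnsupportedCaseError(
            "only the Schnute curve family with a != 0 and b != 0 is implemented"
        )
    if model is GrowthModel.SCHNUTE_RICHARDS and params.b == 0:
        raise UnsupportedCaseError("Schnute-Richards with b = 0 is not defined")


def predict_length(
    model: GrowthModel | str,
    params: GrowthParams,
    age,
    *,
    gompertz_form: str = "printed",
):
    """Predict length (mm) at ``age`` (years) under ``model``.

    ``age`` may be a scalar or array-like; arrays are evaluated element-wise
    preserving order and a scalar input returns a float.

    ``gompertz_form`` selects between the two Gompertz parameterisations
    (``"printed"``, the default, carries the 1/K factor; ``"standard"`` is
    the textbook form) and is ignored for the other models.
    """
    model = GrowthModel.coerce(model)
    _check(model, params)
    t = np.asarray(age, dtype=float)
    scalar = t.ndim == 0

    if model is GrowthModel.VON_BERTALANFFY:
        L = params.L_inf * (1.0 - np.exp(-params.K * (t - params.t0)))
    elif model is GrowthModel.GOMPERTZ:
        inner = np.exp(-params.K * (t - params.t0))
        if gompertz_form == "printed":
            L = params.L_inf * np.exp(-inner / params.K)
        elif gompertz_form == "standard":
            L = params.L_inf * np.exp(-inner)
        else:
            raise ParameterError(
                f"gompertz_form must be 'printed' or 'standard', got {gompertz_form!r}"
            )
    elif model is GrowthModel.LOGISTIC:
        L = params.L_inf / (1.0 + np.exp(-params.K * (t - params.t_infl)))
    elif model is GrowthModel.SCHNUTE:
        p = params
        l1b = p.L1 ** p.b
        l2b = p.L2 ** p.b
        frac = -np.expm1(-p.a * (t - p.T1)) / -math.expm1(-p.a * (p.T2 - p.T1))
        core = l1b + (l2b - l1b) * frac
        # core can dip below zero for extreme (a, b) outside the data range
        L = np.sign(core) * np.abs(core) ** (1.0 / p.b)
    else:  # Schnute-Richards
        p = params
        L = p.L_inf * (1.0 + p.alpha * np.exp(-p.a * t ** p.c)) ** (1.0 / p.b)

    return float(L) if scalar else L


def asymptotic_length(model: GrowthModel | str, params: GrowthParams):
    """Asymptotic length L_inf (mm), or ``None`` where it is undefined.

    The von Bertalanffy, Gompertz, logistic and Schnute-Richards records carry
    L_inf explicitly.  The Schnute family's asymptote is a limit expression
    this package deliberately does not evaluate, so ``None`` is returned.
    """
    model = GrowthModel.coerce(model)
    _check(model, params)
    if model is GrowthModel.SCHNUTE:
        return None
    return params.L_inf


def params_to_dict(params: GrowthParams) -> dict[str, float]:
    return asdict(params)
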