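"""Nonlinear least-squares estimation of growth-model parameters.

Each model is fit by Levenberg-Marquardt (via lmfit's ``leastsq``) minimising
the sum of squared length residuals.  Box bounds keep the flexible models from
diverging: L_inf in (0, 3 * max observed length], rate parameters K / a in
(0, 10], the Schnute-Richards exponent c in (0, 10]; location and shape
parameters (t0, t_infl, b, alpha) are unbounded.

The Gaussian log-likelihood attached to each fit uses the maximum-likelihood
residual variance sigma2 = RSS / n and includes the 2*pi constant,

    log L = -(n / 2) * (ln(2 * pi * sigma2) + 1),

so absolute AICc / BIC values are comparable across software, not only their
differences.  The parameter count reported for the information criteria is
the number of free structural parameters plus one for the residual variance.

Because the flexible models have multimodal least-squares surfaces, fitting
supports seeded multi-start: the initial vector is perturbed multiplicatively
by log-normal factors (sd 0.2 on the log scale) and the lowest-RSS converged
solution wins.  Schnute-Richards defaults to 25 restarts, the others to 5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import lmfit

from .data import AgeLengthTable
from .errors import DomainError, FitConvergenceError, InputError
from .models import (
    GrowthModel,
    GrowthParams,
    SchnuteParams,
    free_param_names,
    criteria_k,
    make_params,
    params_to_dict,
    predict_length,
)

__all__ = [
    "GrowthFit",
    "ParamInterval",
    "default_initial_values",
    "fit_model",
    "confidence_intervals",
    "DEFAULT_RESTARTS",
]

DEFAULT_RESTARTS = {
    GrowthModel.SCHNUTE_RICHARDS: 25,
    GrowthModel.VON_BERTALANFFY: 5,
    GrowthModel.GOMPERTZ: 5,
    GrowthModel.LOGISTIC: 5,
    GrowthModel.SCHNUTE: 5,
}

_PERTURB_SD = 0.2  # log-scale sd of multiplicative restart perturbations


@dataclass(frozen=True)
class GrowthFit:
    """Result of fitting one growth model to one age-length table."""

    model: GrowthModel
    params: GrowthParams
    rss: float
    n: int
    log_lik: float
    k: int
    converged: bool
    n_restarts_used: int
    at_bounds: bool = False
    covar: np.ndarray | None = field(default=None, compare=False)
    data_provenance: str = "raw"

    @property
    def sigma2_hat(self) -> float:
        return self.rss / self.n

    def to_dict(self) -> dict:
        return {
            "model": self.model.value,
            "params": params_to_dict(self.params),
            "rss": self.rss,
            "n": self.n,
            "sigma2_hat": self.sigma2_hat,
            "log_lik": self.log_lik,
            "k": self.k,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "at_bounds": self.at_bounds,
            "data_provenance": self.data_provenance,
        }


@dataclass(frozen=True)
class ParamInterval:
    """A Wald confidence interval for one parameter; ``degenerate`` flags a
    singular or non-finite curvature instead of fabricating bounds."""

    estimate: float
    low: float
    high: float
    degenerate: bool = False


def gaussian_log_likelihood(rss: float, n: int) -> float:
    """Concentrated Gaussian log-likelihood at the least-squares optimum."""
    sigma2 = max(rss / n, 1e-300)  # guard exact zero-residual fits
    return -(n / 2.0) * (math.log(2.0 * math.pi * sigma2) + 1.0)


def default_initial_values(
    model: GrowthModel | str, data: AgeLengthTable
) -> GrowthParams:
    """Deterministic starting values derived from the data.

    L_inf starts at 1.05 * max observed length, rates at 0.3 / y, locations
    at 0; Schnute starts at (a, b) = (0.3, 1) with its endpoints fixed at the
    observed age/length extremes; Schnute-Richards at alpha = -0.9, a = 0.3,
    b = 0.1, c = 1.
    """
    model = GrowthModel.coerce(model)
    linf0 = 1.05 * data.length_max
    if model is GrowthModel.VON_BERTALANFFY or model is GrowthModel.GOMPERTZ:
        return make_params(model, L_inf=linf0, K=0.3, t0=0.0)
    if model is GrowthModel.LOGISTIC:
        return make_params(model, L_inf=linf0, K=0.3, t_infl=0.0)
    if model is GrowthModel.SCHNUTE:
        return SchnuteParams(
            a=0.3,
            b=1.0,
            T1=float(data.age_min),
            T2=float(data.age_max),
            L1=data.length_min,
            L2=data.length_max,
        )
    return make_params(
        model, L_inf=linf0, alpha=-0.9, a=0.3, b=0.1, c=1.0
    )


def _bounds(model: GrowthModel, name: str, data: AgeLengthTable):
    if name == "L_inf":
        return (1e-9, 3.0 * data.length_max)
    if name in ("K", "a"):
        return (1e-9, 10.0)
    if name == "c":
        return (1e-9, 10.0)
    return (-np.inf, np.inf)


def _lm_once(
    model: GrowthModel,
    data: AgeLengthTable,
    init: GrowthParams,
    gompertz_form: str,
):
    names = free_param_names(model)
    init_dict = params_to_dict(init)
    pars = lmfit.Parameters()
    for name in names:
        lo, hi = _bounds(model, name, data)
        value = float(np.clip(init_dict[name], lo, hi))
        pars.add(name, value=value, min=lo, max=hi)

    fixed = {k: v for k, v in init_dict.items() if k not in names}

    def residual(p):
        rec = make_params(model, **{n: p[n].value for n in names}, **fixed)
        pred = predict_length(model, rec, data.ages, gompertz_form=gompertz_form)
        return data.lengths - pred

    try:
        result = lmfit.minimize(residual, pars, method="leastsq")
    except Exception:
        return None
    values = {n: result.params[n].value for n in names}
    rec = make_params(model, **values, **fixed)
    rss = float(np.sum(np.square(residual(result.params))))
    at_bounds = any(
        math.isfinite(result.params[n].min)
        and (
            abs(values[n] - result.params[n].min)
            <= 1e-8 * max(1.0, abs(values[n]))
            or abs(values[n] - result.params[n].max)
            <= 1e-8 * max(1.0, abs(values[n]))
        )
        for n in names
    )
    covar = getattr(result, "covar", None)
    return rec, rss, bool(result.success), at_bounds, covar


def _perturb(init: GrowthParams, model: GrowthModel, rng: np.random.Generator):
    """Multiplicative log-normal perturbation of the free starting values."""
    names = free_param_names(model)
    d = params_to_dict(init)
    factors = np.exp(rng.normal(0.0, _PERTURB_SD, size=len(names)))
    for name, f in zip(names, factors):
        d[name] = d[name] * f
    return make_params(model, **d)


def fit_model(
    model: GrowthModel | str,
    data: AgeLengthTable,
    init: GrowthParams | None = None,
    restarts: int | None = None,
    seed: int = 0,
    gompertz_form: str = "printed",
) -> GrowthFit:
    """Fit ``model`` to ``data`` by Levenberg-Marquardt least squares.

    ``restarts`` >= 1 attempts are made: the first from ``init`` (or the
    default heuristics), the rest from seeded multiplicative perturbations of
    it.  The lowest-RSS converged attempt is returned.  Raises
    :class:`FitConvergenceError` (carrying the best attempt) if nothing
    converges.
    """
    model = GrowthModel.coerce(model)
    if restarts is None:
        restarts = DEFAULT_RESTARTS[model]
    if restarts < 1:
        raise InputError("restarts must be >= 1")
    k = criteria_k(model)
    n_support = np.unique(data.ages).size
    if n_support < k - 1:
        # need at least as many distinct ages as structural parameters
        raise InputError(
            f"{model.value} needs >= {k - 1} distinct ages; table has {n_support}"
        )
    if init is None:
        init = default_initial_values(model, data)

    rng = np.random.default_rng(seed)
    best = None  # (rss, rec, at_bounds, covar) among converged
    best_any = None  # among all attempts, for the error path
    used = 0
    for attempt in range(restarts):
        start = init if attempt == 0 else _perturb(init, model, rng)
        out = _lm_once(model, data, start, gompertz_form)
        used += 1
        if out is None:
            continue
        rec, rss, success, at_bounds, covar = out
        if best_any is None or rss < best_any[0]:
            best_any = (rss, rec, at_bounds, covar)
        if success and (best is None or rss < best[0]):
            best = (rss, rec, at_bounds, covar)

    if best is None:
        attempt_fit = None
        if best_any is not None:
            rss, rec, at_bounds, covar = best_any
            attempt_fit = GrowthFit(
                model=model,
                params=rec,
                rss=rss,
                n=data.n,
                log_lik=gaussian_log_likelihood(rss, data.n),
                k=k,
                converged=False,
                n_restarts_used=used,
                at_bounds=at_bounds,
                covar=covar,
                data_provenance=data.provenance,
            )
        raise FitConvergenceError(
            f"no restart of {model.value} converged in {used} attempts",
            best_attempt=attempt_fit,
        )

    rss, rec, at_bounds, covar = best
    return GrowthFit(
        model=model,
        params=rec,
        rss=rss,
        n=data.n,
        log_lik=gaussian_log_likelihood(rss, data.n),
        k=k,
        converged=True,
        n_restarts_used=used,
        at_bounds=at_bounds,
        covar=covar,
        data_provenance=data.provenance,
    )


def confidence_intervals(fit: GrowthFit, level: float = 0.95):
    """Wald confidence intervals from the least-squares curvature.

    Returns ``{name: ParamInterval}`` over the fit's free structural
    parameters.  Entries whose variance is unavailable or non-positive are
    flagged ``degenerate`` with infinite bounds rather than fabricated.
    """
    from scipy import stats

    if not fit.converged:
        raise InputError("confidence intervals require a converged fit")
    if not 0.0 < level < 1.0:
        raise DomainError("confidence level must lie in (0, 1)")
    names = free_param_names(fit.model)
    values = params_to_dict(fit.params)
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = {}
    covar = fit.covar
    for i, name in enumerate(names):
        est = values[name]
        var = None
        if covar is not None and covar.shape[0] == len(names):
            var = float(covar[i, i])
        if var is None or not math.isfinite(var) or var < 0:
            out[name] = ParamInterval(est, -math.inf, math.inf, degenerate=True)
        else:
            half = z * math.sqrt(var)
            out[name] = ParamInterval(est, est - half, est + half)
    return out


def refit_from(fit: GrowthFit, data: AgeLengthTable, **kwargs) -> GrowthFit:
    """Refit the same model using a previous fit's parameters as the start."""
    return fit_model(fit.model, data, init=fit.params, restarts=1, **kwargs)
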