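"""Information-criterion model comparison and Akaike-weight averaging.

Given Gaussian log-likelihoods, the criteria are

    AIC  = -2 log L + 2 k
    AICc = AIC + 2 k (k + 1) / (n - k - 1)
    BIC  = -2 log L + k ln(n)

with k the parameter count (structural parameters plus the residual
variance) and n the number of records.  AICc is the small-sample corrected
AIC and converges to it as n grows.  Akaike weights transform the AICc
differences Delta_i = AICc_i - min AICc into normalised model evidence,

    w_i = exp(-Delta_i / 2) / sum_k exp(-Delta_k / 2),

and support weight-based averaging of the asymptotic length across the
models that possess one.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InputError
from .fitting import GrowthFit
from .models import asymptotic_length

__all__ = [
    "aic",
    "aicc",
    "bic",
    "akaike_weights",
    "build_selection_table",
    "weighted_average_linf",
    "model_average_linf",
]


def aic(log_lik: float, k: int) -> float:
    return -2.0 * log_lik + 2.0 * k


def aicc(log_lik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; undefined unless n > k + 1."""
    if n <= k + 1:
        raise DomainError(f"AICc correction undefined for n={n}, k={k} (need n > k+1)")
    return aic(log_lik, k) + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def bic(log_lik: float, k: int, n: int) -> float:
    if n < 1:
        raise DomainError("BIC requires n >= 1")
    return -2.0 * log_lik + k * math.log(n)


def akaike_weights(deltas: Sequence[float]) -> np.ndarray:
    """Normalised evidence weights from AICc differences (min delta = 0)."""
    d = np.asarray(deltas, dtype=float)
    if d.size == 0:
        raise InputError("akaike_weights needs at least one delta")
    if np.any(d < 0) or not np.isclose(d.min(), 0.0):
        raise InputError("deltas must be >= 0 with at least one zero")
    ev = np.exp(-0.5 * d)
    return ev / ev.sum()


def build_selection_table(fits: Sequence[GrowthFit]) -> pd.DataFrame:
    """Assemble the per-model comparison table from fits to the same data.

    Columns: model, k, aicc, delta_aicc, weight, bic, delta_bic; rows sorted
    by ascending AICc with ties broken by smaller k, then model name.
    """
    if len(fits) == 0:
        raise InputError("no fits supplied")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise InputError(f"fits were made on differing record counts: {sorted(ns)}")
    n = ns.pop()
    rows = []
    for f in fits:
        rows.append(
            {
                "model": f.model.value,
                "k": f.k,
                "aicc": aicc(f.log_lik, f.k, n),
                "bic": bic(f.log_lik, f.k, n),
            }
        )
    table = pd.DataFrame(rows)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    table["delta_bic"] = table["bic"] - table["bic"].min()
    table = table.sort_values(
        ["aicc", "k", "model"], kind="mergesort", ignore_index=True
    )
    table["weight"] = akaike_weights(table["delta_aicc"].to_numpy())
    return table[["model", "k", "aicc", "delta_aicc", "weight", "bic", "delta_bic"]]


def weighted_average_linf(
    weights: Sequence[float],
    linf_values: Sequence[float],
    renormalize: bool = False,
) -> float:
    """Weighted average of asymptotic lengths.

    With ``renormalize=False`` this is the plain dot product, appropriate
    when the weights already sum to one (e.g. a published table of rounded
    weights).  With ``renormalize=True`` the weights are rescaled to sum to
    one first, appropriate after dropping models without an asymptote.
    """
    w = np.asarray(weights, dtype=float)
    linf = np.asarray(linf_values, dtype=float)
    if w.size == 0 or w.size != linf.size:
        raise InputError("weights and L_inf values must be non-empty, equal length")
    if renormalize:
        total = w.sum()
        if total <= 0:
            raise DomainError("weights sum to zero; nothing to average")
        w = w / total
    return float(w @ linf)


def model_average_linf(table: pd.DataFrame, fits: Sequence[GrowthFit]) -> float:
    """Akaike-weight model average of L_inf over the fitted models.

    Models without a defined asymptote (the Schnute family) are excluded and
    the remaining weights renormalised over that subset.
    """
    by_model = {f.model.value: f for f in fits}
    weights, linfs = [], []
    for _, row in table.iterrows():
        fit = by_model.get(row["model"])
        if fit is None:
            raise InputError(f"no fit supplied for model {row['model']!r}")
        linf = asymptotic_length(fit.model, fit.params)
        if linf is None:
            continue
        weights.append(row["weight"])
        linfs.append(linf)
    if not weights or sum(weights) <= 0:
        raise DomainError("all Akaike weight falls on models without a defined L_inf")
    return weighted_average_linf(weights, linfs, renormalize=True)
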