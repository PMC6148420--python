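"""Simple indicators of sampling bias in age-length data.

Fishery-dependent samples rarely cover every age and size class evenly:
size-selective gear and heavy exploitation leave old, large fish
under-represented, which drags fitted asymptotic lengths down and growth
rates up.  This module implements three cheap diagnostics:

* **Bolstering** — simulate the ideal sampling outcome by topping every
  observed age class up to an equal target count (default 200) with normal
  draws matching that class's observed mean and standard deviation, then
  refit; parameter shifts between raw and bolstered fits expose
  distribution-driven estimates.
* **Empirical L_inf check** — the Froese-Binohlan regression predicts
  L_inf from the largest fish in the sample,
  log10 L_inf = 0.044 + 0.9841 log10 L_max; a fitted L_inf far below it
  flags missing large fish.
* **Frequency histograms** — length (10 mm bins) and age (unit bins)
  frequencies; bimodality signals a mixture of sampling sources rather than
  population structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import AgeLengthTable
from .errors import DomainError, InputError

__all__ = [
    "per_age_stats",
    "bolster_dataset",
    "froese_binohlan_linf",
    "frequency_histogram",
]


def per_age_stats(data: AgeLengthTable) -> pd.DataFrame:
    """Per-age-class sample size, mean length and SD (n-1 denominator).

    Classes with a single record get ``sd_length = NaN`` — a flagged
    undefined value, never a fabricated zero.
    """
    frame = data.to_frame()
    stats = (
        frame.groupby("age")["length_mm"]
        .agg(n_obs="size", mean_length="mean", sd_length=lambda s: s.std(ddof=1))
        .reset_index()
    )
    return stats


def bolster_dataset(
    data: AgeLengthTable, target_per_age: int = 200, seed: int = 0
) -> AgeLengthTable:
    """Top every observed age class up to ``target_per_age`` records.

    Simulated lengths are drawn from Normal(mean_age, sd_age) of the raw
    class; non-positive draws are rejected and redrawn.  Original records are
    preserved verbatim as a prefix of the output, whose provenance is tagged
    ``"bolstered"``.  Downsampling is refused: the target must be at least
    the largest existing class count.
    """
    stats = per_age_stats(data)
    if int(stats["n_obs"].max()) > target_per_age:
        raise InputError(
            f"target_per_age={target_per_age} is below an existing class count "
            f"({int(stats['n_obs'].max())}); downsampling is not supported"
        )
    deficient = stats[stats["n_obs"] < target_per_age]
    bad = deficient[~np.isfinite(deficient["sd_length"])]
    if len(bad):
        ages = bad["age"].tolist()
        raise InputError(
            f"age classes {ages} have a single record, so their SD is undefined; "
            "merge classes or supply an SD before bolstering"
        )
    rng = np.random.default_rng(seed)
    new_ages = [data.ages]
    new_lengths = [data.lengths]
    for _, row in stats.iterrows():
        deficit = target_per_age - int(row["n_obs"])
        if deficit == 0:
            continue
        draws = rng.normal(row["mean_length"], row["sd_length"], size=deficit)
        while np.any(draws <= 0):  # lengths are physical: reject and redraw
            bad_mask = draws <= 0
            draws[bad_mask] = rng.normal(
                row["mean_length"], row["sd_length"], size=int(bad_mask.sum())
            )
        new_ages.append(np.full(deficit, int(row["age"])))
        new_lengths.append(draws)
    return AgeLengthTable(
        ages=np.concatenate(new_ages),
        lengths=np.concatenate(new_lengths),
        provenance="bolstered",
        max_age=data.max_age,
    )


def froese_binohlan_linf(l_max: float) -> float:
    """Empirical asymptotic length predicted from the largest sampled fish.

    Evaluates 10^(0.044 + 0.9841 * log10(L_max)), in mm.
    """
    if not l_max > 0:
        raise DomainError("L_max must be positive")
    return 10.0 ** (0.044 + 0.9841 * np.log10(l_max))


def frequency_histogram(
    data: AgeLengthTable, variable: str = "length", bin_width: float = 10.0
) -> pd.DataFrame:
    """Binned frequency of lengths or ages.

    Length bins are left-closed right-open, anchored at zero, with width
    ``bin_width`` mm (default 10); ages use unit integer bins.  Returns a
    two-column frame (bin_left, count) whose counts sum to n.
    """
    if variable == "length":
        if not bin_width > 0:
            raise InputError("bin_width must be positive")
        values = data.lengths
        width = float(bin_width)
    elif variable == "age":
        values = data.ages.astype(float)
        width = 1.0
    else:
        raise InputError(f"variable must be 'length' or 'age', got {variable!r}")
    idx = np.floor(values / width).astype(int)
    left_edges = np.arange(idx.min(), idx.max() + 1) * width
    counts = np.bincount(idx - idx.min(), minlength=left_edges.size)
    return pd.DataFrame({"bin_left": left_edges, "count": counts})
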