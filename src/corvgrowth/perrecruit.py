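"""Per-recruit yield and female spawning-biomass model.

A discrete annual cohort model tracks the relative numbers N_a of a single
recruit's cohort from age 1 to a maximum age A_max, under a constant natural
mortality rate M (1/y) and stage-specific annual exploitation rates
(harvested fractions per year): zero before the maturity age a_R, E_YA for
young adults (a_R <= a < a_OA) and E_OA for old adults (a >= a_OA).  By
default harvest is taken at the start of the year, before natural mortality,
so the recursion is

    N_1 = 1,    N_{a+1} = N_a * (1 - u_a) * exp(-M).

Yield-per-recruit (YPR) is the lifetime harvested biomass of the cohort,
sum_a N_a * u_a * W_a; female spawning-stock-biomass-per-recruit (SSBR) is
the female fraction of post-harvest adult biomass,
f * sum_{a >= a_R} N_a * (1 - u_a) * W_a.  NSSBR is SSBR with no fishing and
FNSSBR = SSBR / NSSBR is the depletion ratio used as a reproductive-capacity
reference point.  Weight-at-age comes from a length-weight power law
W = lw_a * L(age)^lw_b applied to any configured growth scenario, so the
consequences of choosing one growth model over another propagate directly
into the assessment quantities.

Both orderings (harvest before or after natural mortality, spawning measured
pre- or post-harvest) are switchable by config flags; the defaults reflect a
fishery that targets spawning aggregations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .models import GrowthModel, GrowthParams, predict_length

__all__ = [
    "PerRecruitConfig",
    "PerRecruitCurves",
    "weight_at_age",
    "survivorship_schedule",
    "ypr",
    "ssbr",
    "per_recruit_curves",
    "compare_growth_scenarios",
]

_DEMOGRAPHIC_FIELDS = (
    "a_R",
    "a_OA",
    "A_max",
    "M",
    "E_OA",
    "E_YA",
    "female_fraction",
    "lw_a",
    "lw_b",
    "harvest_before_M",
    "spawn_after_harvest",
)


@dataclass(frozen=True)
class PerRecruitConfig:
    """Demographic schedule plus a growth scenario.

    ``M``, ``lw_a`` and ``lw_b`` have no universal defaults and must be
    supplied explicitly; the package never invents them.
    """

    M: float  # natural mortality rate, 1/y
    lw_a: float  # weight-length coefficient (kg per mm^lw_b)
    lw_b: float  # weight-length exponent
    growth: tuple[GrowthModel, GrowthParams]
    E_OA: float = 0.825  # annual exploitation rate of old adults
    E_YA: float = 0.0  # annual exploitation rate of young adults
    a_R: int = 2  # age at sexual maturity, y
    a_OA: int = 5  # age at transition to the old-adult stage, y
    A_max: int = 8  # maximum modelled age, y
    female_fraction: float = 0.5
    harvest_before_M: bool = True
    spawn_after_harvest: bool = True
    gompertz_form: str = "printed"

    def __post_init__(self):
        if not (1 <= self.a_R <= self.a_OA <= self.A_max):
            raise InputError("require 1 <= a_R <= a_OA <= A_max")
        for name in ("E_OA", "E_YA", "female_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must lie in [0, 1], got {v}")
        if self.M < 0:
            raise InputError("M must be >= 0")
        model, params = self.growth
        object.__setattr__(self, "growth", (GrowthModel.coerce(model), params))

    def exploitation_at_age(self, age: int, E_OA: float | None = None) -> float:
        e_oa = self.E_OA if E_OA is None else E_OA
        if age < self.a_R:
            return 0.0
        if age < self.a_OA:
            return self.E_YA
        return e_oa


@dataclass(frozen=True)
class PerRecruitCurves:
    """YPR and SSBR evaluated over a grid of old-adult exploitation rates."""

    E_grid: np.ndarray
    ypr: np.ndarray
    ssbr: np.ndarray
    nssbr: float
    fnssbr: np.ndarray
    ypr_max: float
    E_at_ypr_max: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "E_OA": self.E_grid,
                "YPR": self.ypr,
                "SSBR": self.ssbr,
                "FNSSBR": self.fnssbr,
            }
        )


def weight_at_age(cfg: PerRecruitConfig, age) -> float | np.ndarray:
    """Body weight at age under the configured growth scenario (power law)."""
    model, params = cfg.growth
    length = predict_length(model, params, age, gompertz_form=cfg.gompertz_form)
    length = np.maximum(length, 0.0)  # negative predicted lengths clamp to 0
    return cfg.lw_a * length ** cfg.lw_b


def survivorship_schedule(
    cfg: PerRecruitConfig, E_OA: float | None = None
) -> np.ndarray:
    """Relative numbers-at-age N_a for a = 1 .. A_max, with N_1 = 1."""
    ages = np.arange(1, cfg.A_max + 1)
    n = np.empty(cfg.A_max)
    n[0] = 1.0
    for i, age in enumerate(ages[:-1]):
        u = cfg.exploitation_at_age(int(age), E_OA)
        n[i + 1] = n[i] * (1.0 - u) * np.exp(-cfg.M)
    return n


def ypr(cfg: PerRecruitConfig, E_OA: float | None = None) -> float:
    """Yield-per-recruit (biomass) at the given old-adult exploitation rate."""
    n = survivorship_schedule(cfg, E_OA)
    total = 0.0
    for i, age in enumerate(range(1, cfg.A_max + 1)):
        u = cfg.exploitation_at_age(age, E_OA)
        if u == 0.0:
            continue
        exposed = n[i] if cfg.harvest_before_M else n[i] * np.exp(-cfg.M)
        total += exposed * u * float(weight_at_age(cfg, age))
    return total


def ssbr(cfg: PerRecruitConfig, E_OA: float | None = None) -> float:
    """Female spawning-stock biomass per recruit at the given rate."""
    n = survivorship_schedule(cfg, E_OA)
    total = 0.0
    for i, age in enumerate(range(1, cfg.A_max + 1)):
        if age < cfg.a_R:
            continue
        u = cfg.exploitation_at_age(age, E_OA)
        survivors = n[i] * (1.0 - u) if cfg.spawn_after_harvest else n[i]
        total += survivors * float(weight_at_age(cfg, age))
    return cfg.female_fraction * total


def per_recruit_curves(
    cfg: PerRecruitConfig, E_grid: np.ndarray | None = None, step: float = 0.005
) -> PerRecruitCurves:
    """Evaluate YPR, SSBR and FNSSBR over a grid of exploitation rates.

    The default grid spans [0, 1] with step 0.005; YPR_max and its argmax are
    located by grid scan, bounding the argmax error by half a step.  The grid
    must include 0, where the no-fishing spawning biomass NSSBR is taken.
    """
    if E_grid is None:
        E_grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    E_grid = np.asarray(E_grid, dtype=float)
    if not np.any(E_grid == 0.0):
        raise InputError("E_grid must include 0 (NSSBR is undefined otherwise)")
    ypr_vals = np.array([ypr(cfg, e) for e in E_grid])
    ssbr_vals = np.array([ssbr(cfg, e) for e in E_grid])
    nssbr = float(ssbr_vals[E_grid == 0.0][0])
    fnssbr = ssbr_vals / nssbr if nssbr > 0 else np.full_like(ssbr_vals, np.nan)
    imax = int(np.argmax(ypr_vals))
    return PerRecruitCurves(
        E_grid=E_grid,
        ypr=ypr_vals,
        ssbr=ssbr_vals,
        nssbr=nssbr,
        fnssbr=fnssbr,
        ypr_max=float(ypr_vals[imax]),
        E_at_ypr_max=float(E_grid[imax]),
    )


def compare_growth_scenarios(
    cfgs: dict[str, PerRecruitConfig],
    E_current: float,
    step: float = 0.005,
) -> pd.DataFrame:
    """Current FNSSBR and YPR / YPR_max per growth scenario.

    All configs must share identical demographic fields; only the growth
    scenario may differ.  Returns one row per scenario, in input order.
    """
    if not cfgs:
        raise InputError("no scenarios supplied")
    ref = next(iter(cfgs.values()))
    for name, cfg in cfgs.items():
        for f in _DEMOGRAPHIC_FIELDS:
            if getattr(cfg, f) != getattr(ref, f):
                raise InputError(
                    f"scenario {name!r} differs from the others in "
                    f"demographic field {f!r}; only growth may vary"
                )
    rows = []
    for name, cfg in cfgs.items():
        curves = per_recruit_curves(cfg, step=step)
        cur_ypr = ypr(cfg, E_current)
        cur_ssbr = ssbr(cfg, E_current)
        rows.append(
            {
                "scenario": name,
                "fnssbr": cur_ssbr / curves.nssbr,
                "ypr_over_ypr_max": cur_ypr / curves.ypr_max,
                "ypr_max": curves.ypr_max,
                "E_at_ypr_max": curves.E_at_ypr_max,
            }
        )
    return pd.DataFrame(rows)
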