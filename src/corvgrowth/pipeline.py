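"""End-to-end analysis orchestration.

``run_full_analysis`` composes the whole workflow on one age-length table:

1. fit all five growth models to the raw records and rank them by AICc/BIC;
2. compute the bias indicators (length/age frequency histograms, per-age
   statistics, the empirical L_inf check against each model's fitted
   asymptote);
3. bolster every age class to an equal target count and refit/re-rank;
4. optionally propagate growth scenarios (fitted and/or configured) through
   the per-recruit model and tabulate current FNSSBR and YPR / YPR_max.

Every table is written as delimited text, the machine-readable report as
JSON (validating against the pydantic model :class:`AnalysisReport`, whose
JSON schema ships with the package), and a human-readable summary alongside.
All randomness flows from one explicit seed recorded in the report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel

from . import bias, selection
from .data import AgeLengthTable, read_age_length, write_age_length
from .errors import CorvgrowthError, InputError
from .fitting import GrowthFit, confidence_intervals, fit_model
from .models import GrowthModel, asymptotic_length, make_params
from .perrecruit import PerRecruitConfig, compare_growth_scenarios, per_recruit_curves

logger = logging.getLogger("corvgrowth")

__all__ = [
    "AnalysisReport",
    "run_full_analysis",
    "load_config",
    "fit_from_dict",
    "report_json_schema",
]

ALL_MODELS = list(GrowthModel)


class FitRecord(BaseModel):
    model: str
    params: dict[str, float]
    rss: float
    n: int
    sigma2_hat: float
    log_lik: float
    k: int
    converged: bool
    n_restarts_used: int
    at_bounds: bool
    data_provenance: str
    conf_int: Optional[dict[str, list[float]]] = None


class SelectionRecord(BaseModel):
    model: str
    k: int
    aicc: float
    delta_aicc: float
    weight: float
    bic: float
    delta_bic: float


class IndicatorSummary(BaseModel):
    l_max: float
    froese_binohlan_linf: float
    linf_by_model: dict[str, Optional[float]]
    linf_gap_by_model: dict[str, Optional[float]]
    n_age_classes: int


class ScenarioRecord(BaseModel):
    scenario: str
    fnssbr: float
    ypr_over_ypr_max: float
    ypr_max: float
    E_at_ypr_max: float


class AnalysisReport(BaseModel):
    """Machine-readable record of one full analysis run."""

    seed: int
    data_path: str
    n_records: int
    config: dict[str, Any]
    raw_fits: list[FitRecord]
    raw_selection: list[SelectionRecord]
    raw_model_averaged_linf: Optional[float]
    bolstered_fits: list[FitRecord]
    bolstered_selection: list[SelectionRecord]
    bolstered_model_averaged_linf: Optional[float]
    indicator_summary: IndicatorSummary
    per_recruit_summary: Optional[list[ScenarioRecord]] = None
    outputs: list[str]


def report_json_schema() -> dict:
    """JSON schema of the analysis report (also shipped as a package file)."""
    return AnalysisReport.model_json_schema()


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: config must be a mapping")
    return cfg


def fit_from_dict(d: dict) -> GrowthFit:
    """Rebuild a GrowthFit from its JSON representation (without covariance)."""
    model = GrowthModel.coerce(d["model"])
    return GrowthFit(
        model=model,
        params=make_params(model, **d["params"]),
        rss=d["rss"],
        n=d["n"],
        log_lik=d["log_lik"],
        k=d["k"],
        converged=d["converged"],
        n_restarts_used=d["n_restarts_used"],
        at_bounds=d.get("at_bounds", False),
        covar=None,
        data_provenance=d.get("data_provenance", "raw"),
    )


def _fit_record(fit: GrowthFit, with_ci: bool = True) -> FitRecord:
    ci = None
    if with_ci and fit.converged:
        ci = {
            name: [float(iv.low), float(iv.high)]
            for name, iv in confidence_intervals(fit).items()
            if not iv.degenerate
        }
    return FitRecord(**fit.to_dict(), conf_int=ci)


def _fit_all(data: AgeLengthTable, seed: int, restarts_cfg: dict) -> list[GrowthFit]:
    fits = []
    for model in ALL_MODELS:
        restarts = restarts_cfg.get(model.value)
        fit = fit_model(model, data, restarts=restarts, seed=seed)
        logger.info(
            "fit %-16s to %-9s data: rss=%.6g converged=%s restarts=%d",
            model.value,
            data.provenance,
            fit.rss,
            fit.converged,
            fit.n_restarts_used,
        )
        fits.append(fit)
    return fits


def _growth_scenarios_from_config(pr_cfg: dict) -> dict[str, tuple]:
    out = {}
    for name, spec in (pr_cfg.get("extra_scenarios") or {}).items():
        model = GrowthModel.coerce(spec["model"])
        out[name] = (model, make_params(model, **spec["params"]))
    return out


def run_full_analysis(
    data_path: str | Path,
    config_path: str | Path | None,
    out_dir: str | Path,
    seed: int = 0,
) -> AnalysisReport:
    """Run fit -> select -> indicators -> bolster -> refit -> per-recruit.

    Writes all tables, ``report.json`` and ``summary.txt`` under ``out_dir``.
    A stage failure raises :class:`CorvgrowthError` naming the stage;
    outputs written before the failure are left on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    stage = "load"

    def _write_frame(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        outputs.append(str(path))

    def _write_json(obj, name: str) -> None:
        path = out / name
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)
        outputs.append(str(path))

    try:
        cfg = load_config(config_path)
        data = read_age_length(
            data_path,
            column_map=cfg.get("column_map"),
            max_age=int(cfg.get("max_age", 8)),
        )
        logger.info("loaded %d records from %s", data.n, data_path)
        restarts_cfg = cfg.get("restarts") or {}

        stage = "fit_raw"
        raw_fits = _fit_all(data, seed, restarts_cfg)
        _write_json([f.to_dict() for f in raw_fits], "raw_fits.json")

        stage = "select_raw"
        raw_table = selection.build_selection_table(raw_fits)
        _write_frame(raw_table, "raw_selection.csv")
        raw_avg_linf = selection.model_average_linf(raw_table, raw_fits)

        stage = "indicators"
        for variable in ("length", "age"):
            _write_frame(
                bias.frequency_histogram(data, variable), f"hist_{variable}.csv"
            )
        _write_frame(bias.per_age_stats(data), "per_age_stats.csv")
        fb_linf = bias.froese_binohlan_linf(data.length_max)
        linf_by_model = {
            f.model.value: asymptotic_length(f.model, f.params) for f in raw_fits
        }
        indicator = IndicatorSummary(
            l_max=data.length_max,
            froese_binohlan_linf=fb_linf,
            linf_by_model=linf_by_model,
            linf_gap_by_model={
                m: (fb_linf - v if v is not None else None)
                for m, v in linf_by_model.items()
            },
            n_age_classes=int(data.observed_ages.size),
        )
        _write_json(indicator.model_dump(), "indicators.json")

        stage = "bolster"
        target = int(cfg.get("bolster", {}).get("target_per_age", 200))
        bolstered = bias.bolster_dataset(data, target_per_age=target, seed=seed)
        write_age_length(bolstered, out / "bolstered.csv")
        outputs.append(str(out / "bolstered.csv"))

        stage = "fit_bolstered"
        bol_fits = _fit_all(bolstered, seed, restarts_cfg)
        _write_json([f.to_dict() for f in bol_fits], "bolstered_fits.json")

        stage = "select_bolstered"
        bol_table = selection.build_selection_table(bol_fits)
        _write_frame(bol_table, "bolstered_selection.csv")
        bol_avg_linf = selection.model_average_linf(bol_table, bol_fits)

        stage = "per_recruit"
        pr_summary = None
        pr_cfg = cfg.get("per_recruit")
        if pr_cfg:
            demo = {
                k: pr_cfg[k]
                for k in (
                    "M",
                    "lw_a",
                    "lw_b",
                    "E_OA",
                    "E_YA",
                    "a_R",
                    "a_OA",
                    "A_max",
                    "female_fraction",
                )
                if k in pr_cfg
            }
            scenarios = dict(_growth_scenarios_from_config(pr_cfg))
            by_model = {f.model.value: f for f in raw_fits}
            by_model_bol = {f.model.value: f for f in bol_fits}
            scenarios["vb_raw"] = (
                GrowthModel.VON_BERTALANFFY,
                by_model["von_bertalanffy"].params,
            )
            scenarios["vb_bolstered"] = (
                GrowthModel.VON_BERTALANFFY,
                by_model_bol["von_bertalanffy"].params,
            )
            scenarios["sr_raw"] = (
                GrowthModel.SCHNUTE_RICHARDS,
                by_model["schnute_richards"].params,
            )
            scenarios["sr_bolstered"] = (
                GrowthModel.SCHNUTE_RICHARDS,
                by_model_bol["schnute_richards"].params,
            )
            cfgs = {
                name: PerRecruitConfig(growth=growth, **demo)
                for name, growth in scenarios.items()
            }
            step = float(pr_cfg.get("e_grid_step", 0.005))
            comparison = compare_growth_scenarios(
                cfgs, E_current=cfgs["vb_raw"].E_OA, step=step
            )
            _write_frame(comparison, "per_recruit_scenarios.csv")
            for name, c in cfgs.items():
                _write_frame(
                    per_recruit_curves(c, step=step).to_frame(),
                    f"per_recruit_curves_{name}.csv",
                )
            pr_summary = [
                ScenarioRecord(**row) for row in comparison.to_dict("records")
            ]

        stage = "report"
        report = AnalysisReport(
            seed=seed,
            data_path=str(data_path),
            n_records=data.n,
            config=cfg,
            raw_fits=[_fit_record(f) for f in raw_fits],
            raw_selection=[
                SelectionRecord(**row) for row in raw_table.to_dict("records")
            ],
            raw_model_averaged_linf=raw_avg_linf,
            bolstered_fits=[_fit_record(f) for f in bol_fits],
            bolstered_selection=[
                SelectionRecord(**row) for row in bol_table.to_dict("records")
            ],
            bolstered_model_averaged_linf=bol_avg_linf,
            indicator_summary=indicator,
            per_recruit_summary=pr_summary,
            outputs=outputs,
        )
        _write_json(report.model_dump(), "report.json")
        (out / "summary.txt").write_text(_summary_text(report))
        outputs.append(str(out / "summary.txt"))
        return report
    except CorvgrowthError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise CorvgrowthError(f"stage {stage!r} failed: {exc}") from exc


def _summary_text(report: AnalysisReport) -> str:
    lines = [
        "corvgrowth full analysis",
        f"seed: {report.seed}",
        f"data: {report.data_path} ({report.n_records} records)",
        "",
        "raw-data model ranking (by AICc):",
    ]
    for row in report.raw_selection:
        lines.append(
            f"  {row.model:<16s} k={row.k} AICc={row.aicc:10.2f} "
            f"dAICc={row.delta_aicc:8.2f} w={row.weight:.2f} "
            f"BIC={row.bic:10.2f} dBIC={row.delta_bic:8.2f}"
        )
    lines.append(
        f"model-averaged L_inf (raw): {report.raw_model_averaged_linf:.1f} mm"
    )
    lines.append("")
    lines.append("bolstered-data model ranking (by AICc):")
    for row in report.bolstered_selection:
        lines.append(
            f"  {row.model:<16s} k={row.k} AICc={row.aicc:10.2f} "
            f"dAICc={row.delta_aicc:8.2f} w={row.weight:.2f} "
            f"BIC={row.bic:10.2f} dBIC={row.delta_bic:8.2f}"
        )
    lines.append(
        f"model-averaged L_inf (bolstered): "
        f"{report.bolstered_model_averaged_linf:.1f} mm"
    )
    ind = report.indicator_summary
    lines += [
        "",
        f"L_max = {ind.l_max:.0f} mm; empirical (Froese-Binohlan) "
        f"L_inf = {ind.froese_binohlan_linf:.0f} mm",
        "fitted L_inf and gap to the empirical prediction:",
    ]
    for m, v in ind.linf_by_model.items():
        gap = ind.linf_gap_by_model[m]
        if v is None:
            lines.append(f"  {m:<16s} L_inf undefined")
        else:
            lines.append(f"  {m:<16s} L_inf={v:8.2f} mm  gap={gap:+8.2f} mm")
    if report.per_recruit_summary:
        lines += ["", "per-recruit scenarios (current FNSSBR, YPR/YPRmax):"]
        for s in report.per_recruit_summary:
            lines.append(
                f"  {s.scenario:<16s} FNSSBR={s.fnssbr:.2f} "
                f"YPR/YPRmax={s.ypr_over_ypr_max:.2f} "
                f"(E* = {s.E_at_ypr_max:.3f})"
            )
    lines.append("")
    return "\n".join(lines)
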