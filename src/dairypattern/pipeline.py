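"""End-to-end pipeline: chain composite building, substitution modeling,
and goal evaluation into a report bundle.

Reports are deterministic functions of their inputs; every printed cell in
the CSV outputs is traceable to an unrounded value dumped in the JSON
report, which also records the fixture checksums of the run.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .composites import FoodRecord, read_food_table
from .fixtures import data_checksums, load_fixtures
from .goals import (
    DEFAULT_THRESHOLDS,
    DriTable,
    check_thresholds,
    default_dri,
    goal_report,
)
from .modeling import (
    PatternModel,
    run_models,
    shipped_plans,
    plans_from_payload,
    usda_reference_pattern,
)
from .panel import default_panel, round_for_display
from .synth import synthetic_standin_foods

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    out_dir: Path
    food_table: Path | None = None        # None -> shipped synthetic stand-ins
    plans: Path | None = None             # None -> shipped seven plans
    dri: Path | None = None               # None -> shipped DRI table
    baseline: str = "Model 1"
    formats: tuple[str, ...] = ("csv", "json")
    groups: tuple[str, ...] = ("females_19_30", "males_51_plus")
    include_single_food_models: bool = True

    def __post_init__(self) -> None:
        for fmt in self.formats:
            if fmt not in ("csv", "json"):
                raise ValueError(f"unknown output format {fmt!r}")


def _load_inputs(config: RunConfig):
    panel = default_panel()
    if config.food_table is not None:
        foods = read_food_table(config.food_table, panel)
    elif config.include_single_food_models:
        foods = synthetic_standin_foods(panel)
    else:
        foods = None
    if config.plans is not None:
        with open(config.plans) as fh:
            plans = plans_from_payload(json.load(fh), foods)
    else:
        plans = shipped_plans(foods)
    dri = (
        DriTable.from_frame(pd.read_csv(config.dri))
        if config.dri is not None
        else default_dri()
    )
    return foods, plans, dri


def validate_inputs(config: RunConfig) -> list[str]:
    """Collect every input violation (report-only, never raises)."""
    violations: list[str] = []
    for label in ("food_table", "plans", "dri"):
        path = getattr(config, label)
        if path is not None and not Path(path).exists():
            violations.append(f"{label} path does not exist: {path}")
            return violations
    try:
        foods, plans, dri = _load_inputs(config)
    except Exception as exc:  # surface parse errors as violations
        return violations + [f"inputs failed to load: {exc}"]
    ref = usda_reference_pattern()
    if config.baseline not in plans:
        violations.append(f"baseline {config.baseline!r} is not a defined plan")
    for name, plan in plans.items():
        if abs(plan.total_servings - ref.dairy_servings) > 1e-9:
            violations.append(
                f"plan {name!r} supplies {plan.total_servings} servings, "
                f"pattern carries {ref.dairy_servings}"
            )
        for comp in plan.components:
            if comp.servings < 0:
                violations.append(f"plan {name!r} has negative servings")
    for group in config.groups:
        if group not in dri.groups:
            violations.append(f"DRI table lacks group {group!r}")
    return violations


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow and write the report bundle.

    Writes model-totals, percent-change, and goal tables plus a threshold
    summary under ``config.out_dir``; returns the in-memory report dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    foods, plans, dri = _load_inputs(config)
    ref = usda_reference_pattern()
    logger.info("stage=load fixtures=%s", sorted(data_checksums()))
    models, reports = run_models(ref, plans, baseline=config.baseline)
    logger.info("stage=model n_models=%d", len(models))

    panel = default_panel()
    totals = pd.DataFrame({"nutrient_id": panel.ids})
    totals["reference_pattern"] = ref.total.values
    for name, model in models.items():
        totals[name] = model.total.values
    display = pd.DataFrame({"nutrient_id": panel.ids})
    display["unit"] = [e.unit for e in panel.entries]
    display["reference_pattern"] = round_for_display(ref.total)["value"].values
    for name, model in models.items():
        display[name] = round_for_display(model.total)["value"].values

    pct = pd.DataFrame({"nutrient_id": panel.ids})
    for name, rep in reports.items():
        pct[name] = rep.frame["display"].values

    goals_frames = []
    threshold_rows = {}
    for name, model in models.items():
        g = goal_report(model.total, config.groups, dri)
        g.insert(0, "model", name)
        goals_frames.append(g)
        flags = check_thresholds(model.total, DEFAULT_THRESHOLDS)
        threshold_rows[name] = {
            "saturated_fat_pct_kcal": flags.saturated_fat_pct_kcal,
            "saturated_fat_pct_display": flags.saturated_fat_pct_display,
            "saturated_fat_exceeds": flags.saturated_fat_exceeds,
            "saturated_fat_at_limit": flags.saturated_fat_at_limit,
            "sodium_mg": flags.sodium_mg,
            "sodium_exceeds_cdrr": flags.sodium_exceeds_cdrr,
            "sodium_below_current_mean": flags.sodium_below_current_mean,
        }
    goals_out = pd.concat(goals_frames, ignore_index=True)
    logger.info("stage=evaluate groups=%s", ",".join(config.groups))

    if "csv" in config.formats:
        display.to_csv(out / "model_totals.csv", index=False)
        pct.to_csv(out / "percent_change.csv", index=False)
        goals_out.to_csv(out / "goal_report.csv", index=False)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool_version": __version__,
        "fixture_checksums": data_checksums(),
        "baseline": config.baseline,
        "models": sorted(models),
        "unrounded_totals": {
            name: model.total.to_dict() for name, model in models.items()
        },
        "percent_change_unrounded": {
            name: {
                nid: (float(p) if pd.notna(p) else None)
                for nid, p in zip(panel.ids, rep.frame["pct_change"])
            }
            for name, rep in reports.items()
        },
        "thresholds": threshold_rows,
        "models_exceeding_sodium_cdrr": sorted(
            name for name, row in threshold_rows.items() if row["sodium_exceeds_cdrr"]
        ),
    }
    if "json" in config.formats:
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, allow_nan=False, default=str)
    logger.info("stage=report out=%s", out)
    return report
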