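"""Serving-substitution modeling of the 2000-kcal reference eating pattern.

The reference pattern carries 3 daily cup-equivalents of a fat-free dairy
composite.  Modeling proceeds in two steps: (1) derive the non-dairy
remainder by peeling the dairy contribution out of the day-level total;
(2) add back 3 cup-equivalents supplied by a substitution plan (e.g. two
servings of the updated fat-free composite plus one serving of the
whole-fat composite).  Nothing else in the pattern is re-optimized, so
energy moves with the substituted servings.

Percent change is always computed on unrounded day-level totals against
the updated-composite baseline (Model 1), matching the published layout;
the original pattern serves only for the separately reported deltas.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composites import Composite, FoodRecord, composite_from_table1
from .panel import (
    NutrientProfile,
    default_panel,
    profile_add,
    profile_scale,
    profile_sub,
    round_half_up,
)

#: |Δ%| thresholds for a meaningful change, mirroring the 10% "good source"
#: and 20% "excellent source" Daily-Value labeling cut-offs.
GOOD_SOURCE_PCT = 10.0
EXCELLENT_SOURCE_PCT = 20.0

SERVINGS_TOLERANCE = 1e-9


class PlanError(ValueError):
    pass


@dataclass(frozen=True)
class ReferencePattern:
    """A day-level eating pattern with an identified dairy component."""

    name: str
    total: NutrientProfile
    dairy_component: Composite
    dairy_servings: float

    def __post_init__(self) -> None:
        if not self.dairy_servings > 0:
            raise ValueError("dairy_servings must be > 0")


@dataclass(frozen=True)
class PlanComponent:
    component: Composite | FoodRecord
    servings: float

    @property
    def label(self) -> str:
        if isinstance(self.component, FoodRecord):
            return f"food:{self.component.food_code}"
        return f"composite:{self.component.name}"

    @property
    def per_serving(self) -> NutrientProfile:
        if isinstance(self.component, FoodRecord):
            return self.component.profile
        return self.component.per_serving


@dataclass(frozen=True)
class SubstitutionPlan:
    name: str
    components: tuple  # of PlanComponent

    @property
    def total_servings(self) -> float:
        return float(sum(c.servings for c in self.components))


@dataclass(frozen=True)
class PatternModel:
    plan: SubstitutionPlan
    remainder: NutrientProfile
    total: NutrientProfile


@dataclass(frozen=True)
class PercentChangeReport:
    """Per-nutrient 100·(model − baseline)/baseline on unrounded totals."""

    model_name: str
    baseline_name: str
    frame: pd.DataFrame  # nutrient_id, pct_change (NaN where baseline == 0), display

    def pct(self, nutrient_id: str) -> float:
        return float(self.frame.set_index("nutrient_id").loc[nutrient_id, "pct_change"])

    def display(self, nutrient_id: str) -> float:
        return float(self.frame.set_index("nutrient_id").loc[nutrient_id, "display"])


def derive_remainder(ref: ReferencePattern) -> NutrientProfile:
    """Non-dairy remainder: total − servings × dairy composite.

    A negative remainder for any nutrient signals inconsistent inputs and
    raises, naming the nutrient.
    """
    dairy = profile_scale(
        ref.dairy_component.per_serving, ref.dairy_servings, basis="per_day"
    )
    return profile_sub(ref.total, dairy)


def apply_plan(
    remainder: NutrientProfile,
    plan: SubstitutionPlan,
    expected_servings: float = 3.0,
) -> PatternModel:
    """Add a plan's serving-weighted components back onto the remainder."""
    if abs(plan.total_servings - expected_servings) > SERVINGS_TOLERANCE:
        raise PlanError(
            f"plan {plan.name!r} supplies {plan.total_servings} servings; "
            f"the reference pattern carries {expected_servings}"
        )
    total = remainder
    for comp in plan.components:
        if comp.servings < 0:
            raise PlanError(f"negative servings in plan {plan.name!r}")
        total = profile_add(
            total, profile_scale(comp.per_serving, comp.servings, basis="per_day")
        )
    return PatternModel(plan=plan, remainder=remainder, total=total)


def percent_change(model: PatternModel, baseline: PatternModel) -> PercentChangeReport:
    b = baseline.total.values
    m = model.total.values
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(b != 0, 100.0 * (m - b) / np.where(b != 0, b, 1.0), np.nan)
    frame = pd.DataFrame(
        {
            "nutrient_id": model.total.panel.ids,
            "pct_change": pct,
            "display": [
                round_half_up(p, 1) if np.isfinite(p) else np.nan for p in pct
            ],
            "baseline_zero": b == 0,
        }
    )
    return PercentChangeReport(
        model_name=model.plan.name, baseline_name=baseline.plan.name, frame=frame
    )


def flag_meaningful_changes(report: PercentChangeReport) -> list[tuple[str, str]]:
    """Nutrients whose |Δ%| reaches the good-/excellent-source scale."""
    flags = []
    for row in report.frame.itertuples(index=False):
        if not np.isfinite(row.pct_change):
            continue
        mag = abs(row.pct_change)
        if mag >= EXCELLENT_SOURCE_PCT:
            flags.append((row.nutrient_id, "excellent-source-scale"))
        elif mag >= GOOD_SOURCE_PCT:
            flags.append((row.nutrient_id, "good-source-scale"))
    return flags


# ---------------------------------------------------------------------------
# Shipped reference pattern and plans
# ---------------------------------------------------------------------------


def usda_reference_pattern() -> ReferencePattern:
    """The 2000-kcal reference pattern with 3 servings of its 2015-era
    fat-free dairy composite (printed pattern column + printed composite)."""
    from .fixtures import load_fixtures

    fx = load_fixtures()
    total = NutrientProfile(default_panel(), fx.usda_pattern.to_dict(), "per_day")
    return ReferencePattern(
        name="USDA 2000-kcal pattern",
        total=total,
        dairy_component=composite_from_table1("USDA2015"),
        dairy_servings=3.0,
    )


def _resolve_ref(ref: str, foods: Mapping[str, FoodRecord] | None):
    kind, _, key = ref.partition(":")
    if kind == "composite":
        return composite_from_table1(key)
    if kind == "food":
        if foods is None or key not in (foods or {}):
            raise PlanError(f"plan references {ref!r} but no such food was supplied")
        return foods[key]
    raise PlanError(f"unknown component reference {ref!r}")


def plans_from_payload(
    payload: Mapping, foods: Mapping[str, FoodRecord] | None = None
) -> dict[str, SubstitutionPlan]:
    plans = {}
    for entry in payload["plans"]:
        comps = tuple(
            PlanComponent(_resolve_ref(c["ref"], foods), float(c["servings"]))
            for c in entry["components"]
        )
        plans[entry["name"]] = SubstitutionPlan(name=entry["name"], components=comps)
    return plans


def shipped_plans(
    foods: Mapping[str, FoodRecord] | None = None, *, composites_only: bool = False
) -> dict[str, SubstitutionPlan]:
    """The seven shipped substitution plans.

    Models 1–3 use printed composites only; Models 4–7 need per-cup food
    profiles and are skipped unless a food table is supplied (or
    ``composites_only`` is set).
    """
    from importlib import resources

    with resources.files("dairypattern.data").joinpath("plans.json").open() as fh:
        payload = json.load(fh)
    plans: dict[str, SubstitutionPlan] = {}
    for entry in payload["plans"]:
        needs_foods = any(c["ref"].startswith("food:") for c in entry["components"])
        if needs_foods and (foods is None or composites_only):
            continue
        plans.update(plans_from_payload({"plans": [entry]}, foods))
    return plans


def run_models(
    ref: ReferencePattern | None = None,
    plans: Mapping[str, SubstitutionPlan] | None = None,
    baseline: str = "Model 1",
) -> tuple[dict[str, PatternModel], dict[str, PercentChangeReport]]:
    """Derive the remainder, apply every plan, and compare to the baseline."""
    ref = ref or usda_reference_pattern()
    plans = plans if plans is not None else shipped_plans(composites_only=True)
    if baseline not in plans:
        raise PlanError(f"baseline {baseline!r} is not among the plans")
    remainder = derive_remainder(ref)
    models = {
        name: apply_plan(remainder, plan, ref.dairy_servings)
        for name, plan in plans.items()
    }
    base = models[baseline]
    reports = {
        name: percent_change(model, base)
        for name, model in models.items()
        if name != baseline
    }
    return models, reports
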