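"""Consumption-weighted dairy composites.

A "dairy food composite" is a single per-serving (one cup-equivalent)
nutrient profile formed as a consumption-share-weighted average of
representative milk, cheese, and yogurt nutrient records.  Raw shares are
population intake percentages and need not sum to exactly 100 (the shipped
shares sum to 99.99); the builder normalizes by the actual sum.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import (
    NutrientPanel,
    NutrientProfile,
    PanelMismatchError,
    default_panel,
    profile_add,
    profile_scale,
    zero_profile,
)

FOOD_GROUPS = ("milk", "cheese", "yogurt", "other")
FAT_TIERS = ("fat_free", "low_fat", "reduced_fat", "whole")

#: Table-style composite names resolvable by :func:`composite_from_table1`.
TABLE1_NAMES = ("USDA2015", "A", "B", "C")


class UnknownFoodCodeError(KeyError):
    pass


@dataclass(frozen=True)
class FoodRecord:
    """One food (8-digit code) with its per-cup-equivalent profile."""

    food_code: str
    description: str
    group: str
    fat_tier: str
    profile: NutrientProfile

    def __post_init__(self) -> None:
        if self.group not in FOOD_GROUPS:
            raise ValueError(f"group {self.group!r} not in {FOOD_GROUPS}")
        if self.fat_tier not in FAT_TIERS:
            raise ValueError(f"fat_tier {self.fat_tier!r} not in {FAT_TIERS}")
        if self.profile.basis != "per_serving":
            raise ValueError("food profiles are per_serving (one cup-equivalent)")


@dataclass(frozen=True)
class CompositeSpec:
    """(food, weight%) recipe; weights are raw intake percentages."""

    name: str
    components: tuple  # of (food_code, weight_percent)

    @classmethod
    def from_pairs(cls, name: str, pairs: Iterable[tuple[str, float]]) -> "CompositeSpec":
        return cls(name=name, components=tuple((str(c), float(w)) for c, w in pairs))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "components": [
                {"food_code": c, "weight_percent": w} for c, w in self.components
            ],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "CompositeSpec":
        return cls.from_pairs(
            payload["name"],
            [(c["food_code"], c["weight_percent"]) for c in payload["components"]],
        )


@dataclass(frozen=True)
class Composite:
    name: str
    spec: CompositeSpec | None
    per_serving: NutrientProfile
    normalized_weights: Mapping[str, float] = field(default_factory=dict)


def normalize_weights(spec: CompositeSpec) -> dict[str, float]:
    """Normalize raw intake percentages to fractions summing to 1.

    Division is by the actual sum (the shipped shares print as 99.99), so
    scaling every raw weight by a constant leaves the result unchanged.
    """
    if not spec.components:
        raise ValueError(f"composite {spec.name!r} has no components")
    for code, w in spec.components:
        if not w > 0:
            raise ValueError(f"weight for food {code!r} must be > 0, got {w}")
    total = sum(w for _, w in spec.components)
    return {code: w / total for code, w in spec.components}


def build_composite(spec: CompositeSpec, foods: Mapping[str, FoodRecord]) -> Composite:
    """Weighted average of per-cup food profiles under normalized shares."""
    weights = normalize_weights(spec)
    panel: NutrientPanel | None = None
    acc: NutrientProfile | None = None
    for code, frac in weights.items():
        if code not in foods:
            raise UnknownFoodCodeError(f"food code {code!r} not in food table")
        rec = foods[code]
        if panel is None:
            panel = rec.profile.panel
            acc = zero_profile(panel, "per_serving")
        elif rec.profile.panel != panel:
            diff = panel.first_difference(rec.profile.panel)
            raise PanelMismatchError(
                f"food {code!r} is on a different panel (first difference: {diff!r})"
            )
        acc = profile_add(acc, profile_scale(rec.profile, frac))
    assert acc is not None
    return Composite(name=spec.name, spec=spec, per_serving=acc, normalized_weights=weights)


# ---------------------------------------------------------------------------
# Food-table CSV dialect: food_code, description, group, fat_tier, then one
# column per panel nutrient named "<nutrient_id>__<unit>".
# ---------------------------------------------------------------------------

_META_COLUMNS = ("food_code", "description", "group", "fat_tier")


def _nutrient_columns(panel: NutrientPanel) -> list[str]:
    return [f"{e.nutrient_id}__{e.unit}" for e in panel.entries]


def food_table_to_frame(foods: Mapping[str, FoodRecord]) -> pd.DataFrame:
    rows = []
    for rec in foods.values():
        row: dict = {
            "food_code": rec.food_code,
            "description": rec.description,
            "group": rec.group,
            "fat_tier": rec.fat_tier,
        }
        for entry, amount in zip(rec.profile.panel.entries, rec.profile.values):
            row[f"{entry.nutrient_id}__{entry.unit}"] = float(amount)
        rows.append(row)
    return pd.DataFrame(rows)


def food_table_from_frame(
    frame: pd.DataFrame, panel: NutrientPanel | None = None
) -> dict[str, FoodRecord]:
    panel = panel or default_panel()
    expected = _nutrient_columns(panel)
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ValueError(f"food table missing nutrient column(s): {missing}")
    foods: dict[str, FoodRecord] = {}
    for row in frame.to_dict("records"):
        code = str(row["food_code"])
        if code in foods:
            raise ValueError(f"duplicate food code {code!r} in food table")
        amounts = {
            e.nutrient_id: float(row[f"{e.nutrient_id}__{e.unit}"])
            for e in panel.entries
        }
        foods[code] = FoodRecord(
            food_code=code,
            description=str(row.get("description", "")),
            group=str(row["group"]),
            fat_tier=str(row["fat_tier"]),
            profile=NutrientProfile(panel, amounts, "per_serving"),
        )
    return foods


def read_food_table(path, panel: NutrientPanel | None = None) -> dict[str, FoodRecord]:
    return food_table_from_frame(pd.read_csv(path, dtype={"food_code": str}), panel)


def write_food_table(foods: Mapping[str, FoodRecord], path) -> None:
    food_table_to_frame(foods).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Printed composites (2015 reference composite and Composites A/B/C).
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def composite_from_table1(name: str) -> Composite:
    """A printed composite profile, verbatim from the source table.

    Individual food profiles behind these columns are not published, so the
    printed aggregate is used directly rather than rebuilt from a food
    table.  Nutrients the composite table omits (fiber, the fatty-acid
    fractions, iron, copper) are filled with zero; dairy genuinely supplies
    no fiber, while the fat fractions are a known limitation of the printed
    inputs.
    """
    from .fixtures import load_fixtures  # local import to avoid a cycle

    if name not in TABLE1_NAMES:
        raise KeyError(f"unknown composite {name!r}; expected one of {TABLE1_NAMES}")
    fx = load_fixtures()
    column = {"USDA2015": "usda_2015", "A": "composite_a", "B": "composite_b", "C": "composite_c"}[name]
    panel = default_panel()
    amounts = fx.table1[column].to_dict()
    profile = NutrientProfile(panel, amounts, "per_serving", fill_missing=0.0)
    spec = None
    if name in fx.composite_specs:
        spec = fx.composite_specs[name]
    weights = normalize_weights(spec) if spec is not None else {}
    return Composite(name=name, spec=spec, per_serving=profile, normalized_weights=weights)
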