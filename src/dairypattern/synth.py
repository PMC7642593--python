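"""Synthetic food tables and consumption shares.

The real analysis consumes per-food, per-cup-equivalent nutrient records
keyed by 8-digit food codes, plus population consumption shares estimated
from dietary-recall surveys.  Neither input can be redistributed here, so
this module generates structurally faithful stand-ins: per-cup profiles
drawn log-normally around tier-appropriate centers (whole-tier fat centers
above fat-free centers, mineral and vitamin magnitudes in per-cup dairy
ranges), and Dirichlet consumption shares over milk/cheese/yogurt
representatives that sum to ~100 before normalization.

Everything is a deterministic function of the seed.  Synthetic foods are
used for property tests and for stand-in single-food model runs only,
never for reproduction checks against printed values.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np

from .composites import (
    FAT_TIERS,
    CompositeSpec,
    FoodRecord,
    read_food_table,
)
from .panel import NutrientPanel, NutrientProfile, default_panel


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_foods_per_group: int = 4     # foods per (group, fat tier) cell
    sigma: float = 0.15            # log-scale spread of nutrient draws
    consumption_concentration: float = 20.0  # Dirichlet concentration

    def __post_init__(self) -> None:
        if self.n_foods_per_group < 0:
            raise ValueError("n_foods_per_group must be >= 0")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not self.consumption_concentration > 0:
            raise ValueError("consumption_concentration must be > 0")


# Per-cup medians for the fat-free tier of each dairy group, loosely
# calibrated to published per-cup dairy magnitudes.  Fat-linked nutrients
# are scaled up by tier multipliers below.
_BASE_MEDIANS: dict[str, dict[str, float]] = {
    "milk": {
        "energy": 85, "protein": 8.5, "carbohydrate": 12.0, "fiber": 0.0,
        "total_fat": 0.3, "saturated_fat": 0.15, "monounsaturated_fat": 0.08,
        "polyunsaturated_fat": 0.02, "linoleic_acid": 0.01, "linolenic_acid": 0.01,
        "epa": 0.0, "dha": 0.0, "stearic_acid": 0.03, "cholesterol": 5.0,
        "calcium": 300, "iron": 0.1, "magnesium": 27, "phosphorus": 230,
        "potassium": 380, "sodium": 110, "zinc": 1.0, "copper": 0.03,
        "selenium": 7.5, "vitamin_a": 150, "vitamin_e": 0.05, "vitamin_d": 115,
        "vitamin_c": 0.1, "thiamin": 0.11, "riboflavin": 0.45, "niacin": 0.23,
        "vitamin_b6": 0.09, "vitamin_b12": 1.2, "choline": 38, "vitamin_k": 0.1,
    },
    "cheese": {
        "energy": 70, "protein": 12.0, "carbohydrate": 4.0, "fiber": 0.0,
        "total_fat": 0.4, "saturated_fat": 0.25, "monounsaturated_fat": 0.1,
        "polyunsaturated_fat": 0.02, "linoleic_acid": 0.01, "linolenic_acid": 0.01,
        "epa": 0.0, "dha": 0.0, "stearic_acid": 0.04, "cholesterol": 7.0,
        "calcium": 320, "iron": 0.1, "magnesium": 14, "phosphorus": 250,
        "potassium": 80, "sodium": 400, "zinc": 1.6, "copper": 0.02,
        "selenium": 11, "vitamin_a": 60, "vitamin_e": 0.02, "vitamin_d": 8,
        "vitamin_c": 0.1, "thiamin": 0.02, "riboflavin": 0.25, "niacin": 0.1,
        "vitamin_b6": 0.05, "vitamin_b12": 0.7, "choline": 12, "vitamin_k": 0.1,
    },
    "yogurt": {
        "energy": 120, "protein": 10.0, "carbohydrate": 17.0, "fiber": 0.0,
        "total_fat": 0.3, "saturated_fat": 0.2, "monounsaturated_fat": 0.08,
        "polyunsaturated_fat": 0.02, "linoleic_acid": 0.01, "linolenic_acid": 0.01,
        "epa": 0.0, "dha": 0.0, "stearic_acid": 0.03, "cholesterol": 5.0,
        "calcium": 350, "iron": 0.1, "magnesium": 30, "phosphorus": 270,
        "potassium": 430, "sodium": 130, "zinc": 1.5, "copper": 0.02,
        "selenium": 8, "vitamin_a": 25, "vitamin_e": 0.02, "vitamin_d": 3,
        "vitamin_c": 1.0, "thiamin": 0.08, "riboflavin": 0.35, "niacin": 0.2,
        "vitamin_b6": 0.08, "vitamin_b12": 1.0, "choline": 30, "vitamin_k": 0.1,
    },
}

#: Nutrients that scale with the fat tier, and the tier multipliers applied
#: to the fat-free medians above.
_FAT_LINKED = (
    "total_fat", "saturated_fat", "monounsaturated_fat", "polyunsaturated_fat",
    "linoleic_acid", "linolenic_acid", "stearic_acid", "cholesterol",
)
_TIER_FACTOR = {"fat_free": 1.0, "low_fat": 8.0, "reduced_fat": 16.0, "whole": 28.0}
#: Extra energy per gram of added fat, applied on top of the base energy.
_KCAL_PER_G_FAT = 9.0

_GROUP_DIGIT = {"milk": "1", "cheese": "2", "yogurt": "3"}
_TIER_DIGIT = {t: str(i) for i, t in enumerate(FAT_TIERS)}


def _median_profile(group: str, tier: str) -> dict[str, float]:
    base = dict(_BASE_MEDIANS[group])
    added_fat = 0.0
    for nid in _FAT_LINKED:
        scaled = base[nid] * _TIER_FACTOR[tier]
        if nid == "total_fat":
            added_fat = scaled - base[nid]
        base[nid] = scaled
    base["energy"] = base["energy"] + added_fat * _KCAL_PER_G_FAT
    return base


def generate_food_table(
    cfg: SyntheticConfig, panel: NutrientPanel | None = None
) -> dict[str, FoodRecord]:
    """Draw a synthetic food table; identical seeds give identical tables."""
    panel = panel or default_panel()
    rng = np.random.default_rng(cfg.seed)
    foods: dict[str, FoodRecord] = {}
    for group in ("milk", "cheese", "yogurt"):
        for tier in FAT_TIERS:
            medians = _median_profile(group, tier)
            for i in range(cfg.n_foods_per_group):
                noise = rng.lognormal(mean=0.0, sigma=cfg.sigma, size=len(panel))
                amounts = {
                    nid: medians.get(nid, 0.0) * noise[j]
                    for j, nid in enumerate(panel.ids)
                }
                code = f"9{_GROUP_DIGIT[group]}{_TIER_DIGIT[tier]}{i:05d}"
                foods[code] = FoodRecord(
                    food_code=code,
                    description=f"synthetic {tier} {group} #{i}",
                    group=group,
                    fat_tier=tier,
                    profile=NutrientProfile(panel, amounts, "per_serving"),
                )
    return foods


def generate_consumption_shares(
    cfg: SyntheticConfig,
    foods: Mapping[str, FoodRecord],
    fat_tier: str | None = None,
    name: str = "synthetic composite",
) -> CompositeSpec:
    """Dirichlet consumption shares over one representative per group.

    Shares are expressed as percentages summing to ~100 before
    normalization (the builder normalizes by the actual sum).  High
    concentration pulls the shares toward equality.
    """
    if not foods:
        raise ValueError("food table is empty")
    rng = np.random.default_rng((cfg.seed, 1))
    reps = []
    for group in ("milk", "cheese", "yogurt"):
        candidates = sorted(
            code
            for code, rec in foods.items()
            if rec.group == group and (fat_tier is None or rec.fat_tier == fat_tier)
        )
        if not candidates:
            raise ValueError(f"no {group!r} foods available for share draws")
        reps.append(candidates[int(rng.integers(len(candidates)))])
    shares = rng.dirichlet(np.full(3, cfg.consumption_concentration)) * 100.0
    return CompositeSpec.from_pairs(name, zip(reps, shares))


def synthetic_standin_foods(panel: NutrientPanel | None = None) -> dict[str, FoodRecord]:
    """The shipped single-food stand-ins (whole/reduced-fat milk and cheese).

    These are synthetic, clearly-labelled, non-authoritative per-cup
    profiles that let the single-food substitution models run end to end;
    the true per-cup values behind the published single-food models are not
    printed anywhere.
    """
    path = resources.files("dairypattern.data").joinpath("synthetic_foods.csv")
    with resources.as_file(path) as p:
        return read_food_table(p, panel)
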