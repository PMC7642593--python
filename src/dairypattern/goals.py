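"""Dietary-goal evaluation: % RDA/AI/UL, macronutrient % of energy, and
saturated-fat / sodium threshold screening.

Goals are 2015-era Dietary Reference Intakes for the two sample groups
(females 19–30 years, males 51+ years), with the pre-2019 potassium AI of
4,700 mg and a fiber AI of 28 g derived from the 2000-kcal level (14 g per
1,000 kcal, identical for both groups).  Percent-of-energy rows use Atwater
factors 4/4/9 kcal per g for protein, carbohydrate, and every fat class.

The saturated-fat limit is judged on the displayed (integer-rounded)
percent of calories: a pattern displaying exactly 10 is at the limit, not
over it.  Sodium is screened against the 2,300 mg/day chronic-disease risk
reduction level.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import NutrientProfile, round_half_up

logger = logging.getLogger(__name__)

GOAL_TYPES = ("RDA", "AI", "UL")

ATWATER = {"protein": 4.0, "carbohydrate": 4.0, "fat": 9.0}

#: Fat-class panel nutrients evaluated as % of energy (all at 9 kcal/g).
FAT_CLASSES = ("saturated_fat", "monounsaturated_fat", "polyunsaturated_fat")
DEFAULT_PCT_KCAL_NUTRIENTS = ("protein", "carbohydrate") + FAT_CLASSES


@dataclass(frozen=True)
class GoalEntry:
    goal_type: str
    value: float

    def __post_init__(self) -> None:
        if self.goal_type not in GOAL_TYPES:
            raise ValueError(f"goal_type {self.goal_type!r} not in {GOAL_TYPES}")
        if not self.value > 0:
            raise ValueError("goal values must be > 0")


@dataclass(frozen=True)
class DriTable:
    """Reference values per age–sex group plus the energy goal."""

    groups: Mapping[str, Mapping[str, GoalEntry]]
    energy_goal_kcal: float = 2000.0
    atwater: Mapping[str, float] = field(default_factory=lambda: dict(ATWATER))

    def goal(self, group: str, nutrient_id: str) -> GoalEntry | None:
        if group not in self.groups:
            raise KeyError(f"unknown age-sex group {group!r}")
        return self.groups[group].get(nutrient_id)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, energy_goal_kcal: float = 2000.0) -> "DriTable":
        groups: dict[str, dict[str, GoalEntry]] = {}
        for row in frame.itertuples(index=False):
            entry = GoalEntry(goal_type=str(row.goal_type), value=float(row.value))
            bucket = groups.setdefault(str(row.group), {})
            if row.nutrient_id in bucket:
                raise ValueError(
                    f"duplicate goal for {row.nutrient_id!r} in group {row.group!r}"
                )
            bucket[str(row.nutrient_id)] = entry
        return cls(groups=groups, energy_goal_kcal=energy_goal_kcal)


@lru_cache(maxsize=1)
def default_dri() -> DriTable:
    from .fixtures import load_fixtures

    return DriTable.from_frame(load_fixtures().dri_frame)


@dataclass(frozen=True)
class ThresholdSet:
    saturated_fat_max_pct_kcal: float = 10.0
    sodium_cdrr_mg: float = 2300.0
    #: report-only context: current mean U.S. sodium intake
    current_mean_sodium_mg: float = 3410.0


DEFAULT_THRESHOLDS = ThresholdSet()


def pct_of_goal(
    profile: NutrientProfile, group: str, dri: DriTable | None = None
) -> pd.DataFrame:
    """Percent of the group's RDA/AI/UL for every covered panel nutrient.

    ``pct_display`` is the half-up integer shown in goal tables;
    ``pct_unrounded`` backs the reconstruction identity
    pct/100 × goal ≈ amount.  Nutrients without a goal entry (energy and
    the fatty-acid fractions, which are judged as % of energy instead) are
    omitted with a warning.
    """
    dri = dri or default_dri()
    if group not in dri.groups:
        raise KeyError(f"unknown age-sex group {group!r}")
    rows, skipped = [], []
    for entry, amount in zip(profile.panel.entries, profile.values):
        goal = dri.goal(group, entry.nutrient_id)
        if goal is None:
            skipped.append(entry.nutrient_id)
            continue
        pct = 100.0 * float(amount) / goal.value
        rows.append(
            {
                "nutrient_id": entry.nutrient_id,
                "group": group,
                "goal_type": goal.goal_type,
                "goal_value": goal.value,
                "amount": float(amount),
                "pct_unrounded": pct,
                "pct_display": round_half_up(pct, 0),
            }
        )
    if skipped:
        logger.warning(
            "no %s goal entry for: %s", group, ", ".join(skipped)
        )
    return pd.DataFrame(rows)


def pct_kcal(
    profile: NutrientProfile,
    dri: DriTable | None = None,
    nutrients: Sequence[str] = DEFAULT_PCT_KCAL_NUTRIENTS,
) -> pd.DataFrame:
    """Macronutrient percent of energy: 100 × grams × Atwater / kcal."""
    dri = dri or default_dri()
    energy = profile.amount("energy")
    if not energy > 0:
        raise ValueError("profile energy must be > 0 for %-of-energy rows")
    rows = []
    for nid in nutrients:
        # protein/carbohydrate carry their own factor; every fat class is 9
        factor = dri.atwater.get(nid, dri.atwater["fat"])
        pct = 100.0 * profile.amount(nid) * factor / energy
        rows.append(
            {
                "nutrient_id": nid,
                "kcal_per_g": factor,
                "pct_unrounded": pct,
                "pct_display": round_half_up(pct, 0),
            }
        )
    return pd.DataFrame(rows)


def pct_energy_goal(profile: NutrientProfile, dri: DriTable | None = None) -> float:
    dri = dri or default_dri()
    return 100.0 * profile.amount("energy") / dri.energy_goal_kcal


@dataclass(frozen=True)
class ThresholdFlags:
    saturated_fat_pct_kcal: float          # unrounded
    saturated_fat_pct_display: float       # half-up integer, basis of the flag
    saturated_fat_exceeds: bool            # display value strictly above limit
    saturated_fat_at_limit: bool
    sodium_mg: float
    sodium_exceeds_cdrr: bool              # amount strictly above 2,300 mg
    sodium_below_current_mean: bool


def check_thresholds(
    profile: NutrientProfile, thresholds: ThresholdSet = DEFAULT_THRESHOLDS
) -> ThresholdFlags:
    """Saturated-fat and sodium limit screening for a day-level profile."""
    energy = profile.amount("energy")
    sat_pct = 100.0 * profile.amount("saturated_fat") * ATWATER["fat"] / energy
    sat_display = round_half_up(sat_pct, 0)
    sodium = profile.amount("sodium")
    return ThresholdFlags(
        saturated_fat_pct_kcal=sat_pct,
        saturated_fat_pct_display=sat_display,
        saturated_fat_exceeds=sat_display > thresholds.saturated_fat_max_pct_kcal,
        saturated_fat_at_limit=sat_display == thresholds.saturated_fat_max_pct_kcal,
        sodium_mg=sodium,
        sodium_exceeds_cdrr=sodium > thresholds.sodium_cdrr_mg,
        sodium_below_current_mean=sodium < thresholds.current_mean_sodium_mg,
    )


def goal_report(
    profile: NutrientProfile,
    groups: Sequence[str] = ("females_19_30", "males_51_plus"),
    dri: DriTable | None = None,
) -> pd.DataFrame:
    """Full goal grid for one day-level profile: energy vs goal, %RDA/AI/UL
    rows per group, and the macronutrient %-of-energy rows."""
    dri = dri or default_dri()
    frames = []
    for group in groups:
        amount_rows = pct_of_goal(profile, group, dri)
        amount_rows["kind"] = "amount_vs_goal"
        energy_pct = pct_energy_goal(profile, dri)
        energy_row = pd.DataFrame(
            [
                {
                    "nutrient_id": "energy",
                    "group": group,
                    "goal_type": "energy",
                    "goal_value": dri.energy_goal_kcal,
                    "amount": profile.amount("energy"),
                    "pct_unrounded": energy_pct,
                    "pct_display": round_half_up(energy_pct, 0),
                    "kind": "energy_vs_goal",
                }
            ]
        )
        kcal_rows = pct_kcal(profile, dri)
        kcal_rows["group"] = group
        kcal_rows["kind"] = "pct_kcal"
        frames.extend([energy_row, amount_rows, kcal_rows])
    return pd.concat(frames, ignore_index=True)
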