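"""Machine-readable printed fixtures: composite table, pattern column,
model totals/percent changes, and the goal-evaluation grid.

Values are stored exactly as printed (data/*.csv, ASCII minus signs) and
parsed here together with their printing precision: ``ulp`` is one unit in
the last printed digit (``"2.4" -> 0.1``, ``"77" -> 1``), the granularity
every reproduction tolerance is expressed in, since the published inputs
are themselves rounded.  Cells the source flags as suspected typos are
enumerated and excluded from comparison sets.

File integrity is verified against data/checksums.json on load.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping

import pandas as pd

from .composites import CompositeSpec

_DATA_FILES = (
    "panel.csv",
    "table1_composites.csv",
    "usda_pattern.csv",
    "model_tables.csv",
    "table4_goals.csv",
    "dri.csv",
    "plans.json",
    "composite_specs.json",
    "synthetic_foods.csv",
)

MODEL_NAMES = tuple(f"model{i}" for i in range(1, 8))
GROUPS = ("females_19_30", "males_51_plus")

#: Current mean U.S. sodium intake, mg/day, report-only context values.
CURRENT_MEAN_SODIUM_MG = 3410.0   # main-text figure, used in reports
CURRENT_MEAN_SODIUM_MG_ABSTRACT = 3440.0  # abstract prints a different figure
#: Discretionary added-sugars calorie allowance at the 2000-kcal level.
ADDED_SUGARS_ALLOWANCE_KCAL = 120.0


class FixtureChecksumError(RuntimeError):
    pass


def printed_ulp(text: str) -> float:
    """One unit in the last printed digit of a numeric string."""
    text = text.strip()
    if "." in text:
        return 10.0 ** -(len(text) - text.index(".") - 1)
    return 1.0


def _parse(text: str) -> float:
    return float(text.replace(",", ""))


@dataclass(frozen=True)
class PaperFixtures:
    table1: pd.DataFrame            # per-serving composite profiles (float)
    table1_ulp: pd.DataFrame
    usda_pattern: pd.Series         # day-level reference pattern column
    usda_pattern_ulp: pd.Series
    model_totals: pd.DataFrame      # day-level totals, models 1-7
    model_totals_ulp: pd.DataFrame
    pct_change: pd.DataFrame        # printed % change vs model 1, models 2-7
    table4: pd.DataFrame            # goal grid: metric rows x (model, group)
    dri_frame: pd.DataFrame
    composite_specs: Mapping[str, CompositeSpec]
    updated_shares: Mapping[str, float]
    legacy_shares: Mapping[str, float]
    typo_flags: tuple

    def is_typo_flagged(self, column: str, nutrient_id: str) -> bool:
        return any(
            f["column"] == column and f["nutrient_id"] == nutrient_id
            for f in self.typo_flags
        )


def _data_path(name: str):
    return resources.files("dairypattern.data").joinpath(name)


def _verify_checksums() -> None:
    with _data_path("checksums.json").open() as fh:
        expected = json.load(fh)
    for name in _DATA_FILES:
        digest = hashlib.sha256(_data_path(name).read_bytes()).hexdigest()
        if expected.get(name) != digest:
            raise FixtureChecksumError(
                f"fixture file {name!r} does not match its recorded checksum"
            )


def _read_str_csv(name: str) -> pd.DataFrame:
    with _data_path(name).open() as fh:
        return pd.read_csv(fh, dtype=str)


@lru_cache(maxsize=1)
def load_fixtures() -> PaperFixtures:
    """Load and validate all printed fixtures."""
    _verify_checksums()

    t1_raw = _read_str_csv("table1_composites.csv").set_index("nutrient_id")
    table1 = t1_raw.map(_parse)
    table1_ulp = t1_raw.map(printed_ulp)

    pat_raw = _read_str_csv("usda_pattern.csv").set_index("nutrient_id")["amount"]
    usda_pattern = pat_raw.map(_parse)
    usda_pattern_ulp = pat_raw.map(printed_ulp)

    mt_raw = _read_str_csv("model_tables.csv").set_index("nutrient_id")
    total_cols = [c for c in mt_raw.columns if not c.endswith("_pct")]
    pct_cols = [c for c in mt_raw.columns if c.endswith("_pct")]
    model_totals = mt_raw[total_cols].map(_parse)
    model_totals_ulp = mt_raw[total_cols].map(printed_ulp)
    pct_change = mt_raw[pct_cols].map(_parse)
    pct_change.columns = [c.removesuffix("_pct") for c in pct_cols]

    t4 = _read_str_csv("table4_goals.csv")
    value_cols = [f"m{i}_{g}" for i in range(1, 8) for g in ("f", "m")]
    for c in value_cols:
        t4[c] = t4[c].map(_parse)
    table4 = t4.set_index("metric")

    with _data_path("dri.csv").open() as fh:
        dri_frame = pd.read_csv(fh)

    with _data_path("composite_specs.json").open() as fh:
        specs_payload = json.load(fh)
    composite_specs = {
        name: CompositeSpec.from_pairs(
            name, [(c["food_code"], c["weight_percent"]) for c in entry["components"]]
        )
        for name, entry in specs_payload["composites"].items()
    }
    typo_flags = tuple(specs_payload["typo_flags"])

    fx = PaperFixtures(
        table1=table1,
        table1_ulp=table1_ulp,
        usda_pattern=usda_pattern,
        usda_pattern_ulp=usda_pattern_ulp,
        model_totals=model_totals,
        model_totals_ulp=model_totals_ulp,
        pct_change=pct_change,
        table4=table4,
        dri_frame=dri_frame,
        composite_specs=composite_specs,
        updated_shares=dict(specs_payload["updated_shares"]),
        legacy_shares=dict(specs_payload["legacy_2009_2010_shares"]),
        typo_flags=typo_flags,
    )
    _validate(fx)
    return fx


def _validate(fx: PaperFixtures) -> None:
    from .panel import default_panel

    panel = default_panel()
    unknown = set(fx.table1.index) - set(panel.ids)
    if unknown:
        raise ValueError(f"composite fixture nutrients not on panel: {sorted(unknown)}")
    if list(fx.usda_pattern.index) != list(panel.ids):
        raise ValueError("pattern fixture must cover the full panel in panel order")
    if list(fx.model_totals.index) != list(panel.ids):
        raise ValueError("model fixture must cover the full panel in panel order")
    for name in MODEL_NAMES:
        if name not in fx.model_totals.columns:
            raise ValueError(f"missing model column {name!r}")


def data_checksums() -> dict[str, str]:
    """Recorded sha256 digests of the shipped fixture files."""
    with _data_path("checksums.json").open() as fh:
        return json.load(fh)
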