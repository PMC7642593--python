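"""Nutrient panel and profile algebra.

The panel is the fixed 34-nutrient accounting frame used by every stage of
the pipeline: energy and macronutrients (including the milk-fat fractions),
nine minerals, and eleven vitamins, each with the unit and display precision
used in printed eating-pattern tables.  Units are carried as opaque labels
exactly as the source tables print them (selenium and several vitamins are
conventionally µg but print as mg; vitamin D is kept in IU) — no unit
conversion is ever attempted.

All arithmetic is performed on unrounded values; half-up rounding to the
panel's display precision happens only in :func:`round_for_display`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Units a panel entry may carry (as printed in the source tables).
ALLOWED_UNITS = frozenset({"kcal", "g", "mg", "ug", "ug_RAE", "mg_AT", "IU"})
CATEGORIES = ("macronutrient", "mineral", "vitamin")
BASES = ("per_serving", "per_day")


class PanelMismatchError(ValueError):
    """Two profiles do not share the same nutrient panel."""


class NegativeAmountError(ValueError):
    """A nutrient amount that must be non-negative is negative."""


def _normalize_unit(unit: str) -> str:
    return unit.replace("µg", "ug").replace("μg", "ug")


@dataclass(frozen=True)
class PanelEntry:
    nutrient_id: str
    unit: str
    display_precision: int
    category: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", _normalize_unit(self.unit))
        if self.unit not in ALLOWED_UNITS:
            raise ValueError(f"unit {self.unit!r} not in {sorted(ALLOWED_UNITS)}")
        if self.category not in CATEGORIES:
            raise ValueError(f"category {self.category!r} not in {CATEGORIES}")
        if self.display_precision < 0:
            raise ValueError("display_precision must be >= 0")


class NutrientPanel:
    """An ordered, immutable collection of :class:`PanelEntry` rows.

    The order is fixed and identical across every profile in a run; profiles
    store their amounts as arrays aligned to this order.
    """

    def __init__(self, entries: Iterable[PanelEntry]):
        self.entries = tuple(entries)
        if not self.entries:
            raise ValueError("panel must have at least one entry")
        self.ids = tuple(e.nutrient_id for e in self.entries)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("nutrient_ids must be unique")
        self._index = {nid: i for i, nid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, nutrient_id: str) -> bool:
        return nutrient_id in self._index

    def index(self, nutrient_id: str) -> int:
        try:
            return self._index[nutrient_id]
        except KeyError:
            raise KeyError(f"nutrient {nutrient_id!r} not on panel") from None

    def entry(self, nutrient_id: str) -> PanelEntry:
        return self.entries[self.index(nutrient_id)]

    def unit(self, nutrient_id: str) -> str:
        return self.entry(nutrient_id).unit

    def precision(self, nutrient_id: str) -> int:
        return self.entry(nutrient_id).display_precision

    def __eq__(self, other: object) -> bool:
        return isinstance(other, NutrientPanel) and self.entries == other.entries

    def __hash__(self) -> int:
        return hash(self.entries)

    def first_difference(self, other: "NutrientPanel") -> str | None:
        """Nutrient id of the first differing entry, for error messages."""
        for a, b in zip(self.entries, other.entries):
            if a != b:
                return a.nutrient_id
        if len(self) != len(other):
            longer = self if len(self) > len(other) else other
            return longer.ids[min(len(self), len(other))]
        return None

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "NutrientPanel":
        return cls(
            PanelEntry(
                nutrient_id=str(r.nutrient_id),
                unit=str(r.unit),
                display_precision=int(r.display_precision),
                category=str(r.category),
            )
            for r in frame.itertuples(index=False)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nutrient_id": self.ids,
                "unit": [e.unit for e in self.entries],
                "display_precision": [e.display_precision for e in self.entries],
                "category": [e.category for e in self.entries],
            }
        )


@lru_cache(maxsize=1)
def default_panel() -> NutrientPanel:
    """The shipped 34-nutrient panel (energy … vitamin K, plus fiber)."""
    with resources.files("dairypattern.data").joinpath("panel.csv").open() as fh:
        frame = pd.read_csv(fh)
    return NutrientPanel.from_frame(frame)


class NutrientProfile:
    """A vector of nutrient amounts over a panel, per serving or per day.

    Value semantics: operations return new profiles and never mutate their
    inputs.  Per-serving profiles must be non-negative; per-day profiles
    (pattern totals and remainders) must be non-negative as well — a negative
    remainder signals inconsistent inputs and is an error at the point where
    it is derived.
    """

    __slots__ = ("panel", "basis", "_amounts")

    def __init__(
        self,
        panel: NutrientPanel,
        amounts: Mapping[str, float] | np.ndarray,
        basis: str,
        *,
        fill_missing: float | None = None,
    ):
        if basis not in BASES:
            raise ValueError(f"basis {basis!r} not in {BASES}")
        self.panel = panel
        self.basis = basis
        if isinstance(amounts, np.ndarray):
            if amounts.shape != (len(panel),):
                raise ValueError("amount array shape does not match panel")
            arr = np.asarray(amounts, dtype=float).copy()
        else:
            unknown = set(amounts) - set(panel.ids)
            if unknown:
                raise KeyError(f"amounts for nutrients not on panel: {sorted(unknown)}")
            missing = [nid for nid in panel.ids if nid not in amounts]
            if missing:
                if fill_missing is None:
                    raise KeyError(f"missing amounts for panel nutrients: {missing}")
                logger.warning(
                    "filling %d missing nutrient(s) with %g: %s",
                    len(missing), fill_missing, ", ".join(missing),
                )
            arr = np.array(
                [float(amounts.get(nid, fill_missing or 0.0)) for nid in panel.ids]
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("amounts must be finite")
        if np.any(arr < 0):
            bad = panel.ids[int(np.argmin(arr))]
            raise NegativeAmountError(f"negative amount for {bad!r}: {arr.min()}")
        arr.flags.writeable = False
        self._amounts = arr

    @property
    def values(self) -> np.ndarray:
        """Read-only amount array aligned to the panel order."""
        return self._amounts

    def amount(self, nutrient_id: str) -> float:
        return float(self._amounts[self.panel.index(nutrient_id)])

    def __getitem__(self, nutrient_id: str) -> float:
        return self.amount(nutrient_id)

    def as_series(self) -> pd.Series:
        return pd.Series(self._amounts.copy(), index=list(self.panel.ids), name=self.basis)

    def to_dict(self) -> dict:
        return {"basis": self.basis, "amounts": dict(zip(self.panel.ids, map(float, self._amounts)))}

    @classmethod
    def from_dict(cls, panel: NutrientPanel, payload: Mapping) -> "NutrientProfile":
        return cls(panel, payload["amounts"], payload["basis"])

    def _check_panel(self, other: "NutrientProfile") -> None:
        if self.panel != other.panel:
            diff = self.panel.first_difference(other.panel)
            raise PanelMismatchError(f"panels differ at nutrient {diff!r}")

    def allclose(self, other: "NutrientProfile", rtol: float = 1e-9, atol: float = 1e-12) -> bool:
        self._check_panel(other)
        return bool(np.allclose(self._amounts, other._amounts, rtol=rtol, atol=atol))

    def __repr__(self) -> str:
        return f"NutrientProfile(basis={self.basis!r}, n={len(self.panel)})"


def profile_add(a: NutrientProfile, b: NutrientProfile) -> NutrientProfile:
    """Element-wise sum of two profiles on the same panel and basis."""
    a._check_panel(b)
    if a.basis != b.basis:
        raise ValueError(f"basis mismatch: {a.basis!r} + {b.basis!r}")
    return NutrientProfile(a.panel, a.values + b.values, a.basis)


def profile_sub(a: NutrientProfile, b: NutrientProfile) -> NutrientProfile:
    """Element-wise difference ``a − b``; negative results are errors.

    Used to peel a dairy contribution out of a day-level total; a negative
    entry means the inputs are inconsistent and names the first offending
    nutrient.
    """
    a._check_panel(b)
    diff = a.values - b.values
    neg = diff < -1e-9
    if np.any(neg):
        bad = a.panel.ids[int(np.argmax(neg))]
        raise NegativeAmountError(
            f"subtraction drives {bad!r} negative ({diff[np.argmax(neg)]:.6g})"
        )
    return NutrientProfile(a.panel, np.clip(diff, 0.0, None), a.basis)


def profile_scale(a: NutrientProfile, k: float, *, basis: str | None = None) -> NutrientProfile:
    """Element-wise multiple of a profile by ``k >= 0``.

    ``basis`` converts a per-serving profile into a per-day contribution
    (serving count × per-serving profile) without a separate operation.
    """
    if k < 0:
        raise ValueError(f"scale factor must be >= 0, got {k}")
    return NutrientProfile(a.panel, a.values * float(k), basis or a.basis)


def round_half_up(value: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (2.44→2.4, 46.7→47)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def round_for_display(profile: NutrientProfile) -> pd.DataFrame:
    """Printed-precision view of a profile (half-up per panel precision).

    Rounding is idempotent and applied only here, never inside arithmetic.
    """
    rows = []
    for entry, amount in zip(profile.panel.entries, profile.values):
        rows.append(
            {
                "nutrient_id": entry.nutrient_id,
                "unit": entry.unit,
                "value": round_half_up(float(amount), entry.display_precision),
            }
        )
    return pd.DataFrame(rows)


def zero_profile(panel: NutrientPanel, basis: str = "per_serving") -> NutrientProfile:
    return NutrientProfile(panel, np.zeros(len(panel)), basis)
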