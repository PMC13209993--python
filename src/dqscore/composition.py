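"""Food-composition table: per-100 g food-group serve content and moderation class.

Each consumable item is described by one row joining two pieces of metadata
that drive all downstream processing:

* the mean number of serves of each of the five core food groups (grain,
  fruit, vegetable, milk and alternatives, meat and alternatives) contained
  in 100 g of the item, in the style of the Australian Health Survey
  food-group database built on AUSNUT 2011-13; and
* a moderation class flagging the item as a discretionary food, a
  sugar-sweetened beverage (SSB), an alcoholic beverage, or none of these,
  in the style of the Australian Health Survey Discretionary Food List.

Items carrying a moderation class are scored by energy (600 kJ = 1 serve)
and contribute nothing to core food-group serves, even if the table carries
serve values for them; those values are ignored at aggregation.

Plain water is not a composition row: it enters the pipeline as intake
events measured in cups (see :mod:`dqscore.intake`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import pandas as pd

from .errors import CompositionLookupError, SchemaError, UniquenessError, ValidationError

logger = logging.getLogger(__name__)

#: The five core food groups of the Australian Dietary Guidelines-2013.
CORE_GROUPS = ("grain", "fruit", "vegetable", "milk_alt", "meat_alt")

#: Moderation classes: anything but "none" is excluded from core serves and
#: scored through the 600 kJ energy-to-serve conversion.
MODERATION_CLASSES = ("none", "discretionary_food", "ssb", "alcohol")

#: CSV column layout (UTF-8, header required).
CSV_COLUMNS = (
    "item_id",
    "label",
    "energy_kj_per_100g",
    "serves_grain_per_100g",
    "serves_fruit_per_100g",
    "serves_vegetable_per_100g",
    "serves_milk_alt_per_100g",
    "serves_meat_alt_per_100g",
    "moderation_class",
    "fruit_type_id",
    "vegetable_type_id",
)

_SERVE_COLUMNS = {g: f"serves_{g}_per_100g" for g in CORE_GROUPS}


@dataclass(frozen=True)
class FoodCompositionEntry:
    """One food or beverage item's composition metadata.

    Parameters
    ----------
    item_id
        Opaque unique identifier (AUSNUT-style food code).
    label
        Human-readable "mini label".
    energy_kj_per_100g
        Energy density, kJ per 100 g, >= 0.
    serves_per_100g
        Mapping core food group -> serves contained in 100 g (>= 0).
    moderation_class
        One of :data:`MODERATION_CLASSES`.
    fruit_type_id, vegetable_type_id
        Optional identifiers naming the unique fruit/vegetable *type* the
        item contributes to variety counting; ``None`` when not applicable.
    """

    item_id: str
    label: str
    energy_kj_per_100g: float
    serves_per_100g: Mapping[str, float] = field(default_factory=dict)
    moderation_class: str = "none"
    fruit_type_id: Optional[str] = None
    vegetable_type_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.moderation_class not in MODERATION_CLASSES:
            raise ValidationError(
                f"item {self.item_id!r}: unknown moderation_class "
                f"{self.moderation_class!r}"
            )
        if not math.isfinite(self.energy_kj_per_100g) or self.energy_kj_per_100g < 0:
            raise ValidationError(
                f"item {self.item_id!r}: energy_kj_per_100g must be finite and >= 0"
            )
        for group in CORE_GROUPS:
            v = float(self.serves_per_100g.get(group, 0.0))
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"item {self.item_id!r}: serves_per_100g[{group!r}] must be >= 0"
                )

    @property
    def is_moderation(self) -> bool:
        return self.moderation_class != "none"

    def effective_serves_per_100g(self) -> dict[str, float]:
        """Core serves actually credited downstream.

        Zero for every group when the item carries a moderation class:
        discretionary/SSB/alcohol items are not included in food-group
        serving calculations.
        """
        if self.is_moderation:
            return {g: 0.0 for g in CORE_GROUPS}
        return {g: float(self.serves_per_100g.get(g, 0.0)) for g in CORE_GROUPS}


@dataclass
class CompositionTable:
    """An indexed collection of :class:`FoodCompositionEntry`."""

    entries: list[FoodCompositionEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[str, FoodCompositionEntry] = {}
        dupes = []
        for e in self.entries:
            if e.item_id in self._index:
                dupes.append(e.item_id)
            self._index[e.item_id] = e
        if dupes:
            raise UniquenessError(f"duplicate item_id values: {sorted(set(dupes))}")
        # canonical order: sorted by item_id, so loading is order-independent
        self.entries = sorted(self.entries, key=lambda e: e.item_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[FoodCompositionEntry]:
        return iter(self.entries)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._index

    def lookup(self, item_id: str) -> FoodCompositionEntry:
        """Return the unique entry for ``item_id``.

        Raises
        ------
        CompositionLookupError
            If no entry exists — this signals an intake event referencing
            an item absent from the composition table.
        """
        try:
            return self._index[item_id]
        except KeyError:
            raise CompositionLookupError(item_id) from None

    def to_frame(self) -> pd.DataFrame:
        """Serialise to the canonical CSV column layout."""
        rows = []
        for e in self.entries:
            row: dict[str, object] = {
                "item_id": e.item_id,
                "label": e.label,
                "energy_kj_per_100g": e.energy_kj_per_100g,
                "moderation_class": e.moderation_class,
                "fruit_type_id": e.fruit_type_id if e.fruit_type_id is not None else "",
                "vegetable_type_id": (
                    e.vegetable_type_id if e.vegetable_type_id is not None else ""
                ),
            }
            for g, col in _SERVE_COLUMNS.items():
                row[col] = float(e.serves_per_100g.get(g, 0.0))
            rows.append(row)
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _entry_from_row(row: pd.Series) -> FoodCompositionEntry:
    def _opt(v: object) -> Optional[str]:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        s = str(v).strip()
        return s or None

    return FoodCompositionEntry(
        item_id=str(row["item_id"]),
        label=str(row["label"]),
        energy_kj_per_100g=float(row["energy_kj_per_100g"]),
        serves_per_100g={g: float(row[_SERVE_COLUMNS[g]]) for g in CORE_GROUPS},
        moderation_class=str(row["moderation_class"]).strip() or "none",
        fruit_type_id=_opt(row["fruit_type_id"]),
        vegetable_type_id=_opt(row["vegetable_type_id"]),
    )


def load_composition_table(path: str | Path, strict: bool = True) -> CompositionTable:
    """Load and validate a composition CSV.

    With ``strict`` on, any violated invariant aborts the load; with it off,
    offending rows are dropped and logged with their (1-based data) row
    numbers.

    Raises
    ------
    SchemaError
        Missing required column (names the column).
    UniquenessError
        Duplicate ``item_id`` (lists the duplicates).
    ValidationError
        Negative serve or energy value, in strict mode.
    """
    df = pd.read_csv(path, dtype={"item_id": str, "fruit_type_id": str, "vegetable_type_id": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"composition table missing required column(s): {missing}")

    dupes = df["item_id"][df["item_id"].duplicated()].unique().tolist()
    if dupes:
        raise UniquenessError(f"duplicate item_id values: {sorted(dupes)}")

    entries = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            entries.append(_entry_from_row(row))
        except (ValidationError, ValueError) as exc:
            if strict:
                if isinstance(exc, ValidationError):
                    raise
                raise ValidationError(f"row {pos}: {exc}") from exc
            logger.warning("dropping composition row %d: %s", pos, exc)
    return CompositionTable(entries)


def build_table(entries: Iterable[FoodCompositionEntry]) -> CompositionTable:
    """Construct a table from in-memory entries (convenience for tests/fixtures)."""
    return CompositionTable(list(entries))
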