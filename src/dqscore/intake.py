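"""Aggregate raw intake events into mean daily intakes across the 11 DQS dimensions.

The processing chain mirrors how analyst-coded food records are prepared for
food-based diet quality scoring:

1. every consumed item is *disaggregated* into core food-group serves using
   its per-100 g composition (a chicken-and-salad sandwich yields meat,
   vegetable and grain serves in proportion to the grams consumed);
2. discretionary foods, SSBs and alcoholic beverages are excluded from core
   serves; instead their energy (kJ) is pooled per class and converted to
   serves at 600 kJ per serve;
3. fruit and vegetable *variety* is the number of unique types consumed,
   counted per day;
4. plain water is recorded in cups (1 cup = 250 mL) and reported both in
   cups and litres;
5. every total is divided by the number of days the participant recorded,
   giving mean daily values; participants with fewer than two recorded days
   are excluded before any scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .composition import CORE_GROUPS, CompositionTable, FoodCompositionEntry
from .errors import SchemaError, ValidationError

#: Reserved item_id for plain water events (amount is in cups).
WATER_TOKEN = "WATER"

#: One standard Australian metric cup = 250 mL.
LITRES_PER_CUP = 0.25

#: Energy content of one discretionary/SSB/alcohol serve.
KJ_PER_SERVE = 600.0

#: Moderation pools tracked alongside the five core groups.
MODERATION_GROUPS = ("discretionary_food", "ssb", "alcohol")

#: All serve-denominated dimensions of the summary.
SERVE_DIMENSIONS = CORE_GROUPS + MODERATION_GROUPS

INTAKE_CSV_COLUMNS = ("participant_id", "day_index", "item_id", "amount", "unit")


@dataclass(frozen=True)
class IntakeEvent:
    """One consumed item on one recorded day.

    ``amount`` is grams for food/beverage items and cups when ``item_id``
    is the reserved water token.
    """

    participant_id: str
    day_index: int
    item_id: str
    amount: float
    unit: str = "g"

    def __post_init__(self) -> None:
        if not math.isfinite(self.amount) or self.amount < 0:
            raise ValidationError(
                f"event ({self.participant_id}, day {self.day_index}, "
                f"{self.item_id}): amount must be finite and >= 0"
            )
        if self.day_index < 1:
            raise ValidationError("day_index must be >= 1")
        if self.unit not in ("g", "cup"):
            raise ValidationError(f"unknown unit {self.unit!r}")
        if self.unit == "cup" and self.item_id != WATER_TOKEN:
            raise ValidationError("unit 'cup' is permitted only for the water token")

    @property
    def is_water(self) -> bool:
        return self.item_id == WATER_TOKEN


@dataclass(frozen=True)
class EventContribution:
    """Per-dimension contribution of a single disaggregated event."""

    core_serves: Mapping[str, float]
    moderation_energy_kj: Mapping[str, float]
    total_energy_kj: float
    fruit_type_id: Optional[str] = None
    vegetable_type_id: Optional[str] = None


@dataclass
class DailyIntakeSummary:
    """A participant's mean daily intake across the 11 DQS dimensions."""

    participant_id: str
    days_recorded: int
    serves: dict[str, float]  # per SERVE_DIMENSIONS, mean serves/day
    water_cups_per_day: float
    fruit_variety_per_day: float
    vegetable_variety_per_day: float
    mean_energy_kj_per_day: float

    @property
    def water_litres_per_day(self) -> float:
        return self.water_cups_per_day * LITRES_PER_CUP

    def as_dict(self) -> dict[str, float]:
        d: dict[str, object] = {
            "participant_id": self.participant_id,
            "days_recorded": self.days_recorded,
        }
        for g in SERVE_DIMENSIONS:
            d[f"serves_{g}"] = self.serves[g]
        d["water_cups_per_day"] = self.water_cups_per_day
        d["water_litres_per_day"] = self.water_litres_per_day
        d["fruit_variety_per_day"] = self.fruit_variety_per_day
        d["vegetable_variety_per_day"] = self.vegetable_variety_per_day
        d["mean_energy_kj_per_day"] = self.mean_energy_kj_per_day
        return d


@dataclass(frozen=True)
class ExclusionMarker:
    """A participant removed before scoring, with the stage's reason."""

    participant_id: str
    reason: str  # "insufficient_days" | "no_records"


def disaggregate_event(
    event: IntakeEvent, entry: FoodCompositionEntry
) -> EventContribution:
    """Split one event into food-group serves and energy pools.

    For unflagged items, serves credited to group *g* are
    ``amount_g * serves_per_100g[g] / 100``; an item may contribute to
    several groups at once (the sandwich case) with no renormalisation.
    For moderation-class items all core serves are zero and the event's
    energy is credited to that class's pool. Total energy is always
    ``amount_g * energy_kj_per_100g / 100`` and feeds only the
    plausibility screen.
    """
    if event.is_water:
        raise ValidationError("water events are aggregated volumetrically, not disaggregated")
    scale = event.amount / 100.0
    total_energy = scale * entry.energy_kj_per_100g
    moderation = {g: 0.0 for g in MODERATION_GROUPS}
    if entry.is_moderation:
        core = {g: 0.0 for g in CORE_GROUPS}
        moderation[entry.moderation_class] = total_energy
        return EventContribution(core, moderation, total_energy)
    core = {g: scale * s for g, s in entry.effective_serves_per_100g().items()}
    contributes_fruit = core["fruit"] > 0
    contributes_veg = core["vegetable"] > 0
    return EventContribution(
        core,
        moderation,
        total_energy,
        fruit_type_id=entry.fruit_type_id if contributes_fruit else None,
        vegetable_type_id=entry.vegetable_type_id if contributes_veg else None,
    )


def energy_to_serves(total_kj: float) -> float:
    """Convert moderation-pool energy to serves at 600 kJ/serve, unrounded."""
    if not math.isfinite(total_kj) or total_kj < 0:
        raise ValidationError("energy must be finite and >= 0")
    return total_kj / KJ_PER_SERVE


def count_variety(
    events: Sequence[IntakeEvent], composition: CompositionTable, kind: str
) -> float:
    """Mean unique fruit/vegetable types per recorded day for one participant.

    For each recorded day the distinct type identifiers of the requested
    kind among that day's serve-contributing events are counted; the mean
    divides the summed daily counts by the number of recorded days. The same
    type eaten twice in one day counts once that day.
    """
    if kind not in ("fruit", "vegetable"):
        raise ValidationError(f"kind must be 'fruit' or 'vegetable', got {kind!r}")
    days: dict[int, set[str]] = {}
    recorded: set[int] = set()
    for ev in events:
        recorded.add(ev.day_index)
        if ev.is_water:
            continue
        contrib = disaggregate_event(ev, composition.lookup(ev.item_id))
        type_id = contrib.fruit_type_id if kind == "fruit" else contrib.vegetable_type_id
        if type_id is not None:
            days.setdefault(ev.day_index, set()).add(type_id)
    if not recorded:
        return 0.0
    return sum(len(s) for s in days.values()) / len(recorded)


def summarise_participant(
    events: Sequence[IntakeEvent],
    composition: CompositionTable,
    days_required_min: int = 2,
) -> Union[DailyIntakeSummary, ExclusionMarker]:
    """Aggregate one participant's events into a :class:`DailyIntakeSummary`.

    Every total (core serves, moderation energy converted to serves, water
    cups, variety counts, energy) is summed over all events then divided by
    the number of distinct recorded days. Participants with an empty record
    or fewer than ``days_required_min`` recorded days get an
    :class:`ExclusionMarker` instead.
    """
    events = list(events)
    if not events:
        return ExclusionMarker(participant_id="", reason="no_records")
    pid = events[0].participant_id
    if any(ev.participant_id != pid for ev in events):
        raise ValidationError("summarise_participant expects one participant's events")

    days = sorted({ev.day_index for ev in events})
    n_days = len(days)
    if n_days < days_required_min:
        return ExclusionMarker(participant_id=pid, reason="insufficient_days")

    core_total = {g: 0.0 for g in CORE_GROUPS}
    moderation_kj = {g: 0.0 for g in MODERATION_GROUPS}
    water_cups = 0.0
    energy_kj = 0.0
    fruit_types: dict[int, set[str]] = {}
    veg_types: dict[int, set[str]] = {}

    for ev in events:
        if ev.is_water:
            water_cups += ev.amount
            continue
        contrib = disaggregate_event(ev, composition.lookup(ev.item_id))
        for g in CORE_GROUPS:
            core_total[g] += contrib.core_serves[g]
        for g in MODERATION_GROUPS:
            moderation_kj[g] += contrib.moderation_energy_kj[g]
        energy_kj += contrib.total_energy_kj
        if contrib.fruit_type_id is not None:
            fruit_types.setdefault(ev.day_index, set()).add(contrib.fruit_type_id)
        if contrib.vegetable_type_id is not None:
            veg_types.setdefault(ev.day_index, set()).add(contrib.vegetable_type_id)

    serves = {g: core_total[g] / n_days for g in CORE_GROUPS}
    for g in MODERATION_GROUPS:
        serves[g] = energy_to_serves(moderation_kj[g]) / n_days

    return DailyIntakeSummary(
        participant_id=pid,
        days_recorded=n_days,
        serves=serves,
        water_cups_per_day=water_cups / n_days,
        fruit_variety_per_day=sum(len(s) for s in fruit_types.values()) / n_days,
        vegetable_variety_per_day=sum(len(s) for s in veg_types.values()) / n_days,
        mean_energy_kj_per_day=energy_kj / n_days,
    )


def summarise_cohort(
    events: Iterable[IntakeEvent],
    composition: CompositionTable,
    days_required_min: int = 2,
) -> tuple[list[DailyIntakeSummary], list[ExclusionMarker]]:
    """Group events by participant and summarise each; returns (summaries, exclusions)."""
    by_pid: dict[str, list[IntakeEvent]] = {}
    for ev in events:
        by_pid.setdefault(ev.participant_id, []).append(ev)
    summaries, exclusions = [], []
    for pid in sorted(by_pid):
        result = summarise_participant(by_pid[pid], composition, days_required_min)
        if isinstance(result, ExclusionMarker):
            exclusions.append(result)
        else:
            summaries.append(result)
    return summaries, exclusions


def load_intake_events(path: str | Path) -> list[IntakeEvent]:
    """Read an intake CSV (participant_id, day_index, item_id, amount, unit)."""
    df = pd.read_csv(path, dtype={"participant_id": str, "item_id": str})
    missing = [c for c in INTAKE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"intake table missing required column(s): {missing}")
    if df.empty:
        raise SchemaError("intake table contains no events")
    return [
        IntakeEvent(
            participant_id=str(r.participant_id),
            day_index=int(r.day_index),
            item_id=str(r.item_id),
            amount=float(r.amount),
            unit=str(r.unit),
        )
        for r in df.itertuples(index=False)
    ]


def events_to_frame(events: Iterable[IntakeEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": e.participant_id,
                "day_index": e.day_index,
                "item_id": e.item_id,
                "amount": e.amount,
                "unit": e.unit,
            }
            for e in events
        ],
        columns=list(INTAKE_CSV_COLUMNS),
    )


def summaries_to_frame(summaries: Iterable[DailyIntakeSummary]) -> pd.DataFrame:
    """One CSV row per participant with all summary fields."""
    return pd.DataFrame([s.as_dict() for s in summaries])
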