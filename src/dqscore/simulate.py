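"""Seeded synthetic fixtures: composition table, intake events, participant profiles.

No real food-record dataset ships with this package, so every pipeline stage
is exercised against generated cohorts with the statistical structure the
method assumes:

* a composition table spanning all five core food groups, multi-group
  ("sandwich-like") items, and discretionary/SSB/alcohol items with
  realistic energy densities;
* 4-day records (one weekend day by study design) with a small share of
  participants recording fewer than two days, who must be filtered out;
* heavy and light misreporters planted in the tails of the EI:BMR
  distribution, which the plausibility screen must trim;
* sociodemographic covariates (age, attention paid to diet, physical
  activity, cholesterol) linked to a latent diet quality propensity, so the
  construct-validity battery has real signal to find.

Every participant's *true* mean daily intake per dimension is returned
alongside the events; with day-to-day noise disabled the aggregation chain
recovers these targets exactly, which is the package's main end-to-end
correctness check.

All randomness flows from a single seed through one ``numpy`` generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .composition import CompositionTable, FoodCompositionEntry, build_table
from .errors import ValidationError
from .intake import WATER_TOKEN, IntakeEvent, events_to_frame

# Reference items used to realise intake targets. serves are per 100 g;
# energy densities are typical for the item class (kJ/100 g).
_REF_ITEMS = {
    "grain": ("GRAIN_REF", "bread, wholemeal", 950.0, 1.5),
    "milk_alt": ("MILK_REF", "milk, reduced fat", 270.0, 0.4),
    "meat_alt": ("MEAT_REF", "chicken breast, cooked", 800.0, 1.5),
}
_FRUIT_ENERGY, _FRUIT_SERVES = 250.0, 2.0 / 3.0  # 150 g = 1 serve
_VEG_ENERGY, _VEG_SERVES = 120.0, 4.0 / 3.0  # 75 g = 1 serve
_FRUIT_LABELS = ("apple", "banana", "orange", "strawberries", "grapes", "pear", "kiwifruit", "mango")
_VEG_LABELS = ("lettuce", "tomato", "carrot", "broccoli", "potato", "capsicum",
               "spinach", "onion", "pumpkin", "zucchini")
_MODERATION_ITEMS = (
    ("DISC01", "meat pie", 1600.0, "discretionary_food"),
    ("SSB01", "cola soft drink", 180.0, "ssb"),
    ("ALC01", "beer, full strength", 160.0, "alcohol"),
)
_EXTRA_MODERATION = (("DISC02", "chocolate bar", 2200.0, "discretionary_food"),)
# multi-group item exercising disaggregation: grain + vegetable + meat serves
_SANDWICH = ("SANDWICH", "sandwich, chicken & salad", 850.0,
             {"grain": 1.0, "vegetable": 0.4, "meat_alt": 0.5})

_MIN_ITEMS = 8  # one per core group + one per moderation class


@dataclass
class FixtureSpec:
    """Parameters of a synthetic cohort.

    Defaults emulate the study conditions: 280 participants recording 4 days
    including one weekend day, 8 of whom record a single day, with intake
    levels typical of Australian adults living with higher weight (low fruit
    and vegetable variety, grain around 3-4 serves, discretionary foods
    around 2 serves/day) and misreporters planted in both EI:BMR tails.
    """

    seed: int = 0
    n_participants: int = 280
    n_days: int = 4
    n_food_items: int = 32
    fraction_insufficient_days: float = 8.0 / 280.0
    tail_misreporter_fraction: float = 0.05
    day_noise_sd: float = 0.25  # lognormal sigma of day-to-day multipliers

    # median daily intakes (units of the scored dimension) and lognormal
    # sigmas of the between-participant distributions
    serve_medians: dict[str, float] = field(default_factory=lambda: {
        "fruit": 0.8, "vegetable": 2.8, "grain": 3.8, "milk_alt": 1.2, "meat_alt": 1.2,
    })
    serve_sigmas: dict[str, float] = field(default_factory=lambda: {
        "fruit": 0.6, "vegetable": 0.4, "grain": 0.4, "milk_alt": 0.5, "meat_alt": 0.4,
    })
    # gamma-distributed moderation energy, mean kJ/day per class
    moderation_mean_kj: dict[str, float] = field(default_factory=lambda: {
        "discretionary_food": 1350.0, "ssb": 150.0, "alcohol": 120.0,
    })
    water_cups_mean: float = 4.5
    water_cups_sd: float = 2.0

    # covariate model
    age_range: tuple[float, float] = (18.0, 65.0)
    proportion_women: float = 0.71
    age_effect: float = 0.35  # latent-quality SDs per SD of age
    attention_effect: float = 0.45  # per step of attention-to-diet
    latent_noise_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.n_participants < 3:
            raise ValidationError("n_participants must be >= 3")
        if not (0 <= self.fraction_insufficient_days < 1):
            raise ValidationError("fraction_insufficient_days must be in [0, 1)")
        if not (0 <= self.tail_misreporter_fraction < 1):
            raise ValidationError("tail_misreporter_fraction must be in [0, 1)")
        if self.n_days < 1:
            raise ValidationError("n_days must be >= 1")


def generate_composition(spec: FixtureSpec) -> CompositionTable:
    """Deterministic composition table with all classes represented."""
    if spec.n_food_items < _MIN_ITEMS:
        raise ValidationError(
            f"n_food_items must be >= {_MIN_ITEMS} to cover all core groups "
            f"and moderation classes"
        )
    rng = np.random.default_rng(spec.seed)
    entries: list[FoodCompositionEntry] = []

    for group, (item_id, label, energy, serves) in _REF_ITEMS.items():
        entries.append(FoodCompositionEntry(
            item_id=item_id, label=label, energy_kj_per_100g=energy,
            serves_per_100g={group: serves},
        ))

    budget = spec.n_food_items - len(entries) - len(_MODERATION_ITEMS)
    n_fruit = max(1, min(len(_FRUIT_LABELS), budget // 2))
    n_veg = max(1, min(len(_VEG_LABELS), budget - n_fruit))
    for i in range(n_fruit):
        entries.append(FoodCompositionEntry(
            item_id=f"FRUIT{i + 1:02d}", label=_FRUIT_LABELS[i],
            energy_kj_per_100g=_FRUIT_ENERGY,
            serves_per_100g={"fruit": _FRUIT_SERVES},
            fruit_type_id=f"FT{i + 1:02d}",
        ))
    for i in range(n_veg):
        entries.append(FoodCompositionEntry(
            item_id=f"VEG{i + 1:02d}", label=_VEG_LABELS[i],
            energy_kj_per_100g=_VEG_ENERGY,
            serves_per_100g={"vegetable": _VEG_SERVES},
            vegetable_type_id=f"VT{i + 1:02d}",
        ))
    for item_id, label, energy, cls in _MODERATION_ITEMS:
        entries.append(FoodCompositionEntry(
            item_id=item_id, label=label, energy_kj_per_100g=energy,
            moderation_class=cls,
        ))
    if len(entries) < spec.n_food_items:
        item_id, label, energy, serves = _SANDWICH
        entries.append(FoodCompositionEntry(
            item_id=item_id, label=label, energy_kj_per_100g=energy,
            serves_per_100g=serves,
            vegetable_type_id="VT01",  # salad: same type as the first veg item
        ))
    for item_id, label, energy, cls in _EXTRA_MODERATION:
        if len(entries) >= spec.n_food_items:
            break
        entries.append(FoodCompositionEntry(
            item_id=item_id, label=label, energy_kj_per_100g=energy,
            moderation_class=cls,
        ))
    k = 0
    while len(entries) < spec.n_food_items:
        # filler single-group items with randomised composition
        k += 1
        group = ("grain", "milk_alt", "meat_alt", "vegetable", "fruit")[k % 5]
        entry = FoodCompositionEntry(
            item_id=f"MISC{k:03d}", label=f"misc item {k}",
            energy_kj_per_100g=float(np.round(rng.uniform(100, 1800), 1)),
            serves_per_100g={group: float(np.round(rng.uniform(0.2, 2.0), 3))},
            fruit_type_id="FT01" if group == "fruit" else None,
            vegetable_type_id="VT01" if group == "vegetable" else None,
        )
        entries.append(entry)
    return build_table(entries)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)
    return float(min(max(mean, lo), hi))


def generate_cohort(
    spec: FixtureSpec,
    composition: Optional[CompositionTable] = None,
) -> tuple[list[IntakeEvent], pd.DataFrame, pd.DataFrame]:
    """Generate (intake events, participant profiles, true mean daily intakes).

    Exactly ``round(fraction_insufficient_days * N)`` participants record a
    single day; ``round(tail_misreporter_fraction * N)`` of the remainder
    have every food amount scaled by a heavy (~x2.5) or light (~x0.2)
    misreporting factor, planting them in the EI:BMR tails. The truth table
    carries the pre-misreporting intended mean daily intakes.
    """
    if composition is None:
        composition = generate_composition(spec)
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_participants
    width = max(3, len(str(n)))
    pids = [f"P{i + 1:0{width}d}" for i in range(n)]

    n_short = round(spec.fraction_insufficient_days * n)
    short_ids = set(rng.choice(pids, size=n_short, replace=False)) if n_short else set()
    remaining = [p for p in pids if p not in short_ids]
    n_tail = min(round(spec.tail_misreporter_fraction * n), len(remaining))
    tail_ids = list(rng.choice(remaining, size=n_tail, replace=False)) if n_tail else []
    heavy_ids = set(tail_ids[: n_tail // 2])
    light_ids = set(tail_ids[n_tail // 2:])

    fruit_items = sorted(e.item_id for e in composition if e.fruit_type_id and e.item_id.startswith("FRUIT"))
    veg_items = sorted(e.item_id for e in composition if e.vegetable_type_id and e.item_id.startswith("VEG"))
    has_sandwich = "SANDWICH" in composition

    attention_levels = ("a_lot", "a_bit", "not_much")
    ipaq_levels = ("low", "moderate", "high")
    education_levels = ("secondary", "diploma", "university")

    events: list[IntakeEvent] = []
    profiles = []
    truth = []

    for pid in pids:
        sex = "woman" if rng.random() < spec.proportion_women else "man"
        age = float(np.round(rng.uniform(*spec.age_range), 1))
        weight = round(_truncated_normal(
            rng, 95.5 if sex == "woman" else 108.9,
            13.7 if sex == "woman" else 15.9, 62.0, 180.0), 1)
        height_m = _truncated_normal(rng, 1.63 if sex == "woman" else 1.77, 0.07, 1.4, 2.1)
        bmi = round(weight / height_m**2, 1)
        attention = attention_levels[int(rng.choice(3, p=[0.08, 0.72, 0.20]))]
        ipaq = ipaq_levels[int(rng.choice(3, p=[0.48, 0.33, 0.19]))]
        education = education_levels[int(rng.choice(3, p=[0.11, 0.24, 0.65]))]

        # latent diet quality propensity, standardised-ish
        age_mid = (spec.age_range[0] + spec.age_range[1]) / 2
        age_sd = (spec.age_range[1] - spec.age_range[0]) / math.sqrt(12)
        attn_step = {"a_lot": 1.0, "a_bit": 0.0, "not_much": -1.0}[attention]
        z = (spec.age_effect * (age - age_mid) / age_sd
             + spec.attention_effect * attn_step
             + rng.normal(0.0, spec.latent_noise_sd))

        targets: dict[str, float] = {}
        for g, med in spec.serve_medians.items():
            sigma = spec.serve_sigmas[g]
            targets[g] = float(med * math.exp(0.3 * z + rng.normal(0, sigma)))
        # keep optimal-range intakes in a plausible span
        targets["grain"] = min(targets["grain"], 9.0)
        targets["meat_alt"] = min(targets["meat_alt"], 4.0)
        for cls, mean_kj in spec.moderation_mean_kj.items():
            shape = 2.0
            kj = rng.gamma(shape, mean_kj / shape) * math.exp(-0.3 * z)
            targets[cls] = float(kj)  # energy kJ/day; serves = kj/600 downstream
        water = max(0.0, rng.normal(spec.water_cups_mean + 0.4 * z, spec.water_cups_sd))

        max_fruit_var = len(fruit_items)
        max_veg_var = len(veg_items)
        fruit_var = 0 if targets["fruit"] <= 1e-12 else int(
            min(max_fruit_var, max(1, round(1 + 0.8 * z + rng.normal(0, 0.8)))))
        veg_var = 0 if targets["vegetable"] <= 1e-12 else int(
            min(max_veg_var, max(1, round(3 + 0.8 * z + rng.normal(0, 0.8)))))

        cholesterol = round(max(2.5, rng.normal(5.3, 1.0) - 0.15 * z), 2)
        body_fat = round(_truncated_normal(
            rng, 43.2 if sex == "woman" else 31.7, 3.5 if sex == "woman" else 5.2,
            15.0, 60.0), 1)

        days = [1] if pid in short_ids else list(range(1, spec.n_days + 1))
        factor = 1.0
        if pid in heavy_ids:
            factor = float(rng.uniform(2.2, 3.0))
        elif pid in light_ids:
            factor = float(rng.uniform(0.15, 0.30))

        for day in days:
            noise = {}
            dims = list(targets) + ["water"]
            for dim in dims:
                if spec.day_noise_sd > 0:
                    noise[dim] = float(rng.lognormal(
                        -spec.day_noise_sd**2 / 2, spec.day_noise_sd))
                else:
                    noise[dim] = 1.0
            day_target = {dim: targets[dim] * noise[dim] for dim in targets}
            day_water = water * noise["water"]

            # multi-group sandwich on the first day when targets allow it
            if has_sandwich and day == 1 and veg_var >= 1:
                s_entry = composition.lookup("SANDWICH")
                grams = 100.0
                contrib = {g: grams * s / 100.0
                           for g, s in s_entry.serves_per_100g.items()}
                if all(day_target.get(g, 0.0) >= c for g, c in contrib.items()):
                    events.append(IntakeEvent(pid, day, "SANDWICH", grams * factor))
                    for g, c in contrib.items():
                        day_target[g] -= c

            for group, (item_id, _, _, serves) in _REF_ITEMS.items():
                t = day_target.get(group, 0.0)
                if t > 1e-12:
                    events.append(IntakeEvent(pid, day, item_id, t * 100.0 / serves * factor))
            if fruit_var > 0 and day_target["fruit"] > 1e-12:
                per = day_target["fruit"] / fruit_var
                for item_id in fruit_items[:fruit_var]:
                    events.append(IntakeEvent(
                        pid, day, item_id, per * 100.0 / _FRUIT_SERVES * factor))
            if veg_var > 0 and day_target["vegetable"] > 1e-12:
                per = day_target["vegetable"] / veg_var
                for item_id in veg_items[:veg_var]:
                    events.append(IntakeEvent(
                        pid, day, item_id, per * 100.0 / _VEG_SERVES * factor))
            for cls, item_id in (("discretionary_food", "DISC01"),
                                 ("ssb", "SSB01"), ("alcohol", "ALC01")):
                kj = day_target.get(cls, 0.0)
                if kj > 1e-12:
                    entry = composition.lookup(item_id)
                    events.append(IntakeEvent(
                        pid, day, item_id, kj * 100.0 / entry.energy_kj_per_100g * factor))
            if day_water > 1e-12:
                events.append(IntakeEvent(pid, day, WATER_TOKEN, day_water, unit="cup"))

        profiles.append({
            "participant_id": pid, "scoring_sex": sex, "age_years": age,
            "weight_kg": weight, "bmi": bmi, "body_fat_pct": body_fat,
            "total_cholesterol": cholesterol, "attention_to_diet": attention,
            "ipaq_category": ipaq, "education": education,
        })
        truth.append({
            "participant_id": pid,
            "days_recorded": len(days),
            "misreporting_factor": factor,
            **{f"true_serves_{g}": targets[g] for g in spec.serve_medians},
            **{f"true_serves_{c}": targets[c] / 600.0 for c in spec.moderation_mean_kj},
            "true_water_cups_per_day": water,
            "true_fruit_variety_per_day": float(fruit_var),
            "true_vegetable_variety_per_day": float(veg_var),
        })

    return events, pd.DataFrame(profiles), pd.DataFrame(truth)


def write_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write composition.csv, intake.csv, participants.csv and truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    composition = generate_composition(spec)
    events, profiles, truth = generate_cohort(spec, composition)
    paths = {
        "composition": out / "composition.csv",
        "intake": out / "intake.csv",
        "participants": out / "participants.csv",
        "truth": out / "truth.csv",
    }
    composition.write_csv(paths["composition"])
    events_to_frame(events).to_csv(paths["intake"], index=False)
    profiles.to_csv(paths["participants"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return paths
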