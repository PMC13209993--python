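"""Score one participant's 4-day food record.

Builds a tiny composition table, disaggregates the record into food-group
serves (note the sandwich feeding three groups at once), pools discretionary
energy at 600 kJ/serve, and applies the 11-component band scorer.
"""

from dqscore import (
    CompositionTable,
    FoodCompositionEntry,
    IntakeEvent,
    WATER_TOKEN,
    score_participant,
    summarise_participant,
)

table = CompositionTable([
    FoodCompositionEntry("BREAD", "bread, wholemeal", 1000.0, {"grain": 1.5}),
    FoodCompositionEntry("APPLE", "apple", 250.0, {"fruit": 2 / 3},
                         fruit_type_id="FT_APPLE"),
    FoodCompositionEntry("BANANA", "banana", 380.0, {"fruit": 2 / 3},
                         fruit_type_id="FT_BANANA"),
    FoodCompositionEntry("SALAD", "mixed salad", 100.0, {"vegetable": 4 / 3},
                         vegetable_type_id="VT_SALAD"),
    FoodCompositionEntry("MILK", "milk, reduced fat", 270.0, {"milk_alt": 0.4}),
    FoodCompositionEntry("SANDWICH", "chicken & salad sandwich", 850.0,
                         {"grain": 1.2, "vegetable": 0.5, "meat_alt": 0.5},
                         vegetable_type_id="VT_SALAD"),
    FoodCompositionEntry("PIE", "meat pie", 1600.0,
                         moderation_class="discretionary_food"),
    FoodCompositionEntry("COLA", "cola", 180.0, moderation_class="ssb"),
])

events = []
for day in (1, 2, 3, 4):
    events += [
        IntakeEvent("p01", day, "BREAD", 120.0),     # ~1.8 grain serves
        IntakeEvent("p01", day, "SANDWICH", 200.0),  # grain + veg + meat
        IntakeEvent("p01", day, "APPLE", 150.0),     # 1 fruit serve
        IntakeEvent("p01", day, "MILK", 300.0),
        IntakeEvent("p01", day, WATER_TOKEN, 5.0, unit="cup"),
    ]
events += [
    IntakeEvent("p01", 1, "BANANA", 120.0),
    IntakeEvent("p01", 2, "PIE", 150.0),   # 2400 kJ discretionary
    IntakeEvent("p01", 3, "COLA", 375.0),  # 675 kJ SSB
]

summary = summarise_participant(events, table)
print(f"days recorded:        {summary.days_recorded}")
for group in ("grain", "fruit", "vegetable", "milk_alt", "meat_alt",
              "discretionary_food", "ssb", "alcohol"):
    print(f"  {group:<20s} {summary.serves[group]:.3f} serves/day")
print(f"  water                {summary.water_cups_per_day:.2f} cups/day")
print(f"  fruit variety        {summary.fruit_variety_per_day:.2f} types/day")

result = score_participant(summary, sex="woman")
print("\ncomponent points (0-10, varieties 0-5):")
for comp, pts in result.component_points.items():
    print(f"  {comp:<20s} {pts:g}")
print(f"\nDQS total: {result.total:g} / 100")
print("Higher totals mean closer alignment of mean daily intake with the")
print("Australian Dietary Guidelines food-group recommendations.")
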