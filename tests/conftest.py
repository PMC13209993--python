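import pytest

from dqscore.composition import CompositionTable, FoodCompositionEntry


@pytest.fixture(scope="session")
def small_table() -> CompositionTable:
    """A hand-built composition table covering every item class."""
    return CompositionTable([
        FoodCompositionEntry("BREAD", "bread, white", 1000.0, {"grain": 1.5}),
        FoodCompositionEntry("APPLE", "apple", 250.0, {"fruit": 2 / 3},
                             fruit_type_id="FT_APPLE"),
        FoodCompositionEntry("BANANA", "banana", 380.0, {"fruit": 2 / 3},
                             fruit_type_id="FT_BANANA"),
        FoodCompositionEntry("CARROT", "carrot", 120.0, {"vegetable": 4 / 3},
                             vegetable_type_id="VT_CARROT"),
        FoodCompositionEntry("TOMATO", "tomato", 80.0, {"vegetable": 4 / 3},
                             vegetable_type_id="VT_TOMATO"),
        FoodCompositionEntry("MILK", "milk", 270.0, {"milk_alt": 0.4}),
        FoodCompositionEntry("CHICKEN", "chicken breast", 800.0, {"meat_alt": 1.5}),
        FoodCompositionEntry(
            "SANDWICH", "chicken & salad sandwich", 850.0,
            {"grain": 1.2, "vegetable": 0.5, "meat_alt": 0.5},
            vegetable_type_id="VT_SALAD",
        ),
        FoodCompositionEntry("PIE", "meat pie", 1600.0,
                             moderation_class="discretionary_food"),
        FoodCompositionEntry("COLA", "cola", 180.0, moderation_class="ssb"),
        FoodCompositionEntry("BEER", "beer", 160.0, moderation_class="alcohol"),
    ])
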