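import pytest

import dietghge as dg
from dietghge.knowledge_base import (
    Boundary,
    EmissionFactor,
    FoodComponent,
    FoodRecordEntry,
    KnowledgeBase,
    Participant,
    Recipe,
    RecipeKind,
    Sex,
)


def _component(fid, *, protein=0.0, fat=0.0, carb=0.0, alcohol=0.0,
               sugars=(0.0, 0.0, 0.0, 0.0), **extra):
    """Hand-built component with energy consistent with its macros."""
    energy = 17.0 * protein + 37.0 * fat + 17.0 * carb + 29.0 * alcohol
    nutrients = {
        "protein_g": protein,
        "fat_g": fat,
        "carbohydrate_g": carb,
        "alcohol_g": alcohol,
    }
    nutrients.update(extra)
    return FoodComponent(
        food_id=fid,
        name=fid,
        energy_kj=energy,
        energy_excl_alcohol_kj=energy - 29.0 * alcohol,
        sucrose_total_g=sugars[0],
        monosacch_total_g=sugars[1],
        sucrose_natural_g=sugars[2],
        monosacch_natural_g=sugars[3],
        nutrients=nutrients,
    )


@pytest.fixture(scope="session")
def tiny_kb() -> KnowledgeBase:
    """A five-food, three-recipe, four-participant fixture with exactly
    known numbers, covering per-gas factors, yields, losses, alcohol,
    natural/added sugar and nested dishes."""
    components = {
        c.food_id: c
        for c in [
            _component("grain", protein=10, fat=2, carb=60, fibre_g=8.0,
                       iron_mg=4.0),
            _component("meat", protein=30, fat=20, vitamin_b12_ug=2.0,
                       iron_mg=2.5),
            _component("veg", carb=5, fibre_g=3.0, vitamin_c_mg=40.0),
            _component("drink", carb=10, sugars=(5.0, 5.0, 0.2, 0.3)),
            _component("beer", carb=3, alcohol=4),
        ]
    }
    factors = {
        "grain": EmissionFactor(food_id="grain", co2e_per_kg=0.8,
                                boundary=Boundary.retail),
        "meat": EmissionFactor(food_id="meat", ch4_kg=0.5, n2o_kg=0.01,
                               co2_kg=1.0, boundary=Boundary.farm_gate,
                               yield_factor=0.7, edible_fraction=0.9,
                               waste_before=0.05, waste_after=0.1),
        "veg": EmissionFactor(food_id="veg", co2e_per_kg=0.4,
                              boundary=Boundary.farm_gate, waste_before=0.1,
                              waste_after=0.1),
        "drink": EmissionFactor(food_id="drink", co2e_per_kg=0.3,
                                boundary=Boundary.retail),
        "beer": EmissionFactor(food_id="beer", co2e_per_kg=0.5,
                               boundary=Boundary.retail),
    }
    recipes = {
        "bread": Recipe(dish_id="bread", kind=RecipeKind.calculated,
                        ingredients=(("grain", 1.0),)),
        "dishA": Recipe(dish_id="dishA", kind=RecipeKind.calculated,
                        ingredients=(("bread", 0.5), ("veg", 0.5))),
        "plate": Recipe(dish_id="plate", kind=RecipeKind.approximate,
                        ingredients=(("dishA", 0.4), ("meat", 0.4),
                                     ("veg", 0.2))),
    }
    participants = {
        p.participant_id: p
        for p in [
            Participant(participant_id="P1", sex=Sex.F, age=45, height_m=1.65,
                        weight_kg=62.0, pal=1.6),
            Participant(participant_id="P2", sex=Sex.F, age=55, height_m=1.68,
                        weight_kg=70.0, pal=1.5),
            Participant(participant_id="P3", sex=Sex.M, age=30, height_m=1.82,
                        weight_kg=85.0, pal=1.8),
            Participant(participant_id="P4", sex=Sex.M, age=60, height_m=1.78,
                        weight_kg=80.0, pal=1.4),
        ]
    }
    records = []
    menu = {
        "P1": [("grain", 200), ("meat", 150), ("dishA", 100), ("drink", 330)],
        "P2": [("grain", 250), ("veg", 150), ("plate", 300), ("beer", 330)],
        "P3": [("meat", 250), ("grain", 300), ("drink", 500), ("veg", 100)],
        "P4": [("plate", 400), ("bread", 150), ("beer", 400), ("veg", 200)],
    }
    for pid, items in menu.items():
        for day in range(1, 5):
            for fid, grams in items:
                records.append(
                    FoodRecordEntry(participant_id=pid, day=day, food_id=fid,
                                    portion_g=grams * (1 + 0.1 * day))
                )
    return KnowledgeBase(
        components=components,
        factors=factors,
        recipes=recipes,
        participants=participants,
        records=records,
        rules=dg.default_rules(),
    )


@pytest.fixture(scope="session")
def synth_cohort():
    """Mid-size synthetic survey shared by the generator/pipeline tests."""
    cfg = dg.GeneratorConfig(seed=11, n_participants=400)
    kb = dg.make_knowledge_base(cfg)
    participants, records, truth = dg.make_cohort(cfg, kb)
    kb.participants = participants
    kb.records = records
    return cfg, kb, truth
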