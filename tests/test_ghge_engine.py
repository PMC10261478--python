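"""Portion-to-CO2e conversion: factor corrections, recipe flattening,
participant aggregation, and the algebraic properties of the chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dietghge as dg
from dietghge.errors import EmptyRecordError, RecipeCycleError, UnresolvedFoodError
from dietghge.ghge_engine import (
    apply_losses,
    cohort_ghge,
    effective_factor_table,
    entry_emission,
    gwp_to_co2e,
    harmonize_boundary,
    participant_ghge,
    raw_to_prepared,
    resolve_recipe,
)
from dietghge.knowledge_base import (
    AnalysisConfig,
    Boundary,
    FoodRecordEntry,
    KnowledgeBase,
    Recipe,
    RecipeKind,
)
from oracles import brute_participant_ghge

finite = st.floats(0, 1e3, allow_nan=False)


@pytest.mark.parametrize(
    "gases, expected",
    [
        ((1, 0, 0), 34.0),
        ((0, 1, 0), 296.0),
        ((0, 0, 1), 1.0),
        ((0, 0, 0), 0.0),
        ((0.1, 0.05, 2), 20.2),
    ],
)
def test_gwp_aggregation(gases, expected):
    assert gwp_to_co2e(*gases) == pytest.approx(expected, abs=1e-12)


def test_gwp_rejects_negative_mass():
    with pytest.raises(ValueError):
        gwp_to_co2e(-0.1, 0, 0)


@settings(derandomize=True, max_examples=50)
@given(finite, finite, finite, st.floats(0.1, 10))
def test_gwp_is_linear_in_each_gas(ch4, n2o, co2, c):
    lhs = gwp_to_co2e(c * ch4, c * n2o, c * co2)
    assert lhs == pytest.approx(c * gwp_to_co2e(ch4, n2o, co2), rel=1e-12)


@pytest.mark.parametrize(
    "factor, boundary, addendum, expected",
    [
        (2.0, Boundary.farm_gate, 0.5, 2.5),
        (3.0, Boundary.retail, 0.5, 3.0),
        (0.0, Boundary.farm_gate, 0.0, 0.0),
    ],
)
def test_boundary_harmonization(factor, boundary, addendum, expected):
    assert harmonize_boundary(factor, boundary, addendum) == expected


@pytest.mark.parametrize(
    "factor, yield_factor, expected",
    [
        (4.0, 2.5, 1.6),           # hydration (rice-like)
        (7.3, 1.0, 7.3),           # identity yield
        (26.0, 0.7, 26.0 / 0.7),   # dehydration (meat-like)
    ],
)
def test_yield_conversion_preserves_mass_balance(factor, yield_factor, expected):
    prepared = raw_to_prepared(factor, yield_factor)
    assert prepared == pytest.approx(expected, rel=1e-12)
    # emissions of 1 raw kg equal emissions of the prepared mass it becomes
    assert prepared * yield_factor == pytest.approx(factor, rel=1e-12)


@pytest.mark.parametrize(
    "args, expected",
    [
        ((2.0, 1.0, 0.0, 0.0), 2.0),
        ((2.0, 0.5, 0.0, 0.0), 4.0),
        ((1.0, 1.0, 0.1, 0.1), 1.0 / 0.81),
    ],
)
def test_loss_and_waste_correction(args, expected):
    assert apply_losses(*args) == pytest.approx(expected, rel=1e-9)


@settings(derandomize=True, max_examples=50)
@given(
    st.floats(0.01, 100),
    st.floats(0.05, 1.0),
    st.floats(0, 0.9),
    st.floats(0, 0.9),
)
def test_losses_never_decrease_the_factor(f, edible, wb, wa):
    assert apply_losses(f, edible, wb, wa) >= f


@pytest.mark.parametrize("bad", [(1.0, 0.0, 0, 0), (1.0, 1.0, 1.0, 0)])
def test_loss_domain_errors(bad):
    with pytest.raises(ValueError):
        apply_losses(*bad)


def test_resolve_single_component_dish(tiny_kb):
    assert resolve_recipe("bread", tiny_kb.recipes) == [("grain", 1.0)]


def test_resolve_nested_dish_merges_leaf_shares(tiny_kb):
    # dishA = 0.5 bread + 0.5 veg, bread = 1.0 grain
    assert resolve_recipe("dishA", tiny_kb.recipes) == [
        ("grain", 0.5),
        ("veg", 0.5),
    ]


def test_three_ingredient_plate_flattens_with_unit_mass(tiny_kb):
    leaves = resolve_recipe("plate", tiny_kb.recipes)
    assert [fid for fid, _ in leaves] == ["grain", "meat", "veg"]
    assert sum(s for _, s in leaves) == pytest.approx(1.0, abs=1e-12)


def test_recipe_cycle_names_the_dish_chain():
    recipes = {
        "a": Recipe(dish_id="a", kind=RecipeKind.calculated,
                    ingredients=(("b", 1.0),)),
        "b": Recipe(dish_id="b", kind=RecipeKind.calculated,
                    ingredients=(("a", 1.0),)),
    }
    with pytest.raises(RecipeCycleError, match="a -> b -> a"):
        resolve_recipe("a", recipes)


def test_unknown_ingredient_raises_reference_error(tiny_kb):
    recipes = dict(tiny_kb.recipes)
    recipes["ghost"] = Recipe(
        dish_id="ghost", kind=RecipeKind.calculated,
        ingredients=(("nothing", 1.0),),
    )
    with pytest.raises(UnresolvedFoodError, match="nothing"):
        resolve_recipe("ghost", recipes, leaf_ids=set(tiny_kb.components))


def test_entry_emission_scales_with_portion():
    eff = {"x": 1.6}
    entry = FoodRecordEntry(participant_id="P", day=1, food_id="x",
                            portion_g=250)
    assert entry_emission(entry, eff) == pytest.approx(0.4)
    zero = entry.model_copy(update={"portion_g": 0.0})
    assert entry_emission(zero, eff) == 0.0


def test_two_level_dish_emission_by_hand(tiny_kb):
    # 100 g of dishA with leaf factors c=2 (veg), d=4 (grain)
    eff = {"dishA": 0.5 * 2 + 0.5 * 4}
    entry = FoodRecordEntry(participant_id="P", day=1, food_id="dishA",
                            portion_g=100)
    assert entry_emission(entry, eff) == pytest.approx(0.3)


def test_participant_ghge_daily_mean_and_annualization():
    eff = {"x": 1.0}
    entries = [
        FoodRecordEntry(participant_id="P", day=d, food_id="x",
                        portion_g=1000.0 * d)
        for d in range(1, 5)
    ]
    res = participant_ghge(entries, eff, n_days=4)
    assert res.daily_co2e_kg == pytest.approx(2.5)
    assert res.annual_co2e_t == pytest.approx(2.5 * 365 / 1000, rel=1e-12)
    # magnitude check: ~4.9 kg/day is ~1.8 t/year
    one = [FoodRecordEntry(participant_id="P", day=1, food_id="x",
                           portion_g=4930.0)]
    assert participant_ghge(one, eff, n_days=1).annual_co2e_t == pytest.approx(
        1.79945
    )


def test_participant_ghge_requires_entries():
    with pytest.raises(EmptyRecordError):
        participant_ghge([], {}, n_days=4)


def test_cohort_ghge_matches_brute_force_oracle(tiny_kb):
    cfg = AnalysisConfig(postfarm_addendum=0.4)
    result = cohort_ghge(tiny_kb, cfg)
    oracle = brute_participant_ghge(tiny_kb, cfg)
    for pid, daily in oracle.items():
        assert result.loc[pid, "daily_co2e_kg"] == pytest.approx(
            daily, rel=1e-9
        )


def test_cohort_ghge_is_linear_in_portions(tiny_kb):
    cfg = AnalysisConfig()
    base = cohort_ghge(tiny_kb, cfg)
    scaled_records = [
        e.model_copy(update={"portion_g": e.portion_g * 3.0})
        for e in tiny_kb.records
    ]
    kb3 = KnowledgeBase(
        components=tiny_kb.components,
        factors=tiny_kb.factors,
        recipes=tiny_kb.recipes,
        participants=tiny_kb.participants,
        records=scaled_records,
    )
    scaled = cohort_ghge(kb3, cfg)
    assert np.allclose(
        scaled["daily_co2e_kg"], 3.0 * base["daily_co2e_kg"], rtol=1e-12
    )


def test_increasing_waste_never_decreases_anyones_emissions(tiny_kb):
    cfg = AnalysisConfig()
    base = cohort_ghge(tiny_kb, cfg)
    factors = dict(tiny_kb.factors)
    factors["grain"] = factors["grain"].model_copy(
        update={"waste_after": 0.3}
    )
    kb = KnowledgeBase(
        components=tiny_kb.components,
        factors=factors,
        recipes=tiny_kb.recipes,
        participants=tiny_kb.participants,
        records=tiny_kb.records,
    )
    bumped = cohort_ghge(kb, cfg)
    assert (bumped["daily_co2e_kg"] >= base["daily_co2e_kg"] - 1e-12).all()


def test_effective_table_covers_components_and_dishes(tiny_kb):
    eff = effective_factor_table(tiny_kb, AnalysisConfig())
    assert set(eff) == set(tiny_kb.factors) | set(tiny_kb.recipes)
    assert all(v >= 0 for v in eff.values())
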