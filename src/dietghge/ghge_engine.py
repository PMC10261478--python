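"""Conversion of recorded portions to per-participant CO2e emissions.

Each LCA emission factor is quoted per kg of food product at a stated
system boundary.  The chain applied to every factor is:

1. aggregate per-gas masses to CO2e with global-warming potentials
   (skipped when the factor is already quoted in CO2e);
2. harmonize the system boundary to retail by adding a standard
   post-farm addendum to farm-gate factors;
3. convert raw mass to prepared mass through the cooking yield
   (hydration > 1, e.g. rice; dehydration < 1, e.g. meat);
4. inflate for unavoidable losses (edible fraction, e.g. shell and
   bone) and avoidable waste before and after preparation.

Portions in the food record are prepared, as-consumed grams, so the
yield and loss corrections apply to the factor, never to the portion.
Dishes are flattened to leaf components through the recipe graph; the
recipe shares operate on prepared mass, so any cooking yield is already
embedded in each leaf's harmonized factor and is not double-counted.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import EmptyRecordError, RecipeCycleError, UnresolvedFoodError
from .knowledge_base import (
    AnalysisConfig,
    Boundary,
    EmissionFactor,
    FoodRecordEntry,
    GwpConfig,
    KnowledgeBase,
    Recipe,
)


class HarmonizedFactor(BaseModel):
    """Emissions per kg of as-consumed food after all corrections."""

    model_config = ConfigDict(frozen=True)

    food_id: str
    co2e_per_prepared_kg: float = Field(ge=0, allow_inf_nan=False)


class GhgeResult(BaseModel):
    """Per-participant emission summary.

    ``energy_adjusted_co2e_kg`` and ``quartile`` are filled by the
    exposure-statistics stage.
    """

    participant_id: str
    daily_co2e_kg: float = Field(ge=0)
    annual_co2e_t: float = Field(ge=0)
    energy_adjusted_co2e_kg: float | None = None
    quartile: int | None = None


def gwp_to_co2e(
    ch4_kg: float, n2o_kg: float, co2_kg: float, gwp: GwpConfig | None = None
) -> float:
    """Aggregate per-gas masses (kg) to kg CO2e with 100-year GWPs."""
    gwp = gwp or GwpConfig()
    if min(ch4_kg, n2o_kg, co2_kg) < 0:
        raise ValueError("gas masses must be non-negative")
    return gwp.ch4 * ch4_kg + gwp.n2o * n2o_kg + gwp.co2 * co2_kg


def harmonize_boundary(
    co2e_per_kg: float, boundary: Boundary, addendum: float
) -> float:
    """Bring a factor to the retail boundary.

    Farm-gate factors gain the post-farm addendum (processing, packaging,
    distribution and retail); factors already at retail pass through.
    """
    if addendum < 0:
        raise ValueError("post-farm addendum must be non-negative")
    if boundary is Boundary.farm_gate:
        return co2e_per_kg + addendum
    return co2e_per_kg


def raw_to_prepared(co2e_per_raw_kg: float, yield_factor: float) -> float:
    """Re-express a per-raw-kg factor per prepared kg.

    Mass balance: (output factor) x (prepared mass) equals
    (input factor) x (raw mass), with prepared = yield x raw.
    """
    if yield_factor <= 0:
        raise ValueError("yield factor must be positive")
    return co2e_per_raw_kg / yield_factor


def apply_losses(
    co2e_per_kg: float,
    edible_fraction: float,
    waste_before: float,
    waste_after: float,
) -> float:
    """Inflate a factor so that emissions of discarded mass are carried
    by the mass actually consumed."""
    if not (0 < edible_fraction <= 1):
        raise ValueError("edible fraction must be in (0, 1]")
    if not (0 <= waste_before < 1 and 0 <= waste_after < 1):
        raise ValueError("waste fractions must be in [0, 1)")
    return co2e_per_kg / (edible_fraction * (1 - waste_before) * (1 - waste_after))


def harmonized_factor(
    factor: EmissionFactor, cfg: AnalysisConfig | None = None
) -> HarmonizedFactor:
    """Run the full correction chain for one emission factor."""
    cfg = cfg or AnalysisConfig()
    if factor.is_per_gas:
        base = gwp_to_co2e(factor.ch4_kg, factor.n2o_kg, factor.co2_kg, cfg.gwp)
    else:
        base = factor.co2e_per_kg
    at_retail = harmonize_boundary(base, factor.boundary, cfg.postfarm_addendum)
    prepared = raw_to_prepared(at_retail, factor.yield_factor)
    consumed = apply_losses(
        prepared, factor.edible_fraction, factor.waste_before, factor.waste_after
    )
    return HarmonizedFactor(food_id=factor.food_id, co2e_per_prepared_kg=consumed)


def resolve_recipe(
    dish_id: str,
    recipes: Mapping[str, Recipe],
    leaf_ids: set[str] | None = None,
) -> list[tuple[str, float]]:
    """Flatten a dish to base components with prepared-mass shares.

    Returns ``(component_id, share)`` pairs sorted by component id; the
    shares sum to 1 to within 1e-9 at every nesting depth.  ``leaf_ids``,
    when given, restricts which identifiers count as base components;
    anything not in ``recipes`` or ``leaf_ids`` raises
    :class:`UnresolvedFoodError`.
    """
    if dish_id not in recipes:
        raise UnresolvedFoodError(f"unknown dish '{dish_id}'")
    shares: dict[str, float] = {}

    def expand(fid: str, weight: float, stack: tuple[str, ...]) -> None:
        if fid in stack:
            raise RecipeCycleError(stack[stack.index(fid):] + (fid,))
        if fid in recipes:
            for ing_id, share in recipes[fid].ingredients:
                expand(ing_id, weight * share, stack + (fid,))
        else:
            if leaf_ids is not None and fid not in leaf_ids:
                raise UnresolvedFoodError(
                    f"recipe '{stack[-1]}' refers to unknown ingredient '{fid}'"
                )
            shares[fid] = shares.get(fid, 0.0) + weight

    expand(dish_id, 1.0, ())
    return sorted(shares.items())


def effective_factor_table(
    kb: KnowledgeBase, cfg: AnalysisConfig | None = None
) -> dict[str, float]:
    """kg CO2e per prepared kg for every component *and* every dish."""
    cfg = cfg or AnalysisConfig()
    eff = {
        fid: harmonized_factor(f, cfg).co2e_per_prepared_kg
        for fid, f in kb.factors.items()
    }
    for dish_id in kb.recipes:
        leaves = resolve_recipe(dish_id, kb.recipes, leaf_ids=set(kb.factors))
        eff[dish_id] = sum(share * eff[fid] for fid, share in leaves)
    return eff


def entry_emission(
    entry: FoodRecordEntry, effective_factors: Mapping[str, float]
) -> float:
    """kg CO2e of one recorded portion."""
    if entry.food_id not in effective_factors:
        raise UnresolvedFoodError(
            f"no emission factor resolves for food '{entry.food_id}'"
        )
    return entry.portion_g / 1000.0 * effective_factors[entry.food_id]


def participant_ghge(
    entries: Sequence[FoodRecordEntry],
    effective_factors: Mapping[str, float],
    n_days: int = 4,
    days_per_year: float = 365.0,
) -> GhgeResult:
    """Average daily and annualized emissions for one participant.

    The divisor is the nominal record length ``n_days``: a day without
    entries counts as a zero-intake day.
    """
    if not entries:
        raise EmptyRecordError("participant has no food-record entries")
    pids = {e.participant_id for e in entries}
    if len(pids) != 1:
        raise ValueError(f"entries belong to several participants: {sorted(pids)}")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    total = sum(entry_emission(e, effective_factors) for e in entries)
    daily = total / n_days
    return GhgeResult(
        participant_id=pids.pop(),
        daily_co2e_kg=daily,
        annual_co2e_t=daily * days_per_year / 1000.0,
    )


def cohort_ghge(
    kb: KnowledgeBase, cfg: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Vectorized per-participant emissions for the whole cohort.

    Returns a frame indexed by participant id with columns
    ``daily_co2e_kg`` and ``annual_co2e_t``, sorted by participant id.
    """
    cfg = cfg or AnalysisConfig()
    if not kb.records:
        raise EmptyRecordError("no food records loaded")
    eff = effective_factor_table(kb, cfg)
    rec = pd.DataFrame(
        {
            "participant_id": [e.participant_id for e in kb.records],
            "food_id": [e.food_id for e in kb.records],
            "portion_g": [e.portion_g for e in kb.records],
        }
    )
    missing = set(rec["food_id"]) - set(eff)
    if missing:
        raise UnresolvedFoodError(
            f"no emission factor resolves for: {sorted(missing)[:5]}"
        )
    rec["co2e_kg"] = rec["portion_g"] / 1000.0 * rec["food_id"].map(eff)
    daily = rec.groupby("participant_id")["co2e_kg"].sum() / cfg.n_days
    out = pd.DataFrame(
        {
            "daily_co2e_kg": daily,
            "annual_co2e_t": daily * cfg.days_per_year / 1000.0,
        }
    ).sort_index()
    out.index.name = "participant_id"
    return out
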