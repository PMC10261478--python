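"""Per-participant daily-average nutrient intakes and energy shares.

Intakes are computed from per-100 g composition of prepared foods,
dishes being flattened through the recipe graph with prepared-mass
shares.  Energy percentages (E%) are shares of daily energy *excluding
alcohol energy*.  Added sugar is total sucrose + monosaccharides minus
the naturally occurring amounts, floored at zero.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import (
    DegenerateDataError,
    EmptyRecordError,
    MissingNutrientError,
    UnresolvedFoodError,
)
from .ghge_engine import resolve_recipe
from .knowledge_base import (
    AnalysisConfig,
    FoodComponent,
    FoodRecordEntry,
    KnowledgeBase,
)

log = logging.getLogger(__name__)

#: composition columns that are energies (kJ) rather than masses
_ENERGY_COLS = ("energy_kj", "energy_excl_alcohol_kj")
_SUGAR_COLS = (
    "sucrose_total_g",
    "monosacch_total_g",
    "sucrose_natural_g",
    "monosacch_natural_g",
)
#: long-chain and plant n-3 fatty-acid columns summed into ``n3_g``
_N3_PARTS = ("ala_g", "epa_g", "dha_g")


class NutrientProfile(BaseModel):
    """Daily-average intake of one participant.

    ``intake`` maps nutrient column names to amounts per day in the
    column's natural unit; ``epct`` maps macronutrient names to their
    share of non-alcohol energy.
    """

    model_config = ConfigDict(frozen=True)

    participant_id: str
    intake: dict[str, float]
    energy_kj: float = Field(ge=0)
    energy_excl_alcohol_kj: float = Field(ge=0)
    epct: dict[str, float]
    added_sugar_g: float = Field(ge=0)
    added_sugar_epct: float = Field(ge=0)

    def value_for(self, nutrient: str, on_epct_scale: bool) -> float:
        """Look up the quantity a reference rule compares against."""
        if on_epct_scale:
            if nutrient == "added_sugar":
                return self.added_sugar_epct
            if nutrient not in self.epct:
                raise MissingNutrientError(
                    f"no E% value for '{nutrient}' in profile "
                    f"{self.participant_id}"
                )
            return self.epct[nutrient]
        if nutrient not in self.intake:
            raise MissingNutrientError(
                f"nutrient '{nutrient}' missing from profile {self.participant_id}"
            )
        return self.intake[nutrient]


def component_matrix(components: Mapping[str, FoodComponent]) -> pd.DataFrame:
    """Wide per-100 g matrix (components only), indexed by food id."""
    rows = {}
    nutrient_cols = sorted({k for c in components.values() for k in c.nutrients})
    for fid, c in components.items():
        row = {col: c.nutrients.get(col, 0.0) for col in nutrient_cols}
        row["energy_kj"] = c.energy_kj
        row["energy_excl_alcohol_kj"] = c.energy_excl_alcohol_kj
        row["sucrose_total_g"] = c.sucrose_total_g
        row["monosacch_total_g"] = c.monosacch_total_g
        row["sucrose_natural_g"] = c.sucrose_natural_g
        row["monosacch_natural_g"] = c.monosacch_natural_g
        rows[fid] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)


def effective_composition(kb: KnowledgeBase) -> pd.DataFrame:
    """Per-100 g matrix for components and dishes alike.

    A dish's row is the share-weighted sum of its leaf components, since
    100 g of the dish is made up of ``share × 100 g`` of each leaf.
    """
    base = component_matrix(kb.components)
    dish_rows = {}
    for dish_id in kb.recipes:
        leaves = resolve_recipe(dish_id, kb.recipes, leaf_ids=set(kb.components))
        vec = sum(share * base.loc[fid] for fid, share in leaves)
        dish_rows[dish_id] = vec
    if dish_rows:
        base = pd.concat([base, pd.DataFrame.from_dict(dish_rows, orient="index")])
    return base


def entry_nutrients(
    entry: FoodRecordEntry, composition: pd.DataFrame
) -> pd.Series:
    """Nutrient vector of one recorded portion: (portion/100) × per-100 g."""
    if entry.food_id not in composition.index:
        raise UnresolvedFoodError(
            f"no composition resolves for food '{entry.food_id}'"
        )
    return entry.portion_g / 100.0 * composition.loc[entry.food_id]


def energy_percent(
    grams: Mapping[str, float],
    energy_excl_alcohol_kj: float,
    epct_nutrients: Mapping[str, tuple[str, float]],
) -> dict[str, float]:
    """E% of non-alcohol energy for each configured macronutrient.

    ``epct_nutrients`` maps the macronutrient name to its gram column and
    metabolizable-energy factor (kJ/g).
    """
    if energy_excl_alcohol_kj <= 0:
        raise DegenerateDataError(
            "non-alcohol energy intake is zero; E% undefined"
        )
    return {
        name: 100.0 * grams.get(col, 0.0) * kj_per_g / energy_excl_alcohol_kj
        for name, (col, kj_per_g) in epct_nutrients.items()
    }


def added_sugar(
    sucrose_total_g: float,
    monosacch_total_g: float,
    sucrose_natural_g: float,
    monosacch_natural_g: float,
) -> float:
    """Added sugar (g/day): totals minus natural amounts, floored at zero."""
    value = (sucrose_total_g + monosacch_total_g) - (
        sucrose_natural_g + monosacch_natural_g
    )
    if value < 0:
        if value < -1e-6:
            log.warning(
                "natural sugars exceed totals by %.3g g/d; flooring added "
                "sugar at 0",
                -value,
            )
        return 0.0
    return value


def _profile_from_totals(
    participant_id: str, totals: pd.Series, cfg: AnalysisConfig
) -> NutrientProfile:
    energy = float(totals["energy_kj"])
    energy_ex = float(totals["energy_excl_alcohol_kj"])
    intake = {
        k: float(max(v, 0.0))
        for k, v in totals.items()
        if k not in _ENERGY_COLS
    }
    intake["n3_g"] = sum(float(totals.get(c, 0.0)) for c in _N3_PARTS)
    epct = energy_percent(intake, energy_ex, cfg.epct_nutrients)
    added_g = added_sugar(*(float(totals.get(c, 0.0)) for c in _SUGAR_COLS))
    carb_kj_per_g = cfg.energy_factors_kj_per_g["carbohydrate"]
    added_epct = 100.0 * added_g * carb_kj_per_g / energy_ex
    intake["added_sugar_g"] = added_g
    return NutrientProfile(
        participant_id=participant_id,
        intake=intake,
        energy_kj=energy,
        energy_excl_alcohol_kj=energy_ex,
        epct=epct,
        added_sugar_g=added_g,
        added_sugar_epct=added_epct,
    )


def daily_profile(
    entries: Sequence[FoodRecordEntry],
    composition: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
) -> NutrientProfile:
    """Daily-average profile for one participant: sum over the record
    divided by the nominal number of record days."""
    cfg = cfg or AnalysisConfig()
    if not entries:
        raise EmptyRecordError("participant has no food-record entries")
    pids = {e.participant_id for e in entries}
    if len(pids) != 1:
        raise ValueError(f"entries belong to several participants: {sorted(pids)}")
    totals = sum(entry_nutrients(e, composition) for e in entries) / cfg.n_days
    return _profile_from_totals(pids.pop(), totals, cfg)


def cohort_profiles(
    kb: KnowledgeBase, cfg: AnalysisConfig | None = None
) -> dict[str, NutrientProfile]:
    """Daily-average profiles for every participant with records."""
    cfg = cfg or AnalysisConfig()
    if not kb.records:
        raise EmptyRecordError("no food records loaded")
    comp = effective_composition(kb)
    rec = pd.DataFrame(
        {
            "participant_id": [e.participant_id for e in kb.records],
            "food_id": [e.food_id for e in kb.records],
            "portion_g": [e.portion_g for e in kb.records],
        }
    )
    missing = set(rec["food_id"]) - set(comp.index)
    if missing:
        raise UnresolvedFoodError(
            f"no composition resolves for: {sorted(missing)[:5]}"
        )
    per100 = comp.loc[rec["food_id"]].to_numpy()
    scaled = per100 * (rec["portion_g"].to_numpy() / 100.0)[:, None]
    wide = pd.DataFrame(scaled, columns=comp.columns)
    wide["participant_id"] = rec["participant_id"].to_numpy()
    daily = wide.groupby("participant_id").sum() / cfg.n_days
    return {
        pid: _profile_from_totals(pid, row, cfg)
        for pid, row in daily.sort_index().iterrows()
    }


def profiles_frame(profiles: Mapping[str, NutrientProfile]) -> pd.DataFrame:
    """Flatten profiles to one row per participant for CSV output."""
    rows = {}
    for pid, p in profiles.items():
        row = dict(p.intake)
        row["energy_kj"] = p.energy_kj
        row["energy_excl_alcohol_kj"] = p.energy_excl_alcohol_kj
        row.update({f"{k}_epct": v for k, v in p.epct.items()})
        row["added_sugar_epct"] = p.added_sugar_epct
        rows[pid] = row
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "participant_id"
    return out
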