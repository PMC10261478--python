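"""Typed tables, validation and configuration for the diet-emissions pipeline.

The pipeline consumes five delimited text tables — food composition,
emission factors, recipes, participants and food records — plus a
nutrient-recommendation rule table and a YAML analysis configuration.
This module owns the row types (pydantic models), the table readers and
writers, and cross-table referential validation.

All tables are plain delimited text with a header row; comma is the
default separator and tab is accepted.  Nutrient names are free strings
matched exactly between the composition table and the rule table; the
package ships an editable default rule file (``data/nnr2012_rules.csv``)
whose numeric values are a user-maintained transcription of the Nordic
Nutrition Recommendations 2012 and can be replaced wholesale.
"""

from __future__ import annotations

import enum
import graphlib
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

from .errors import ConfigError, SchemaError, TableRowError

log = logging.getLogger(__name__)

_TOL = 1e-9


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class Boundary(str, enum.Enum):
    """Last production stage included in an LCA emission factor."""

    farm_gate = "farm_gate"
    retail = "retail"


class RecipeKind(str, enum.Enum):
    #: full ingredient list from the composition database
    calculated = "calculated"
    #: own estimation for a mixed dish without a database recipe
    approximate = "approximate"


class RuleKind(str, enum.Enum):
    range_epct = "range_epct"        # energy-share window (e.g. protein 10–20 E%)
    upper_epct = "upper_epct"        # energy-share ceiling (SFA, added sugar)
    lower_threshold = "lower_threshold"  # absolute floor (fibre, essential FA)
    ar = "ar"                        # average requirement
    li = "li"                        # lower intake level (potassium)
    ri = "ri"                        # recommended intake (magnesium, sodium)


#: rule kinds whose bound is expressed on the E% scale
EPCT_KINDS = frozenset({RuleKind.range_epct, RuleKind.upper_epct})


class FoodComponent(BaseModel):
    """One food item with per-100 g nutrient content of the prepared food."""

    model_config = ConfigDict(frozen=True)

    food_id: str
    name: str
    energy_kj: float = Field(ge=0)
    energy_excl_alcohol_kj: float = Field(ge=0)
    sucrose_total_g: float = Field(default=0.0, ge=0)
    monosacch_total_g: float = Field(default=0.0, ge=0)
    sucrose_natural_g: float = Field(default=0.0, ge=0)
    monosacch_natural_g: float = Field(default=0.0, ge=0)
    #: remaining nutrients, amount per 100 g in each nutrient's natural
    #: unit; zero entries are dropped (absent and zero are synonymous)
    nutrients: dict[str, float] = Field(default_factory=dict)

    @field_validator("nutrients", mode="before")
    @classmethod
    def _drop_zero_entries(cls, value):
        if isinstance(value, dict):
            return {k: v for k, v in value.items() if v != 0}
        return value

    @model_validator(mode="after")
    def _check_invariants(self) -> "FoodComponent":
        if self.energy_excl_alcohol_kj > self.energy_kj + _TOL:
            raise ValueError(
                f"{self.food_id}: energy_excl_alcohol_kj exceeds energy_kj"
            )
        if self.sucrose_natural_g > self.sucrose_total_g + _TOL:
            raise ValueError(f"{self.food_id}: natural sucrose exceeds total sucrose")
        if self.monosacch_natural_g > self.monosacch_total_g + _TOL:
            raise ValueError(
                f"{self.food_id}: natural monosaccharides exceed total"
            )
        for key, value in self.nutrients.items():
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{self.food_id}: nutrient {key} must be >= 0")
        return self


class EmissionFactor(BaseModel):
    """Cradle-to-boundary emissions per kg of a food product.

    The factor is quoted either directly in kg CO2e per kg product or as
    per-gas masses (kg CH4, N2O and fossil CO2 per kg product) that are
    aggregated with global-warming potentials downstream.  ``yield_factor``
    converts raw mass to prepared mass (hydration > 1, dehydration < 1);
    ``edible_fraction`` removes unavoidable losses such as shell and bone;
    the two waste fractions are avoidable waste before and after
    preparation.
    """

    model_config = ConfigDict(frozen=True)

    food_id: str
    co2e_per_kg: Optional[float] = Field(default=None, ge=0)
    ch4_kg: Optional[float] = Field(default=None, ge=0)
    n2o_kg: Optional[float] = Field(default=None, ge=0)
    co2_kg: Optional[float] = Field(default=None, ge=0)
    boundary: Boundary = Boundary.retail
    yield_factor: float = Field(default=1.0, gt=0)
    edible_fraction: float = Field(default=1.0, gt=0, le=1)
    waste_before: float = Field(default=0.0, ge=0, lt=1)
    waste_after: float = Field(default=0.0, ge=0, lt=1)

    @model_validator(mode="after")
    def _exactly_one_quotation(self) -> "EmissionFactor":
        gases = [self.ch4_kg, self.n2o_kg, self.co2_kg]
        has_gases = all(g is not None for g in gases)
        some_gases = any(g is not None for g in gases)
        if self.co2e_per_kg is not None and some_gases:
            raise ValueError(
                f"{self.food_id}: give either co2e_per_kg or the per-gas "
                "triple, not both"
            )
        if self.co2e_per_kg is None and not has_gases:
            raise ValueError(
                f"{self.food_id}: needs co2e_per_kg or a complete "
                "(ch4_kg, n2o_kg, co2_kg) triple"
            )
        return self

    @property
    def is_per_gas(self) -> bool:
        return self.co2e_per_kg is None


#: hard cap on the ingredient list of an approximate (estimated) recipe
MAX_APPROXIMATE_INGREDIENTS = 3


class Recipe(BaseModel):
    """Decomposition of a dish into ingredient prepared-mass shares.

    Ingredients may themselves be dishes; the graph must be acyclic.
    Approximate recipes (own estimations for dishes without a database
    recipe) are capped at three ingredients; calculated dishes carry the
    full database ingredient list and are uncapped.
    """

    model_config = ConfigDict(frozen=True)

    dish_id: str
    kind: RecipeKind
    ingredients: tuple[tuple[str, float], ...]

    @model_validator(mode="after")
    def _check_shares(self) -> "Recipe":
        if not self.ingredients:
            raise ValueError(f"{self.dish_id}: empty ingredient list")
        total = 0.0
        for ing_id, share in self.ingredients:
            if not (0.0 < share <= 1.0):
                raise ValueError(
                    f"{self.dish_id}: share of {ing_id} must be in (0, 1]"
                )
            total += share
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.dish_id}: ingredient shares sum to {total!r}, not 1"
            )
        if (
            self.kind is RecipeKind.approximate
            and len(self.ingredients) > MAX_APPROXIMATE_INGREDIENTS
        ):
            raise ValueError(
                f"{self.dish_id}: approximate recipe lists "
                f"{len(self.ingredients)} ingredients "
                f"(maximum {MAX_APPROXIMATE_INGREDIENTS})"
            )
        return self


class Participant(BaseModel):
    model_config = ConfigDict(frozen=True)

    participant_id: str
    sex: Sex
    age: float = Field(ge=18, le=80)
    height_m: float = Field(gt=0.5, lt=2.5)
    weight_kg: float = Field(gt=20, lt=350)
    pal: float = Field(gt=0)

    @property
    def bmi(self) -> float:
        return self.weight_kg / self.height_m**2


class FoodRecordEntry(BaseModel):
    model_config = ConfigDict(frozen=True)

    participant_id: str
    day: int = Field(ge=1)
    food_id: str
    portion_g: float = Field(ge=0, allow_inf_nan=False)


class ReferenceRule(BaseModel):
    """One nutrient recommendation with sex/age dispatch.

    ``low``/``high`` are on the E% scale for ``range_epct``/``upper_epct``
    rules and in the nutrient's own unit otherwise.  ``direction``
    overrides the default comparison for threshold-style rules: the
    recommended intake for sodium, for instance, acts as a ceiling
    (adherence = intake at or below the value) while every other
    AR/LI/RI rule is a floor.
    """

    model_config = ConfigDict(frozen=True)

    rule_id: str
    nutrient: str
    kind: RuleKind
    sex: str = "both"  # "F", "M" or "both"
    age_min: float = 18
    age_max: float = 80
    low: Optional[float] = None
    high: Optional[float] = None
    direction: Optional[str] = None  # "ge" or "le", only for ar/li/ri

    @model_validator(mode="after")
    def _check_bounds(self) -> "ReferenceRule":
        if self.sex not in {"F", "M", "both"}:
            raise ValueError(f"{self.rule_id}: sex must be F, M or both")
        if self.age_min > self.age_max:
            raise ValueError(f"{self.rule_id}: empty age interval")
        if self.kind is RuleKind.range_epct:
            if self.low is None or self.high is None:
                raise ValueError(f"{self.rule_id}: range rule needs low and high")
            if not self.low < self.high:
                raise ValueError(f"{self.rule_id}: range needs low < high")
        elif self.kind is RuleKind.upper_epct:
            if self.high is None or self.low is not None:
                raise ValueError(f"{self.rule_id}: upper rule needs only high")
        else:
            if self.low is None or self.high is not None:
                raise ValueError(f"{self.rule_id}: threshold rule needs only low")
        if self.direction is not None and self.direction not in {"ge", "le"}:
            raise ValueError(f"{self.rule_id}: direction must be 'ge' or 'le'")
        return self

    def applies_to(self, sex: Sex, age: float) -> bool:
        sex_ok = self.sex == "both" or self.sex == sex.value
        return sex_ok and self.age_min <= age <= self.age_max


class GwpConfig(BaseModel):
    """100-year global warming potentials used to aggregate gases to CO2e."""

    ch4: float = Field(default=34.0, gt=0)
    n2o: float = Field(default=296.0, gt=0)
    co2: float = Field(default=1.0, gt=0)


class GoldbergConfig(BaseModel):
    """Constants of the Goldberg plausibility band on the EI:BMR scale.

    The coefficients of variation are in percent: within-person variation
    of energy intake (``cv_wei``), error of the BMR estimate (``cv_wb``)
    and variation of PAL (``cv_tp``).  Defaults follow Black's standard
    parameterization for short records.
    """

    cv_wei: float = Field(default=23.0, ge=0)
    cv_wb: float = Field(default=8.5, ge=0)
    cv_tp: float = Field(default=15.0, ge=0)
    n_days: int = Field(default=4, ge=1)
    z: float = Field(default=1.96, ge=0)


class BmrCoefficient(BaseModel):
    """One row of the weight-based linear BMR table: slope·kg + intercept (MJ/d).

    The age interval is half-open: ``age_min <= age < age_max``.
    """

    sex: Sex
    age_min: float
    age_max: float
    slope_mj_per_kg: float
    intercept_mj: float


#: Schofield-type weight-based BMR equations (MJ/day), adults
DEFAULT_BMR_COEFFICIENTS: tuple[BmrCoefficient, ...] = tuple(
    BmrCoefficient(
        sex=Sex(s), age_min=a0, age_max=a1, slope_mj_per_kg=sl, intercept_mj=ic
    )
    for s, a0, a1, sl, ic in [
        ("F", 18, 30, 0.062, 2.036),
        ("F", 30, 60, 0.034, 3.538),
        ("F", 60, 81, 0.038, 2.755),
        ("M", 18, 30, 0.063, 2.896),
        ("M", 30, 60, 0.048, 3.653),
        ("M", 60, 81, 0.049, 2.459),
    ]
)

#: conventional metabolizable-energy factors, kJ per gram
DEFAULT_ENERGY_FACTORS = {
    "protein": 17.0,
    "fat": 37.0,
    "carbohydrate": 17.0,
    "alcohol": 29.0,
}

#: macronutrients for which an E% column is derived, mapped to the gram
#: column of the composition table and the energy factor applied
DEFAULT_EPCT_NUTRIENTS = {
    "protein": ("protein_g", 17.0),
    "fat": ("fat_g", 37.0),
    "carbohydrate": ("carbohydrate_g", 17.0),
    "sfa": ("sfa_g", 37.0),
    "mufa": ("mufa_g", 37.0),
    "pufa": ("pufa_g", 37.0),
}


class AnalysisConfig(BaseModel):
    """Every tunable constant of the analysis, serializable to YAML."""

    gwp: GwpConfig = Field(default_factory=GwpConfig)
    #: kg CO2e/kg added to farm-gate factors to harmonize the system
    #: boundary to retail (processing, packaging, distribution, retail).
    #: No authoritative default is bundled; supply a value from an LCA
    #: source appropriate to the study setting.
    postfarm_addendum: float = Field(default=0.0, ge=0)
    goldberg: GoldbergConfig = Field(default_factory=GoldbergConfig)
    n_days: int = Field(default=4, ge=1)
    days_per_year: float = Field(default=365.0, gt=0)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    n_quartiles: int = Field(default=4, ge=2)
    energy_factors_kj_per_g: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_ENERGY_FACTORS)
    )
    epct_nutrients: dict[str, tuple[str, float]] = Field(
        default_factory=lambda: dict(DEFAULT_EPCT_NUTRIENTS)
    )
    bmr_coefficients: tuple[BmrCoefficient, ...] = Field(
        default_factory=lambda: DEFAULT_BMR_COEFFICIENTS
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(payload)
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# table I/O


@dataclass
class KnowledgeBase:
    """All loaded input tables, keyed by their natural identifiers."""

    components: dict[str, FoodComponent] = field(default_factory=dict)
    factors: dict[str, EmissionFactor] = field(default_factory=dict)
    recipes: dict[str, Recipe] = field(default_factory=dict)
    participants: dict[str, Participant] = field(default_factory=dict)
    records: list[FoodRecordEntry] = field(default_factory=list)
    rules: list[ReferenceRule] = field(default_factory=list)


_COMPONENT_FIXED = [
    "food_id",
    "name",
    "energy_kj",
    "energy_excl_alcohol_kj",
    "sucrose_total_g",
    "monosacch_total_g",
    "sucrose_natural_g",
    "monosacch_natural_g",
]

_SCHEMAS: dict[str, list[str]] = {
    "composition": ["food_id", "name", "energy_kj", "energy_excl_alcohol_kj"],
    "emission_factors": ["food_id", "boundary"],
    "recipes": ["dish_id", "kind", "ingredient_id", "mass_share"],
    "participants": ["participant_id", "sex", "age", "height_m", "weight_kg", "pal"],
    "records": ["participant_id", "day", "food_id", "portion_g"],
    "rules": ["rule_id", "nutrient", "kind", "sex", "age_min", "age_max"],
}


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def _require_columns(df: pd.DataFrame, schema: str) -> None:
    for col in _SCHEMAS[schema]:
        if col not in df.columns:
            raise SchemaError(f"{schema} table is missing required column '{col}'")


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def load_table(path: str | Path, schema: str, *, n_days: int = 4):
    """Read and validate one delimited table.

    Returns a list of row models (or of :class:`Recipe` for the recipes
    table, which is stored in long format with one row per ingredient).
    Raises :class:`SchemaError` for missing columns and
    :class:`TableRowError` (with the offending row index) for invariant
    violations.
    """
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown table schema '{schema}'")
    df = _read_delimited(path)
    _require_columns(df, schema)
    out = _rows_to_models(df, schema, n_days=n_days)
    log.info("loaded %d %s rows from %s", len(out), schema, path)
    return out


def _rows_to_models(df: pd.DataFrame, schema: str, *, n_days: int = 4):
    if schema == "recipes":
        return _build_recipes(df)
    builders = {
        "composition": _build_component,
        "emission_factors": _build_factor,
        "participants": _build_participant,
        "records": lambda row: _build_record(row, n_days),
        "rules": _build_rule,
    }
    build = builders[schema]
    out = []
    for idx, row in enumerate(df.to_dict(orient="records")):
        try:
            out.append(build(row))
        except (ValidationError, ValueError) as exc:
            raise TableRowError(idx, _short_error(exc)) from exc
    return out


def _short_error(exc: Exception) -> str:
    if isinstance(exc, ValidationError):
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "row"
        return f"{loc}: {first['msg']}"
    return str(exc)


def _build_component(row: Mapping) -> FoodComponent:
    nutrients = {
        k: float(v)
        for k, v in row.items()
        if k not in _COMPONENT_FIXED and _opt(v) is not None
    }
    kwargs = {
        k: float(row[k])
        for k in _COMPONENT_FIXED[2:]  # numeric columns only
        if k in row and _opt(row[k]) is not None
    }
    kwargs["food_id"] = str(row["food_id"])
    kwargs["name"] = str(row.get("name", row["food_id"]))
    return FoodComponent(nutrients=nutrients, **kwargs)


def _build_factor(row: Mapping) -> EmissionFactor:
    return EmissionFactor(
        food_id=str(row["food_id"]),
        co2e_per_kg=_opt(row.get("co2e_per_kg")),
        ch4_kg=_opt(row.get("ch4_kg")),
        n2o_kg=_opt(row.get("n2o_kg")),
        co2_kg=_opt(row.get("co2_kg")),
        boundary=Boundary(str(row["boundary"])),
        yield_factor=_opt(row.get("yield_factor")) or 1.0,
        edible_fraction=_opt(row.get("edible_fraction")) or 1.0,
        waste_before=_opt(row.get("waste_before")) or 0.0,
        waste_after=_opt(row.get("waste_after")) or 0.0,
    )


def _build_recipes(df: pd.DataFrame) -> list[Recipe]:
    recipes = []
    for offset, (dish_id, grp) in enumerate(df.groupby("dish_id", sort=False)):
        kinds = set(grp["kind"].astype(str))
        try:
            if len(kinds) != 1:
                raise ValueError(f"{dish_id}: inconsistent recipe kind {kinds}")
            recipes.append(
                Recipe(
                    dish_id=str(dish_id),
                    kind=RecipeKind(kinds.pop()),
                    ingredients=tuple(
                        (str(r.ingredient_id), float(r.mass_share))
                        for r in grp.itertuples()
                    ),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise TableRowError(int(grp.index[0]), _short_error(exc)) from exc
    return recipes


def _build_participant(row: Mapping) -> Participant:
    return Participant(
        participant_id=str(row["participant_id"]),
        sex=Sex(str(row["sex"])),
        age=float(row["age"]),
        height_m=float(row["height_m"]),
        weight_kg=float(row["weight_kg"]),
        pal=float(row["pal"]),
    )


def _build_record(row: Mapping, n_days: int) -> FoodRecordEntry:
    entry = FoodRecordEntry(
        participant_id=str(row["participant_id"]),
        day=int(row["day"]),
        food_id=str(row["food_id"]),
        portion_g=float(row["portion_g"]),
    )
    if entry.day > n_days:
        raise ValueError(f"day {entry.day} outside the {n_days}-day record")
    return entry


def _build_rule(row: Mapping) -> ReferenceRule:
    direction = row.get("direction")
    if isinstance(direction, float) and math.isnan(direction):
        direction = None
    if isinstance(direction, str) and not direction.strip():
        direction = None
    return ReferenceRule(
        rule_id=str(row["rule_id"]),
        nutrient=str(row["nutrient"]),
        kind=RuleKind(str(row["kind"])),
        sex=str(row["sex"]),
        age_min=float(row["age_min"]),
        age_max=float(row["age_max"]),
        low=_opt(row.get("low")),
        high=_opt(row.get("high")),
        direction=direction,
    )


def write_table(objs: Sequence, schema: str, path: str | Path) -> None:
    """Write row models back to delimited text (inverse of :func:`load_table`)."""
    frames = {
        "composition": _components_to_frame,
        "emission_factors": _factors_to_frame,
        "recipes": _recipes_to_frame,
        "participants": _participants_to_frame,
        "records": _records_to_frame,
        "rules": _rules_to_frame,
    }
    if schema not in frames:
        raise SchemaError(f"unknown table schema '{schema}'")
    frames[schema](list(objs)).to_csv(path, index=False)


def _components_to_frame(objs: list[FoodComponent]) -> pd.DataFrame:
    nutrient_cols = sorted({k for o in objs for k in o.nutrients})
    rows = []
    for o in objs:
        row = {k: getattr(o, k) for k in _COMPONENT_FIXED}
        row.update({k: o.nutrients.get(k, 0.0) for k in nutrient_cols})
        rows.append(row)
    return pd.DataFrame(rows, columns=_COMPONENT_FIXED + nutrient_cols)


def _factors_to_frame(objs: list[EmissionFactor]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "food_id": o.food_id,
                "co2e_per_kg": o.co2e_per_kg,
                "ch4_kg": o.ch4_kg,
                "n2o_kg": o.n2o_kg,
                "co2_kg": o.co2_kg,
                "boundary": o.boundary.value,
                "yield_factor": o.yield_factor,
                "edible_fraction": o.edible_fraction,
                "waste_before": o.waste_before,
                "waste_after": o.waste_after,
            }
            for o in objs
        ]
    )


def _recipes_to_frame(objs: list[Recipe]) -> pd.DataFrame:
    rows = [
        {
            "dish_id": o.dish_id,
            "kind": o.kind.value,
            "ingredient_id": ing,
            "mass_share": share,
        }
        for o in objs
        for ing, share in o.ingredients
    ]
    return pd.DataFrame(rows)


def _participants_to_frame(objs: list[Participant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": o.participant_id,
                "sex": o.sex.value,
                "age": o.age,
                "height_m": o.height_m,
                "weight_kg": o.weight_kg,
                "pal": o.pal,
            }
            for o in objs
        ]
    )


def _records_to_frame(objs: list[FoodRecordEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": o.participant_id,
                "day": o.day,
                "food_id": o.food_id,
                "portion_g": o.portion_g,
            }
            for o in objs
        ]
    )


def _rules_to_frame(objs: list[ReferenceRule]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rule_id": o.rule_id,
                "nutrient": o.nutrient,
                "kind": o.kind.value,
                "sex": o.sex,
                "age_min": o.age_min,
                "age_max": o.age_max,
                "low": o.low,
                "high": o.high,
                "direction": o.direction,
            }
            for o in objs
        ]
    )


def load_knowledge_base(
    directory: str | Path, *, n_days: int = 4, rules_path: str | Path | None = None
) -> KnowledgeBase:
    """Load the five standard tables (plus rules) from one directory.

    Expected file names: ``composition.csv``, ``emission_factors.csv``,
    ``recipes.csv``, ``participants.csv``, ``records.csv`` and, unless
    ``rules_path`` is given, ``rules.csv``.
    """
    directory = Path(directory)
    components = load_table(directory / "composition.csv", "composition")
    factors = load_table(directory / "emission_factors.csv", "emission_factors")
    recipes = load_table(directory / "recipes.csv", "recipes")
    participants = load_table(directory / "participants.csv", "participants")
    records = load_table(directory / "records.csv", "records", n_days=n_days)
    rules = load_table(rules_path or directory / "rules.csv", "rules")
    return KnowledgeBase(
        components={c.food_id: c for c in components},
        factors={f.food_id: f for f in factors},
        recipes={r.dish_id: r for r in recipes},
        participants={p.participant_id: p for p in participants},
        records=records,
        rules=rules,
    )


def default_rules() -> list[ReferenceRule]:
    """The bundled 27-recommendation rule table.

    The values are an editable transcription of the Nordic Nutrition
    Recommendations 2012 maintained by the user of the package; the
    analysis logic never depends on the specific numbers.
    """
    with resources.files("dietghge.data").joinpath("nnr2012_rules.csv").open() as fh:
        df = pd.read_csv(fh)
    return _rows_to_models(df, "rules")


# ---------------------------------------------------------------------------
# cross-reference validation


@dataclass
class ValidationReport:
    """Outcome of referential validation across the loaded tables.

    ``unresolved`` holds ``(context, identifier)`` pairs, sorted, so the
    report is independent of input row order.
    """

    unresolved: list[tuple[str, str]] = field(default_factory=list)
    cycles: list[list[str]] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not self.unresolved and not self.cycles

    def summary(self) -> str:
        if self.is_clean:
            return "all cross-references resolve; recipe graph is acyclic"
        lines = [f"{len(self.unresolved)} unresolved reference(s)"]
        lines += [f"  {ctx}: {ref}" for ctx, ref in self.unresolved]
        for cyc in self.cycles:
            lines.append("  cycle: " + " -> ".join(cyc))
        return "\n".join(lines)


def validate_cross_references(kb: KnowledgeBase) -> ValidationReport:
    """Check that every referenced identifier resolves and recipes are acyclic.

    A food id in a record must name a component or a dish; a recipe
    ingredient must name a component or another dish; every component that
    is actually consumed (directly or as a recipe leaf) must carry an
    emission factor; record participant ids must exist in the participant
    table.  A cycle in the recipe graph is reported with the dish chain.
    """
    unresolved: set[tuple[str, str]] = set()
    known_foods = set(kb.components) | set(kb.recipes)

    for entry in kb.records:
        if entry.food_id not in known_foods:
            unresolved.add(("record food_id", entry.food_id))
        if kb.participants and entry.participant_id not in kb.participants:
            unresolved.add(("record participant_id", entry.participant_id))

    graph: dict[str, set[str]] = {}
    for recipe in kb.recipes.values():
        deps = set()
        for ing_id, _ in recipe.ingredients:
            if ing_id in kb.recipes:
                deps.add(ing_id)
            elif ing_id not in kb.components:
                unresolved.add((f"recipe {recipe.dish_id} ingredient", ing_id))
        graph[recipe.dish_id] = deps

    cycles: list[list[str]] = []
    try:
        graphlib.TopologicalSorter(graph).prepare()
    except graphlib.CycleError as exc:
        cycles.append([str(n) for n in exc.args[1]])

    consumed = _consumed_components(kb, cycles)
    for food_id in consumed:
        if food_id not in kb.factors:
            unresolved.add(("emission factor for", food_id))

    return ValidationReport(unresolved=sorted(unresolved), cycles=cycles)


def _consumed_components(kb: KnowledgeBase, cycles: list) -> set[str]:
    """Component ids reachable from the food records (skipped if cyclic)."""
    if cycles:
        return set()
    consumed: set[str] = set()
    stack = [e.food_id for e in kb.records]
    seen: set[str] = set()
    while stack:
        fid = stack.pop()
        if fid in seen:
            continue
        seen.add(fid)
        if fid in kb.recipes:
            stack.extend(ing for ing, _ in kb.recipes[fid].ingredients)
        elif fid in kb.components:
            consumed.add(fid)
    return consumed
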