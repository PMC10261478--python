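"""Energy adjustment, emission quartiles, recommendation adherence and
group-comparison statistics.

The exposure is each participant's average daily diet-related emission.
Because reported intake volume varies with body size and with
under-reporting, the emission is adjusted for total energy intake with
the residual method: regress emissions on energy, keep the residuals and
add back the fitted emission at the cohort mean energy so the values
stay on an interpretable scale.  Quartiles of the adjusted exposure are
formed within sex strata.  Adherence to the nutrient-recommendation
rule table is scored per participant with sex/age dispatch, and group
differences are tested with the Kruskal-Wallis test (continuous
variables) and the chi-square test (adherence proportions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .errors import DegenerateDataError, EmptyRecordError, RuleTableError
from .knowledge_base import (
    AnalysisConfig,
    EPCT_KINDS,
    Participant,
    ReferenceRule,
    RuleKind,
    Sex,
)
from .nutrient_engine import NutrientProfile


class AdherenceVector(BaseModel):
    """Which recommendations one participant fulfils, and how many."""

    model_config = ConfigDict(frozen=True)

    participant_id: str
    per_rule: dict[str, bool]
    total: int = Field(ge=0)

    @model_validator(mode="after")
    def _total_consistent(self) -> "AdherenceVector":
        if self.total != sum(self.per_rule.values()):
            raise ValueError("total does not equal the number of satisfied rules")
        return self


def energy_adjust(
    ghge: np.ndarray | Sequence[float], energy: np.ndarray | Sequence[float]
) -> np.ndarray:
    """Residual-method energy adjustment of the emission exposure.

    Fits ``ghge = a + b * energy`` by least squares and returns
    ``residual + (a + b * mean(energy))``.  The adjusted values are
    uncorrelated with energy and keep the crude mean.
    """
    ghge = np.asarray(ghge, dtype=float)
    energy = np.asarray(energy, dtype=float)
    if ghge.shape != energy.shape or ghge.ndim != 1:
        raise ValueError("ghge and energy must be 1-d arrays of equal length")
    if ghge.size < 3:
        raise DegenerateDataError("residual adjustment needs >= 3 participants")
    if np.ptp(energy) == 0:
        raise DegenerateDataError(
            "energy intake is constant; skip the residual adjustment"
        )
    slope, intercept = np.polyfit(energy, ghge, 1)
    fitted = intercept + slope * energy
    constant = intercept + slope * energy.mean()
    return ghge - fitted + constant


def assign_quartiles(
    values: pd.Series,
    strata: pd.Series | None = None,
    n_groups: int = 4,
) -> pd.Series:
    """Rank-based quartering within each stratum.

    ``values`` is indexed by participant id.  Within a stratum the
    participants are ordered by value, ties broken by the stable
    participant-id order, and cut into ``n_groups`` consecutive blocks
    whose sizes differ by at most one (earlier groups take the
    remainder).  Returns integer labels 1..n_groups.
    """
    values = values.sort_index()
    if strata is None:
        strata = pd.Series("all", index=values.index)
    else:
        strata = strata.reindex(values.index)
    labels = pd.Series(0, index=values.index, dtype=int)
    for _, idx in strata.groupby(strata).groups.items():
        sub = values.loc[idx]
        n = len(sub)
        if n < n_groups:
            raise DegenerateDataError(
                f"stratum with {n} participants cannot be split into "
                f"{n_groups} groups"
            )
        order = np.argsort(sub.to_numpy(), kind="stable")
        base, extra = divmod(n, n_groups)
        sizes = [base + (1 if g < extra else 0) for g in range(n_groups)]
        group_of_rank = np.repeat(np.arange(1, n_groups + 1), sizes)
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        labels.loc[sub.index] = group_of_rank[ranks]
    return labels


def evaluate_rule(profile: NutrientProfile, rule: ReferenceRule) -> bool:
    """Does the profile satisfy one recommendation?

    Boundary semantics: intake ranges are inclusive; E% ceilings are
    strict (adherence = strictly below the threshold); absolute floors
    are strict (strictly above); AR/LI/RI comparisons are inclusive,
    with an optional per-rule ``direction`` override for references that
    act as ceilings (sodium).
    """
    value = profile.value_for(rule.nutrient, rule.kind in EPCT_KINDS)
    if rule.kind is RuleKind.range_epct:
        return rule.low <= value <= rule.high
    if rule.kind is RuleKind.upper_epct:
        return value < rule.high
    if rule.kind is RuleKind.lower_threshold:
        return value > rule.low
    # ar / li / ri
    if rule.direction == "le":
        return value <= rule.low
    return value >= rule.low


def applicable_rules(
    rules: Sequence[ReferenceRule], sex: Sex, age: float
) -> list[ReferenceRule]:
    """Sex/age dispatch: exactly one rule per (nutrient, kind) family.

    Raises :class:`RuleTableError` when dispatch yields zero rules (an
    age gap in the table) or several (overlapping intervals) for a
    family that exists in the table.
    """
    by_family: dict[tuple[str, RuleKind], list[ReferenceRule]] = {}
    for rule in rules:
        by_family.setdefault((rule.nutrient, rule.kind), []).append(rule)
    out = []
    for (nutrient, kind), members in by_family.items():
        hits = [r for r in members if r.applies_to(sex, age)]
        if len(hits) != 1:
            raise RuleTableError(
                f"{len(hits)} applicable rules for nutrient '{nutrient}' "
                f"({kind.value}) at sex={sex.value}, age={age}"
            )
        out.append(hits[0])
    return sorted(out, key=lambda r: r.rule_id)


def adherence_vector(
    profile: NutrientProfile,
    rules: Sequence[ReferenceRule],
    sex: Sex,
    age: float,
) -> AdherenceVector:
    """Evaluate every applicable recommendation for one participant."""
    per_rule = {
        rule.rule_id: evaluate_rule(profile, rule)
        for rule in applicable_rules(rules, sex, age)
    }
    return AdherenceVector(
        participant_id=profile.participant_id,
        per_rule=per_rule,
        total=sum(per_rule.values()),
    )


def cohort_adherence(
    profiles: Mapping[str, NutrientProfile],
    participants: Mapping[str, Participant],
    rules: Sequence[ReferenceRule],
) -> dict[str, AdherenceVector]:
    return {
        pid: adherence_vector(
            profiles[pid], rules, participants[pid].sex, participants[pid].age
        )
        for pid in sorted(profiles)
    }


def adherence_threshold_table(
    vectors: Mapping[str, AdherenceVector],
    thresholds: Sequence[int],
    groups: pd.DataFrame,
) -> pd.DataFrame:
    """Proportion fulfilling at least ``t`` recommendations per group.

    ``groups`` is indexed by participant id with columns ``sex`` and
    ``quartile``.  Within a group the proportions are non-increasing in
    the threshold.
    """
    totals = pd.Series({pid: v.total for pid, v in vectors.items()})
    rows = []
    for (sex, quartile), idx in groups.groupby(["sex", "quartile"]).groups.items():
        sub = totals.reindex(idx).dropna()
        if sub.empty:
            raise EmptyRecordError(f"empty group sex={sex}, quartile={quartile}")
        for t in thresholds:
            rows.append(
                {
                    "sex": sex,
                    "quartile": quartile,
                    "threshold": t,
                    "proportion": float((sub >= t).mean()),
                    "n": len(sub),
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["sex", "quartile", "threshold"], ignore_index=True
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise DegenerateDataError("Kruskal-Wallis needs >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def chi_square(table: np.ndarray | Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square test of independence on a contingency table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateDataError("contingency table has a zero marginal")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupTables:
    """The three group-comparison outputs.

    ``nutrient_summary``: per sex x quartile x variable — n, median,
    25th/75th percentile, plus the Kruskal-Wallis p across quartiles.
    ``adherence``: per sex x quartile x rule — adherence proportion plus
    the chi-square p across quartiles.
    ``thresholds``: proportions fulfilling at least t recommendations.
    """

    nutrient_summary: pd.DataFrame
    adherence: pd.DataFrame
    thresholds: pd.DataFrame


def summarize_groups(
    variables: pd.DataFrame,
    groups: pd.DataFrame,
    vectors: Mapping[str, AdherenceVector],
    thresholds: Sequence[int] = (20, 21, 22, 23, 24, 25, 26, 27),
) -> GroupTables:
    """Build the group-comparison tables.

    ``variables`` is a numeric frame indexed by participant id (one
    column per variable to summarize); ``groups`` is indexed by
    participant id with columns ``sex`` and ``quartile``.
    """
    common = variables.index.intersection(groups.index)
    if common.empty:
        raise EmptyRecordError("no participants shared by variables and groups")
    variables = variables.loc[common]
    groups = groups.loc[common]

    summary_rows = []
    for sex, sex_idx in groups.groupby("sex").groups.items():
        sub_groups = groups.loc[sex_idx]
        sub_vars = variables.loc[sex_idx]
        quartiles = sorted(sub_groups["quartile"].unique())
        for col in variables.columns:
            by_q = [
                sub_vars.loc[sub_groups["quartile"] == q, col].to_numpy()
                for q in quartiles
            ]
            _, kw_p = kruskal_wallis(by_q)
            for q, vals in zip(quartiles, by_q):
                q25, med, q75 = np.percentile(vals, [25, 50, 75])
                summary_rows.append(
                    {
                        "sex": sex,
                        "quartile": q,
                        "variable": col,
                        "n": len(vals),
                        "median": med,
                        "q25": q25,
                        "q75": q75,
                        "kruskal_p": kw_p,
                    }
                )

    adherence_rows = []
    rule_ids = sorted({rid for v in vectors.values() for rid in v.per_rule})
    flags = pd.DataFrame.from_dict(
        {pid: v.per_rule for pid, v in vectors.items()}, orient="index"
    ).reindex(common)
    for sex, sex_idx in groups.groupby("sex").groups.items():
        sub_groups = groups.loc[sex_idx]
        quartiles = sorted(sub_groups["quartile"].unique())
        for rid in rule_ids:
            col = flags.loc[sex_idx, rid].dropna().astype(bool)
            counts = []
            props = {}
            for q in quartiles:
                members = (
                    col.reindex(sub_groups.index[sub_groups["quartile"] == q])
                    .dropna()
                    .astype(bool)
                )
                counts.append(
                    [int(members.sum()), int((~members).sum())]
                )
                props[q] = float(members.mean()) if len(members) else np.nan
            table = np.asarray(counts).T
            try:
                _, chi_p = chi_square(table)
            except DegenerateDataError:
                chi_p = np.nan  # everyone (or no one) adheres in all groups
            for q in quartiles:
                adherence_rows.append(
                    {
                        "sex": sex,
                        "quartile": q,
                        "rule_id": rid,
                        "proportion": props[q],
                        "chi2_p": chi_p,
                    }
                )

    return GroupTables(
        nutrient_summary=pd.DataFrame(summary_rows),
        adherence=pd.DataFrame(adherence_rows),
        thresholds=adherence_threshold_table(vectors, thresholds, groups),
    )


def plot_adherence(
    adherence: pd.DataFrame, sex: str, path: str, rules: Iterable[str] | None = None
):
    """Stacked adhering/not-adhering bars by quartile (one panel per rule)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = adherence[adherence["sex"] == sex]
    if rules is not None:
        sub = sub[sub["rule_id"].isin(set(rules))]
    rule_ids = sorted(sub["rule_id"].unique())
    ncols = 5
    nrows = int(np.ceil(len(rule_ids) / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3 * ncols, 2.2 * nrows), squeeze=False
    )
    for ax in axes.flat[len(rule_ids):]:
        ax.set_visible(False)
    for ax, rid in zip(axes.flat, rule_ids):
        r = sub[sub["rule_id"] == rid].sort_values("quartile")
        ax.bar(r["quartile"], r["proportion"], color="#2c7fb8", label="adhering")
        ax.bar(
            r["quartile"],
            1 - r["proportion"],
            bottom=r["proportion"],
            color="#d9d9d9",
            label="not adhering",
        )
        ax.set_title(rid, fontsize=8)
        ax.set_ylim(0, 1)
        ax.set_xticks(r["quartile"])
    fig.suptitle(f"Adherence by emission quartile ({sex})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
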