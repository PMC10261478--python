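"""Residual adjustment, quartering, rule scoring and group tests."""

import numpy as np
import pandas as pd
import pytest

from dietghge.errors import (
    DegenerateDataError,
    MissingNutrientError,
    RuleTableError,
)
from dietghge.exposure_stats import (
    adherence_threshold_table,
    adherence_vector,
    applicable_rules,
    assign_quartiles,
    chi_square,
    energy_adjust,
    evaluate_rule,
    kruskal_wallis,
    summarize_groups,
)
from dietghge.knowledge_base import ReferenceRule, RuleKind, Sex
from dietghge.nutrient_engine import NutrientProfile
from oracles import brute_chi2, brute_kruskal_h, brute_median_iqr, brute_quartiles


def _profile(pid="P", intake=None, epct=None, added_epct=0.0):
    return NutrientProfile(
        participant_id=pid,
        intake=intake or {},
        energy_kj=9000.0,
        energy_excl_alcohol_kj=9000.0,
        epct=epct or {},
        added_sugar_g=0.0,
        added_sugar_epct=added_epct,
    )


def _rule(rule_id, nutrient, kind, low=None, high=None, sex="both",
          age_min=18, age_max=80, direction=None):
    return ReferenceRule(
        rule_id=rule_id, nutrient=nutrient, kind=kind, sex=sex,
        age_min=age_min, age_max=age_max, low=low, high=high,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# residual-method energy adjustment


def test_hand_ols_example_reproduces_exactly():
    adjusted = energy_adjust([2.0, 3.0, 5.0], [8.0, 10.0, 12.0])
    assert adjusted == pytest.approx([3.5, 3.0, 3.5], abs=1e-12)


def test_exactly_linear_exposure_collapses_to_the_fitted_mean():
    energy = np.array([7.0, 9.0, 10.0, 14.0])
    ghge = 1.0 + 0.5 * energy
    adjusted = energy_adjust(ghge, energy)
    assert np.allclose(adjusted, 1.0 + 0.5 * energy.mean(), atol=1e-12)


def test_uncorrelated_exposure_is_left_unchanged():
    energy = np.array([8.0, 10.0, 12.0])
    ghge = np.array([3.0, 5.0, 3.0])  # symmetric: slope is exactly 0
    assert np.allclose(energy_adjust(ghge, energy), ghge, atol=1e-12)


def test_adjustment_contract_on_random_fixtures():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = rng.integers(5, 200)
        energy = rng.lognormal(9.2, 0.25, n)
        ghge = 0.3 + 4e-4 * energy + rng.normal(0, 0.8, n)
        adjusted = energy_adjust(ghge, energy)
        assert abs(np.corrcoef(adjusted, energy)[0, 1]) < 1e-8
        assert adjusted.mean() == pytest.approx(ghge.mean(), rel=1e-9)


def test_constant_energy_is_a_degenerate_design():
    with pytest.raises(DegenerateDataError):
        energy_adjust([1.0, 2.0, 3.0], [9.0, 9.0, 9.0])


# ---------------------------------------------------------------------------
# quartile assignment


def test_eight_distinct_values_split_into_pairs():
    values = pd.Series([5.0, 1, 7, 3, 8, 2, 6, 4],
                       index=[f"P{i}" for i in range(8)])
    labels = assign_quartiles(values)
    expected = brute_quartiles(values.to_dict(), dict.fromkeys(values.index, "a"))
    assert labels.to_dict() == expected
    assert sorted(labels.value_counts()) == [2, 2, 2, 2]


def test_nine_values_use_the_documented_remainder_rule():
    values = pd.Series(np.arange(9.0), index=[f"P{i}" for i in range(9)])
    sizes = assign_quartiles(values).value_counts().sort_index()
    assert list(sizes) == [3, 2, 2, 2]


def test_all_equal_values_split_by_stable_id_order():
    values = pd.Series(1.0, index=[f"P{i}" for i in range(10)])
    labels = assign_quartiles(values)
    assert labels["P0"] == 1 and labels["P9"] == 4
    assert labels.value_counts().max() - labels.value_counts().min() <= 1


def test_quartiles_match_brute_force_oracle_with_strata():
    rng = np.random.default_rng(5)
    for trial in range(10):
        n = int(rng.integers(8, 200))
        ids = [f"P{i:03d}" for i in range(n)]
        values = pd.Series(rng.normal(size=n).round(1), index=ids)  # ties likely
        strata = pd.Series(rng.choice(["F", "M"], n), index=ids)
        if strata.value_counts().min() < 4:
            continue
        labels = assign_quartiles(values, strata)
        oracle = brute_quartiles(values.to_dict(), strata.to_dict())
        assert labels.to_dict() == oracle


def test_stratum_smaller_than_four_is_an_error():
    values = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
    with pytest.raises(DegenerateDataError):
        assign_quartiles(values)


# ---------------------------------------------------------------------------
# rule evaluation and adherence


def test_range_rule_is_inclusive():
    rule = _rule("r", "protein", RuleKind.range_epct, low=10, high=20)
    assert evaluate_rule(_profile(epct={"protein": 15.0}), rule)
    assert evaluate_rule(_profile(epct={"protein": 10.0}), rule)
    assert evaluate_rule(_profile(epct={"protein": 20.0}), rule)
    assert not evaluate_rule(_profile(epct={"protein": 20.1}), rule)


def test_added_sugar_ceiling_is_strict():
    rule = _rule("r", "added_sugar", RuleKind.upper_epct, high=10)
    assert not evaluate_rule(_profile(added_epct=12.0), rule)
    assert not evaluate_rule(_profile(added_epct=10.0), rule)
    assert evaluate_rule(_profile(added_epct=9.9), rule)


def test_lower_threshold_is_strict_and_ar_is_inclusive():
    fibre = _rule("r", "fibre_g", RuleKind.lower_threshold, low=25)
    assert not evaluate_rule(_profile(intake={"fibre_g": 25.0}), fibre)
    assert evaluate_rule(_profile(intake={"fibre_g": 25.1}), fibre)
    ar = _rule("r", "iron_mg", RuleKind.ar, low=10)
    assert evaluate_rule(_profile(intake={"iron_mg": 10.0}), ar)
    assert not evaluate_rule(_profile(intake={"iron_mg": 9.99}), ar)


def test_direction_override_turns_ri_into_a_ceiling():
    rule = _rule("r", "sodium_mg", RuleKind.ri, low=2400, direction="le")
    assert evaluate_rule(_profile(intake={"sodium_mg": 2400.0}), rule)
    assert not evaluate_rule(_profile(intake={"sodium_mg": 2401.0}), rule)


def test_missing_nutrient_names_the_nutrient():
    rule = _rule("r", "selenium_ug", RuleKind.ar, low=30)
    with pytest.raises(MissingNutrientError, match="selenium_ug"):
        evaluate_rule(_profile(), rule)


def _fe_rules():
    return [
        _rule("fe_young", "iron_mg", RuleKind.ar, low=10, sex="F",
              age_min=18, age_max=50),
        _rule("fe_older", "iron_mg", RuleKind.ar, low=6, sex="F",
              age_min=51, age_max=80),
        _rule("fibre", "fibre_g", RuleKind.lower_threshold, low=25),
    ]


def test_iron_age_split_changes_exactly_the_iron_rule():
    profile = _profile(intake={"iron_mg": 8.0, "fibre_g": 30.0})
    young = adherence_vector(profile, _fe_rules(), Sex.F, 45)
    older = adherence_vector(profile, _fe_rules(), Sex.F, 55)
    assert young.total == 1 and older.total == 2
    assert not young.per_rule["fe_young"]
    assert older.per_rule["fe_older"]
    assert young.per_rule["fibre"] == older.per_rule["fibre"]


def test_age_gap_in_the_rule_table_is_detected():
    with pytest.raises(RuleTableError, match="iron_mg"):
        applicable_rules(_fe_rules(), Sex.F, 50.5)


def test_overlapping_rules_are_detected():
    rules = _fe_rules() + [
        _rule("fe_dup", "iron_mg", RuleKind.ar, low=9, sex="F",
              age_min=40, age_max=60)
    ]
    with pytest.raises(RuleTableError):
        applicable_rules(rules, Sex.F, 45)


def test_adherence_total_matches_rule_by_rule_reevaluation_and_order():
    rng = np.random.default_rng(3)
    rules = [
        _rule(f"r{i}", f"nut{i}", RuleKind.ar, low=float(rng.uniform(1, 9)))
        for i in range(12)
    ]
    profile = _profile(
        intake={f"nut{i}": float(rng.uniform(0, 10)) for i in range(12)}
    )
    vec = adherence_vector(profile, rules, Sex.M, 40)
    manual = sum(evaluate_rule(profile, r) for r in rules)
    assert vec.total == manual
    shuffled = list(rules)
    rng.shuffle(shuffled)
    assert adherence_vector(profile, shuffled, Sex.M, 40).per_rule == vec.per_rule


# ---------------------------------------------------------------------------
# threshold table


def test_threshold_proportions_by_hand():
    from dietghge.exposure_stats import AdherenceVector

    totals = (20, 22, 23, 25)
    vectors = {
        f"P{i}": AdherenceVector(
            participant_id=f"P{i}",
            per_rule={f"r{j}": j < t for j in range(27)},
            total=t,
        )
        for i, t in enumerate(totals)
    }
    groups = pd.DataFrame(
        {"sex": "F", "quartile": 1}, index=[f"P{i}" for i in range(4)]
    )
    table = adherence_threshold_table(vectors, [23, 25, 27], groups)
    by_t = table.set_index("threshold")["proportion"]
    assert by_t[23] == pytest.approx(0.5)
    assert by_t[25] == pytest.approx(0.25)
    assert by_t[27] == 0.0
    # monotone non-increasing in the threshold by set inclusion
    assert (by_t.sort_index().diff().dropna() <= 0).all()


# ---------------------------------------------------------------------------
# group tests


def test_kruskal_identical_groups_and_shift_invariance():
    assert kruskal_wallis([[1.0, 1.0], [1.0, 1.0, 1.0]]) == (0.0, 1.0)
    rng = np.random.default_rng(0)
    groups = [rng.normal(size=12), rng.normal(size=15), rng.normal(size=9)]
    h1, _ = kruskal_wallis(groups)
    h2, _ = kruskal_wallis([g + 100.0 for g in groups])
    assert h1 == pytest.approx(h2, rel=1e-12)


def test_kruskal_matches_brute_force_ranks():
    rng = np.random.default_rng(1)
    for _ in range(10):
        groups = [
            list(rng.integers(0, 12, rng.integers(5, 30)).astype(float))
            for _ in range(4)
        ]
        h, p = kruskal_wallis(groups)
        assert h == pytest.approx(brute_kruskal_h(groups), rel=1e-9)
        assert 0.0 <= p <= 1.0


def test_chi_square_examples_and_scaling():
    x2, p = chi_square([[10, 20], [20, 10]])
    assert x2 == pytest.approx(20.0 / 3.0, rel=1e-12)
    # table proportional to the outer product of its margins
    x2_indep, p_indep = chi_square(np.outer([1, 2], [3, 4]) * 5)
    assert x2_indep == pytest.approx(0.0, abs=1e-12)
    assert p_indep == pytest.approx(1.0)
    # doubling all counts doubles the statistic
    x2_twice, _ = chi_square([[20, 40], [40, 20]])
    assert x2_twice == pytest.approx(2 * x2, rel=1e-12)


def test_chi_square_matches_brute_force_expected_counts():
    rng = np.random.default_rng(2)
    for _ in range(10):
        table = rng.integers(1, 40, size=(2, 4))
        x2, _ = chi_square(table)
        assert x2 == pytest.approx(brute_chi2(table.tolist()), rel=1e-9)


def test_chi_square_zero_marginal_is_an_error():
    with pytest.raises(DegenerateDataError):
        chi_square([[0, 0], [5, 3]])


# ---------------------------------------------------------------------------
# group summary tables


def _toy_groups(n=40, seed=9):
    rng = np.random.default_rng(seed)
    ids = [f"P{i:02d}" for i in range(n)]
    variables = pd.DataFrame(
        {"x": rng.normal(size=n), "y": rng.lognormal(size=n)}, index=ids
    )
    sex = pd.Series(["F" if i % 2 else "M" for i in range(n)], index=ids)
    quartile = pd.Series((np.arange(n) // 2 % 4) + 1, index=ids)
    groups = pd.DataFrame({"sex": sex, "quartile": quartile})
    from dietghge.exposure_stats import AdherenceVector

    vectors = {}
    for pid in ids:
        per_rule = {"r1": bool(rng.random() < 0.6), "r2": True}
        vectors[pid] = AdherenceVector(
            participant_id=pid, per_rule=per_rule,
            total=sum(per_rule.values()),
        )
    return variables, groups, vectors


def test_summary_medians_match_sort_based_oracle():
    variables, groups, vectors = _toy_groups()
    tables = summarize_groups(variables, groups, vectors, thresholds=[1, 2])
    for row in tables.nutrient_summary.itertuples():
        members = groups[
            (groups["sex"] == row.sex) & (groups["quartile"] == row.quartile)
        ].index
        q25, med, q75 = brute_median_iqr(variables.loc[members, row.variable])
        assert row.median == pytest.approx(med, rel=1e-9)
        assert row.q25 == pytest.approx(q25, rel=1e-9)
        assert row.q75 == pytest.approx(q75, rel=1e-9)
        assert row.q25 <= row.median <= row.q75


def test_summary_has_one_row_per_stratum_quartile_variable():
    variables, groups, vectors = _toy_groups()
    tables = summarize_groups(variables, groups, vectors, thresholds=[1])
    assert len(tables.nutrient_summary) == 2 * 4 * 2
    assert len(tables.adherence) == 2 * 4 * 2  # two rules


def test_identical_group_gives_zero_width_iqr():
    ids = [f"P{i}" for i in range(8)]
    variables = pd.DataFrame({"x": 3.14}, index=ids)
    groups = pd.DataFrame(
        {"sex": "F", "quartile": [1, 1, 2, 2, 3, 3, 4, 4]}, index=ids
    )
    from dietghge.exposure_stats import AdherenceVector

    vectors = {
        pid: AdherenceVector(participant_id=pid, per_rule={"r": True}, total=1)
        for pid in ids
    }
    tables = summarize_groups(variables, groups, vectors, thresholds=[1])
    assert (tables.nutrient_summary["median"] == 3.14).all()
    assert (tables.nutrient_summary["q75"] - tables.nutrient_summary["q25"] == 0).all()
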