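"""Independent brute-force reference implementations used only by tests.

Everything here is written from first principles (pure Python loops,
explicit formulas) so that it shares no code path with the package.
"""

import math


def brute_effective_factor(factor, cfg):
    """Fully expanded kg CO2e per consumed kg for one emission factor."""
    if factor.co2e_per_kg is not None:
        base = factor.co2e_per_kg
    else:
        base = (
            cfg.gwp.ch4 * factor.ch4_kg
            + cfg.gwp.n2o * factor.n2o_kg
            + cfg.gwp.co2 * factor.co2_kg
        )
    if factor.boundary.value == "farm_gate":
        base = base + cfg.postfarm_addendum
    base = base / factor.yield_factor
    return base / (
        factor.edible_fraction
        * (1.0 - factor.waste_before)
        * (1.0 - factor.waste_after)
    )


def brute_food_factor(food_id, kb, cfg):
    """Per-kg factor of a component or (recursively) a dish."""
    if food_id in kb.recipes:
        return sum(
            share * brute_food_factor(ing, kb, cfg)
            for ing, share in kb.recipes[food_id].ingredients
        )
    return brute_effective_factor(kb.factors[food_id], cfg)


def brute_participant_ghge(kb, cfg):
    """dict participant_id -> mean daily kg CO2e, by direct summation."""
    totals = {}
    for entry in kb.records:
        f = brute_food_factor(entry.food_id, kb, cfg)
        totals[entry.participant_id] = (
            totals.get(entry.participant_id, 0.0)
            + entry.portion_g / 1000.0 * f
        )
    return {pid: t / cfg.n_days for pid, t in totals.items()}


def brute_quartiles(values, strata, n_groups=4):
    """dict id -> group label, by explicit sort-and-slice per stratum.

    ``values`` and ``strata`` are dicts keyed by participant id; ties are
    broken by id order.
    """
    labels = {}
    for stratum in sorted(set(strata.values())):
        ids = sorted(
            [i for i in values if strata[i] == stratum],
            key=lambda i: (values[i], i),
        )
        n = len(ids)
        base, extra = divmod(n, n_groups)
        pos = 0
        for g in range(1, n_groups + 1):
            size = base + (1 if g <= extra else 0)
            for i in ids[pos:pos + size]:
                labels[i] = g
            pos += size
    return labels


def brute_percentile(sorted_values, q):
    """Linear interpolation between closest ranks (q in [0, 1])."""
    n = len(sorted_values)
    if n == 1:
        return sorted_values[0]
    pos = q * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_values[lo] + (sorted_values[hi] - sorted_values[lo]) * frac


def brute_median_iqr(values):
    s = sorted(values)
    return (
        brute_percentile(s, 0.25),
        brute_percentile(s, 0.50),
        brute_percentile(s, 0.75),
    )


def _midranks(pooled):
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_kruskal_h(groups):
    """Tie-corrected Kruskal-Wallis H from explicit midranks."""
    pooled = [v for g in groups for v in g]
    n_total = len(pooled)
    ranks = _midranks(pooled)
    h = 0.0
    pos = 0
    for g in groups:
        r_sum = sum(ranks[pos:pos + len(g)])
        h += r_sum**2 / len(g)
        pos += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie_sum = sum(t**3 - t for t in counts.values())
    correction = 1.0 - tie_sum / (n_total**3 - n_total)
    return h / correction


def brute_chi2(table):
    """Pearson X^2 from explicit expected counts."""
    n_rows = len(table)
    n_cols = len(table[0])
    row_sums = [sum(table[r]) for r in range(n_rows)]
    col_sums = [sum(table[r][c] for r in range(n_rows)) for c in range(n_cols)]
    total = sum(row_sums)
    x2 = 0.0
    for r in range(n_rows):
        for c in range(n_cols):
            expected = row_sums[r] * col_sums[c] / total
            x2 += (table[r][c] - expected) ** 2 / expected
    return x2
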