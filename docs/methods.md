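# Methods

This note documents the models, conventions and design choices behind
`dietghge`, in the order the pipeline applies them.

## Emission model

Each food product carries an LCA emission factor per kg, quoted either
directly as kg CO2e or as per-gas masses of CH4, N2O and fossil CO2.
Per-gas factors are aggregated with 100-year global warming potentials
(defaults 34, 296 and 1; configurable in `AnalysisConfig.gwp`). The
correction chain is applied in a fixed order:

1. **GWP aggregation** (per-gas factors only).
2. **Boundary harmonization.** Factors quoted at the farm gate gain a
   flat post-farm addendum (kg CO2e/kg) covering processing, packaging,
   distribution and retail; factors already at retail pass through. No
   authoritative addendum is bundled — it is a config value the user must
   source for their setting (the synthetic fixture uses 0.4). Emissions
   after retail (household transport, cooking, waste management) and from
   land-use change are out of scope.
3. **Raw → prepared conversion.** Portions in food records are prepared,
   as-consumed grams, so a factor per raw kg is divided by the cooking
   yield (hydration > 1, e.g. rice; dehydration < 1, e.g. meat). The
   yield applies to the factor, never to the portion.
4. **Loss and waste correction.** Division by
   `edible · (1 − waste_before) · (1 − waste_after)` charges the
   emissions of inedible parts (shell, bone) and avoidable waste before
   and after preparation to the mass actually eaten. The order of steps
   matters only for presentation — all corrections are multiplicative
   except the boundary addendum, which must precede the yield division
   because the addendum is quoted per raw product kg.

Dishes are flattened to leaf components by recursive descent through the
recipe graph. Recipe shares operate on prepared mass, so cooking yields
are embedded in each leaf's factor and are not double-counted.
Approximate recipes (own estimations for dishes without a database
recipe) are validated to at most three ingredients; calculated dishes
are uncapped. Cycles are detected and reported with the dish chain.

Daily emissions divide the record total by the *nominal* record length
(default 4 days): a day with no entries is a zero-intake day, not a
shorter record. Annualization uses 365 days/year (not 365.25) —
configurable, and documented here because survey reports rarely state
the convention.

## Nutrient model

Intakes are `portion/100 ×` per-100 g composition, dishes resolved as
above, summed and divided by the nominal record length. Energy
percentages use metabolizable-energy factors (protein 17, fat 37,
carbohydrate 17, alcohol 29 kJ/g) over **non-alcohol** energy; the
composition table's own energy fields are preferred over recomputation
from macros. Added sugar is
`(sucrose_total + monosaccharide_total) − (sucrose_natural +
monosaccharide_natural)`, floored at zero (flooring is logged; at the
component level natural ≤ total is a hard invariant, so only aggregation
rounding can trip it). Long-chain n-3 intake is the sum of α-linolenic
acid, EPA and DHA. Iron bioavailability and dietary supplements are out
of scope.

## Misreporter exclusion

The Goldberg cut-off compares mean daily energy intake (alcohol
included) with an estimated BMR. BMR comes from a configurable
(sex, age-band) linear table in MJ/day; the default is the
Schofield-type weight equation set. The plausibility band is
`PAL · exp(±z·S/100)`, `S = sqrt(CV²_wEI/d + CV²_wB + CV²_tP)`, with the
individual questionnaire PAL (not a population value) and default CVs
23 % (within-person energy intake), 8.5 % (BMR estimation), 15 % (PAL),
z = 1.96, d = 4 days. These constants follow Black's standard
parameterization and are all configurable; different surveys use
different values, so exclusion counts are not comparable across
parameterizations. Participants below the band are under-reporters,
above it over-reporters; the analysis set keeps the plausible.

## Exposure statistics

**Energy adjustment.** Emissions are regressed on total energy intake by
ordinary least squares; the adjusted exposure is the residual plus the
fitted value at the cohort mean energy, which leaves it uncorrelated
with energy while preserving the crude mean and scale. Adjustment runs
once on the pooled analysis set; a constant-energy design raises an
error directing the caller to skip adjustment.

**Quartiles** are formed within sex strata (sex-specific quartile
medians are otherwise inconsistent with pooled quartering). Within a
stratum, participants are ordered by adjusted exposure with ties broken
by participant-id order, and cut into four consecutive blocks whose
sizes differ by at most one, earlier blocks taking the remainder. This
is deterministic and matches a sort-and-slice oracle exactly.

**Rule scoring.** The rule table holds one row per (nutrient, rule kind,
sex, age band). Kinds: E% ranges (inclusive), E% ceilings (strict <),
absolute floors (strict >), and AR/LI/RI comparisons (inclusive ≥, with
a per-rule `direction` override for references that act as ceilings —
the bundled sodium rule uses ≤, since exceeding the sodium reference is
the failure mode). Sex/age dispatch must yield exactly one rule per
(nutrient, kind) family; gaps and overlaps are errors. The bundled
default table scores **27 recommendations**: 10 macronutrient rules
(ranges for protein, fat, MUFA, PUFA, carbohydrate; ceilings for SFA and
added sugar; floors for linoleic acid, α-linolenic acid and fibre) and
17 micronutrient rules (AR for 14 nutrients — vitamin A, D, E, thiamin,
riboflavin, niacin, B6, folate, B12, C, calcium, iron, zinc, selenium —
plus LI for potassium and RI for magnesium and sodium). Iron has
separate female AR bands for ages 18–50 and 51–80. An iodine AR rule is
deliberately not scored: iodine intake is dominated by salt fortification
that composition tables estimate poorly. The numeric values are an
editable user transcription of the Nordic Nutrition Recommendations
2012; no analysis logic depends on them.

**Group comparisons.** Medians and IQRs use linear interpolation between
closest ranks (configurable convention; stated because it affects small
groups). Continuous variables are compared across quartiles with the
tie-corrected Kruskal–Wallis test (scipy), adherence proportions with
Pearson's chi-square without continuity correction, at α = 0.05 per
variable. No multiple-testing correction is applied — the tables report
per-variable p-values as-is, and readers should treat marginal p-values
across dozens of variables accordingly.

## Synthetic survey generator

The generator emulates a national-survey structure: ~50 food components
in classes spanning ruminant meat and cheese (high emission), pork,
poultry, fish (mid), and grains, vegetables, fruit, legumes, nuts (low),
plus four dishes including a nested three-ingredient approximate recipe.
Component nutrient densities are jittered around food-table-like values;
emission factors are loosely calibrated so the default cohort's median
annual footprint lands in the 1–3 t CO2e range typical of affluent-diet
surveys — a sanity band, never an equality assertion.

Each participant draws a latent diet style `t ∈ [0, 1]` (Beta(2,2));
food-class draw weights are tilted by `exp(effect · tilt · (t − ½))`
where `tilt` is +1 for animal-based and −1 for plant-based classes, so
expected per-kg emissions rise and fibre density falls with `t`. Daily
energy targets follow the participant's PAL × BMR with lognormal
between-person (σ = 0.10) and day-to-day (σ = 0.23, matching the
Goldberg within-person CV) noise; portions are scaled so each day's menu
meets its target. A configurable fraction (default 18 %) of participants
scale all reported portions by ~0.45–0.62 (under-reporters) or ~1.6–2.0
(over-reporters); ground truth records diet style, true energy intake
and misreporting status. Defaults: 1797 participants, 56 % women, ages
18–80, 4-day records, diet-style effect 2.0. Start weekdays are drawn
uniformly and stored in ground truth only.

What the generator does **not** emulate: real consumption shares or food
lists, correlated day-to-day menus (weekday/weekend structure),
intra-household correlation, seasonal foods, or selective (food-specific)
misreporting. Passing tests therefore demonstrate the pipeline's
correctness and directional behaviour, not quantitative agreement with
any real population.

## Numerical conventions and degenerate inputs

Quartering requires ≥ 4 participants per stratum; adjustment ≥ 3
participants and non-constant energy; the Kruskal–Wallis wrapper returns
(H = 0, p = 1) when all pooled values are identical; the chi-square
wrapper rejects tables with a zero marginal. Recipe shares must sum to 1
within 1e-9. Table round-trips are exact: files are read with
round-trip float parsing, and a zero nutrient entry is canonically
equivalent to an absent one. All randomness flows through
`numpy.random.default_rng` seeded from the generator config, so emitted
tables are byte-identical across runs and platforms for a fixed seed.

## Known limitations

- The post-farm boundary addendum is a single flat value; real post-farm
  emissions differ by product group.
- The food-item → LCA-group mapping is the user's responsibility; the
  package only validates that every consumed item resolves.
- Goldberg screening with individual PAL inherits the questionnaire's
  PAL error; the CV constants only approximate it.
- Whole-grain intake is treated as an ordinary composition column if
  supplied; no derivation from ingredient flours is attempted.
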