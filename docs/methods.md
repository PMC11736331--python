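# Methods

## Scope and data model

`vetamc` implements national antimicrobial-consumption (AMC) surveillance
for food animals from point-of-entry import records — a "tier 1"
distribution system, where every veterinary antimicrobial enters the country
as a registered finished product.  One `ImportRecord` is one shipment line:
the declared chemical compound, a formulation (liquid container, tablet
blister, or IU-potency-labelled liquid), its strength and geometry, the
number of packs, the calendar year, and whether the product is indicated for
food animals.  Records without a food-animal indication are excluded before
any totals are formed.

The pipeline assumes no unrecorded (illegal) imports and treats imports as a
proxy for consumption: it measures what entered the country, not what was
administered, and carries no stock/expiry adjustment.

## Quantification

For each record the mass of active ingredient is a deterministic function of
the declared geometry:

* liquid: `g = strength(mg/ml) × volume(ml) / 1000 × packs`
* blister: `g = strength(mg/tablet) × blisters/pack × tablets/blister / 1000 × packs`
* IU liquid: the potency label is converted to a mass concentration first,
  `mg/ml = IU/ml × f`, with `f` the registry's compound-specific factor
  (default for benzylpenicillin/penicillin G procaine: 0.0006 mg/IU, the
  1 mg ≈ 1667 IU standard).  Factors are registry data, not code, and can be
  overridden per ingredient.

Conventions: salt and hydrate mass is not corrected for — the declared
strength is taken at face value, as surveillance reports based on declared
product strengths do.  Combination products are entered as one record per
active ingredient (sharing a record-id prefix), keeping each conversion
unary.  All internal arithmetic is in unrounded double-precision grams
(group sums via `math.fsum`, which makes aggregation exactly independent of
record order); kilograms, percentages, and the half-up 2-decimal rounding
appear only in report output.  An unknown formulation value is a hard
error, never a guessed default.

The ingredient registry resolves declared names case-insensitively through
an explicit synonym table ("tetracycline hydrochloride" → tetracycline),
and maps each ingredient to class, subclass (cephalosporin generations,
fluoroquinolones), WOAH category (VCIA/VHIA/VIA) and WHO category
(critically-important highest/high priority, highly important, important).
The bundled default covers the 13 ingredients in the Fiji 2017–2021 import
profile; the WOAH/WHO assignments are stamped with a list-edition field
rather than tracking live list revisions.

## Biomass denominator

The standardisation denominator is the national live weight of the five
major food-animal species (cattle, sheep, goats, pigs, chicken) in kg.

* Populations: censuses give two anchor points per species; annual
  populations are interpolated geometrically, `P(t) = P₂(1+r)^(t−y₂)` with
  `r = (P₂/P₁)^(1/y) − 1`, anchored at the later census and projected
  backwards/forwards.  Interpolated populations are kept fractional —
  biomass is a continuous denominator.
* Weights: carcass weight = annual slaughter weight ÷ head slaughtered;
  live weight = carcass weight ÷ conversion coefficient (cattle 0.7,
  sheep 0.47, goat 0.47, pig 0.78, chicken 0.7).
* Species conventions: cattle biomass = interpolated population × live
  weight (the census-based exception used when slaughter proportions per
  age group are unknown); sheep and goats default to interpolated
  population × a 37.5 kg standard live weight, with a slaughter-based mode
  (`small_ruminant_mode="slaughter"`, number slaughtered × live weight)
  behind a switch because the slaughter-based convention is equally
  defensible for small ruminants; pigs and chicken use number
  slaughtered × live weight.  Chicken falls back to a configurable standard
  live weight (default 2.0 kg/bird — an assumption, not a statistic) when
  slaughter weight totals are missing.

The adjusted consumption rate is `mg/kg = annual kg × 10⁶ / national
biomass kg`, with mean and sample standard deviation across years.

## Importance classification

Class totals are partitioned into WOAH categories; every classified
kilogram lands in exactly one category, and classes outside the WOAH list
(nitroimidazoles) are reported separately and excluded from the classified
grand total.  Within-category percentages use the category total; the
headline VCIA share uses the classified total (VCIA+VHIA+VIA).  That
denominator choice reproduces the published headline (447.73/464.04 →
96.48 %); using the all-classes grand total would give 96.43 %.

## Trend test

The Mann–Kendall test is implemented from first principles:
`S = Σ_{i<j} sign(x_j − x_i)`; τ is the tie-corrected tau-b (the time axis
has no ties); `var(S) = [n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18`.  Two p-value
routes:

* **Exact enumeration** (default for tie-free series with n ≤ 10): under
  the null all n! orderings are equally likely and S is a linear function
  of the permutation's inversion count, so the null distribution is the
  Mahonian distribution, computed by the generating-function recurrence —
  no permutations are enumerated.  p = P(|S*| ≥ |S|).
* **Continuity-corrected normal** (`z = (S − sign S)/√var S`; a plain
  normal route is also exposed).  Exact enumeration is not defined under
  ties; a tied series falls back to the corrected normal route with a
  logged note, and a constant series returns τ = 0, p = 1 with a warning.

On the five annual totals both routes agree qualitatively: exact
p = 98/120 ≈ 0.817, continuity-corrected normal ≈ 0.806.  The reported
result always states which method produced it.  By default the trend is
tested on the raw annual kg series (which reproduces the published
τ = −0.20); the biomass-adjusted series can be tested the same way.

## Synthetic data generator

Because national import registries are not deposited, correctness is proven
on synthetic data with exact ground truth.  The generator emulates a tier-1
import dataset: per-shipment masses are log-normal (default median 800 g,
log-sd 1.4 — right-skewed, a few large shipments dominating, at a scale of
a few hundred kg over five years for the default 40 records/year); the
class mix is heavily skewed (defaults: penicillins 0.55, tetracyclines
0.18, sulfonamides 0.08, macrolides 0.05, lincosamides 0.05,
aminoglycosides 0.04, cephalosporins 0.03, quinolones 0.01,
nitroimidazoles 0.01); formulations mix liquids (0.60), blisters (0.25) and
IU-labelled penicillin (0.15, redirected to plain liquid for ingredients
without an IU factor); and shock multipliers (defaults 0.15 in 2020, 0.2
in 2021) emulate the COVID-era import collapse.

The key design choice is **back-solved geometry**: the drawn target mass is
realised by picking strength/pack values from realistic integer grids and
solving for the container volume (or blister count), then recording in the
ledger the mass recomputed from the same defining formulas.  Both generator
and pipeline aggregate with `math.fsum`, so ledger-versus-pipeline equality
is exact to the bit — the strongest possible end-to-end oracle.  Denominator
tables are generated analogously: census pairs exactly consistent with a
drawn growth rate, slaughter totals equal to count × drawn carcass weight,
and the ledger holding the implied national biomass.

What the generator does **not** emulate: importer-level structure, within-
year seasonality, combination products, data-entry noise (typos, unit
confusion), or unrecorded imports.  Passing the synthetic suite shows the
arithmetic pipeline is correct, not that real import registries are clean;
on real data the registry-resolution errors (unknown ingredient, missing
IU factor, malformed rows) are the guard rails.

The published Fiji 2017–2021 summary tables are bundled
(`vetamc.reference`) so the aggregation/classification/trend layer is also
checked against real national results.  Transcription notes: the printed
tables round each cell independently, so the printed per-year cells sum to
the printed totals only within 0.01–0.10 kg; the second-generation
cephalosporin class total prints as 0 in the year-by-class table but
0.01 kg in its 2019 cell and in the importance table — 0.01 is carried,
which makes the class-total column sum exactly to the printed 464.31 kg
grand total.  Derived shares computed from printed values can differ from
printed shares by one unit in the last decimal (e.g. VCIA share 96.485 vs
printed 96.48; lincosamides 88.044 vs 88.05; sd of annual totals 64.131 vs
printed 64.12); tests assert agreement at the printed precision and these
residuals are documented rather than adjusted away.

## Numerical choices and degenerate inputs

* Group sums and grand totals: `math.fsum` (exact, order-independent).
* Report rounding: half away from zero via `decimal`, default 2 digits.
* Growth-rate/interpolation round-trip holds to 1e-9 relative; the
  `GrowthRate` constructor enforces `(1+r)^y P₁ = P₂`.
* Domain errors are raised for non-positive strengths/volumes/populations,
  pack counts < 1, conversion coefficients outside (0, 1], zero animals
  slaughtered, zero biomass denominators, and series shorter than 3;
  a zero total slaughter weight is allowed but logged as degenerate.
* Two runs with identical config and inputs produce byte-identical CSV/JSON
  outputs.

## Known limitations

* Declared-strength masses ignore salt-mass conventions; cross-country
  comparability depends on the same convention being used elsewhere.
* Geometric census interpolation assumes constant growth over the
  inter-census span; shocks between censuses are smoothed over.
* The Mann–Kendall test on a five-point series has very low power; the
  package reports it because it is the field's convention, with the exact
  p-value making the discreteness plain (only 11 distinct |S| values at
  n = 5).
* No dose-based metrics (DDDvet/DCDvet): mass-based only.
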