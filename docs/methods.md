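# Methods

`foodcost` estimates the "hidden" (external) cost of national diets: the
monetary worth of the damage that producing a country's food supply does to
human health and to ecosystems, plus the change in diet-related disease
burden under counterfactual low-carbon diets.  This note documents the
models, the assumptions, the tunable parameters and the limits of what the
synthetic test worlds can show.

## Production-side accounting

**LCIA core.** Food-item life-cycle inventories are linear in their
elementary flows.  Midpoint impact intensities (per kg of food) are
`i_IMP[f,m] = Σ_j LCI[f,j]·CF_IMP[j,m]`; endpoint (externality) intensities
are `i_EXT[f,e] = Σ_m i_IMP[f,m]·CF_EXT[m,e]`, with endpoints `HH` (human
health, DALY/kg) and `ECO` (ecosystem quality, species loss/kg).
Characterization factors are consumed as plain tables — the damage-pathway
models behind them (e.g. ReCiPe2016, hierarchic perspective) are upstream.
Midpoints without an endpoint link contribute zero by design, so the
"22 midpoints / 2 monetarized endpoints" configuration is one configuration
among many, not a hard-coded list.  Endpoint units are treated as opaque
and consistent with the supplied factor table.  The system boundary is
cradle-to-gate and implicit in the inventories; retail and use stages are
never modelled.

**Supply accounting.** Per-capita supply of each food-balance-sheet group
splits into domestic and imported mass.  The domestic channel is valued at
the unweighted arithmetic mean intensity of the country's own items when
any exist, otherwise at the mean over all of the group's items (the
global-average fallback, flagged in the output's `provenance` column); the
import channel always uses the global export-weighted mean.  Impacts are
linear in supply, totals are sums over groups, and imports accrue to the
importing country (consumption-based allocation, no bilateral trade
matrix).  National totals scale per-capita results by population; the four
income groups (LIC/LMIC/UMIC/HIC) partition the countries, so their totals
sum to the global figure by construction.

**Monetarization.** One DALY is valued by the budget-constraint method:
`MF_HH = α·(GDP + GHP)` with `GHP = 0.5·GDP`, α = 1.87 (range 1.57–2.12)
and the US 2018 GDP per capita (PPP) configured at 62,967 USD, which
reproduces the published 176,624 (148,288–200,236) USD/DALY to within a
few dollars of rounding.  Species loss is valued by benefit transfer:
`MF_ECO(2018) = MF_ECO(2000)·(GDP2018/GDP2000)^ε` with income elasticity
ε = 0.38; since the year-2000 factor and GDP inputs behind the published
2018 value are not available, the shipped defaults carry the 2018 bounds
directly (17,891,594; 4,472,899–44,728,985 USD per species unit) and
`ecosystem_factor()` remains available for users with their own inputs.
All values are 2018 USD; no deflators, no alternative valuation schools.
Cost bounds pair impact CI bounds with factor bounds (lower×lower,
upper×upper).  Derived metrics: the hidden-cost factor (cost per dollar of
food expenditure; aggregates use Σcost/ΣFCE, never a mean of ratios), cost
per 1,000 kcal, and cost as % of GDP.

## Dietary-change scenarios

Eight removal-and-substitution diets progressively remove animal-sourced
food classes (red meat → +poultry → +seafood → +dairy/eggs/animal fat) and
redistribute the lost calories: two-thirds to whole-food plant protein and
one-third to fruits and vegetables, or one-third each to plant protein,
fruits/vegetables and insects (NRM-I, PESC-I) or processed meat/milk
alternatives (VEG-P, VGN-P).  Within a substitute class, calories are
apportioned in proportion to baseline supply (uniformly when the class has
zero baseline, logged); masses come from per-group energy densities; the
domestic/import split of every group is held at its baseline ratio.  Total
calories are conserved exactly for every non-EAT scenario.  Design choices
made where the rules were open: animal fat is removed at the vegan stage;
in VGN-P the processed third routes dairy calories to milk alternatives
and meat/seafood/egg calories to meat alternatives (both overridable on
`ScenarioSpec`).  Impact intensities are held fixed across scenarios — no
supply-side feedback.

The EAT reference diet is handled by rescaling: the recommendation is
carried as 15 aggregated food categories whose intakes sum to 2,503
kcal/day; per category, supply is scaled so intake (supply × edible
portion) hits the target while preserving within-category group
proportions.  The shipped category targets and edible-portion factors are
editable configuration with plausible placeholder values; only their total
(2,503) and the scaling mechanics are treated as fixed.

## Consumption-side comparative risk assessment

Four dietary risk factors (fruit, vegetable, legume, red-meat intake) act
on four diseases (CHD, stroke, cancer, type-II diabetes).  Relative-risk
curves are log-linear per serving, `RR(x) = rr^(x/serving)`, clipped at the
theoretical minimum-risk exposure level: protective factors gain nothing
beyond the TMREL, harmful factors nothing below it.  The population
attributable fraction uses a point mass at the national mean intake,
`PAF = (RR(x) − RR(TMREL))/RR(x)`; a quadrature-based continuous form
exists as an oracle and extension.  Multiple risks combine under
independence, `PAF = 1 − Π(1 − PAF_i)`.  Attributable DALYs multiply the
combined PAF by disease-specific burden; avoided DALYs difference two
diets, with bounds from re-running the chain at the lower/upper 95% CI
relative-risk parameters.  **The shipped RR values, serving sizes and
TMRELs are literature-plausible placeholders**, not a meta-analysis; any
substantive application must supply its own.  Scenario intake is supply
converted through energy density and an edible-portion factor that
defaults to 1.0 (supply as a proxy for intake, logged as a warning).
Consumption-linked DALYs are reported alongside — never summed into — the
monetary accounting, because they arise after purchase and are not
embedded in food prices.

## Uncertainty

Per-item intensity uncertainty is a single-parameter lognormal with median
at the central value and a per-item geometric standard deviation (the
upstream databases' pedigree parameterizations are not reproduced).  Items
are independent; no correlation structure.  Monte-Carlo propagation
(default 1,000 iterations, seeded and reproducible per draw) re-evaluates
a deterministic pipeline closure and percentiles the aggregate — the
statistically correct alternative to aggregating per-item percentiles.
`gsd = 1` degenerates to zero-width intervals.  Monetarization-factor
uncertainty is handled deterministically by bound pairing.

## Synthetic worlds

The generator emulates the structure the analysis assumes, not any real
country's numbers: per-capita calorie totals and ASF calorie shares rise
from low- to high-income groups (defaults 2,200→3,100 kcal/day and
8%→32%); ASF per-kcal endpoint intensities exceed plant ones by a
configurable multiplier (default 2.5); processed alternatives and insects
sit between (default 1.5×); intensities are drawn per kcal and converted
to per kg through the density table so mass and energy stay consistent;
every group has a global item and a random ~40% of countries carry
country-specific items, exercising the fallback rule; import shares are
Beta-distributed around 0.3.  Base per-kcal intensities (6e-9 DALY/kcal,
4e-11 species/kcal, 1e-3 kg CO2e/kcal for plant groups) are calibrated so
a high-income synthetic diet lands in the few-thousand-USD/capita/yr
externality range after monetarization.  The generator records its own
analytic accounting (plain numpy loops, independent of the pandas
pipeline) as a known-truth oracle, and a `force_substitute_below_asf`
switch deterministically rescales substitute intensities below the ASF
minimum to construct worlds where scenario savings are provably monotone
along the nested removal chain.

What passing tests on these worlds shows: the accounting identities,
conservation laws, fallback rules and uncertainty machinery are correct.
What they do not show: anything about real FAO/ERS/LCI data — real supply
marginals, trade patterns, item coverage gaps and intensity correlations
are all absent, so headline magnitudes from synthetic worlds are
illustrative only.

## Numerical choices and edge cases

Problem sizes: the default world has 20 countries (5 per income group);
the repeated-conservation suites use 8-country worlds, and the monotone-
ordering check 4-country worlds.  Ties and degenerate inputs: zero
baseline supply in a substitute class → uniform split (logged); zero
supply in both channels → zero impact; missing expenditure → the country
is excluded by validation (mirroring the both-sources selection rule);
all-zero export weights, non-normalized exposure densities, unordered
bounds and gsd < 1 are errors.  Calorie conservation is asserted to 1e-9
relative; analytic-identity tests to 1e-12 relative; the PAF oracle
equivalence to 1e-4 absolute.

## Known limitations

No bilateral trade, no waste modelling beyond what supply embodies, no
nutritional adequacy scoring, no age/sex stratification or time-lagged
risk accumulation, no price or land-use feedbacks, no resource-scarcity
endpoint, and no parsing of commercial LCI database formats.
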