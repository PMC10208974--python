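# foodcost

Market prices of food omit the damage its production does to third
parties: the disease burden caused by agricultural emissions and resource
use, and the loss of ecological species.  `foodcost` is a Python library
for quantifying these *hidden costs of diets* at national scale and for
asking how much of them low-carbon dietary change could avoid.  It is
aimed at researchers in environmental health, food-system modelling and
ecological economics who want a tested, reusable implementation of the
full chain — from life-cycle intensities to monetarized externalities and
comparative risk assessment — driven by their own tables or by a built-in
synthetic-data generator.

## The model

For every country *c*, food group *g* and endpoint *e* ∈ {HH, ECO}:

```
i_IMP[f,m]  = Σ_j LCI[f,j] · CF_IMP[j,m]            (inventory → midpoint)
i_EXT[f,e]  = Σ_m i_IMP[f,m] · CF_EXT[m,e]          (midpoint → endpoint)
Impact[c,g,e] = ī_dom[c,g,e] · domestic[c,g] + i*[g,e] · import[c,g]
Impact[c,e]   = Σ_g Impact[c,g,e]
Cost[c,e]     = Impact[c,e] · MF[e]
```

where `ī_dom` is the mean intensity of the country's own items (global
mean as fallback), `i*` the export-weighted global mean, and the
monetarization factors are `MF_HH = α·(GDP + GHP)` (budget-constraint
method, 176,624 USD/DALY at the defaults) and a benefit-transferred
ecosystem valuation (17.9 M USD per species unit).  Nine dietary-change
scenarios (EAT reference plus progressive animal-sourced-food removal with
whole-food, insect and processed substitutions on a calorie basis) are
rebuilt from any baseline supply table.  Consumption-side health effects
use population-attributable fractions, `PAF = (RR(x) − RR(TMREL))/RR(x)`
with log-linear RR curves and `PAF = 1 − Π(1 − PAF_i)` across risks.
Uncertainty propagates by seeded lognormal Monte Carlo with percentile
intervals.  See `docs/methods.md` for assumptions and parameter defaults.

## A worked example

```python
>>> import foodcost as fc
>>> world = fc.fixture_tiny()              # 2 countries, hand-checkable
>>> report = fc.run_baseline(world)
>>> report["hidden_cost"]
          level    name  factor
0       country     AAA     2.0
1       country     BBB     2.0
2  income_group     HIC     2.0
3  income_group     LIC     2.0
4        global  GLOBAL     2.0
```

Every dollar spent on food in this stylized world carries two dollars of
external cost (the arithmetic is worked through line by line in
`docs/tiny_world.md`).  On a realistic-scale synthetic world:

```python
>>> w = fc.generate_world(fc.WorldConfig(seed=1))
>>> rep = fc.run_baseline(w)
>>> rep["hidden_cost"].query("level=='global'")["factor"].item()
1.8920990748809055
>>> scen = fc.run_scenarios(w)
>>> scen["ghg"].tail(2)
  scenario  reduction_pct
7      VGN      28.248358
8    VGN-P      26.270383
```

i.e. ~1.89 dollars of externalities per consumer dollar at baseline, and a
~28 % cut in food-production GHG emissions under the vegan scenario.  The
`examples/` directory has one narrative script per capability (LCIA,
baseline costs, scenarios, health CRA, uncertainty); each prints its
numbers with a line on what they mean.  A thin CLI wraps the same
pipeline: `foodcost generate|baseline|scenarios|cra|report --help`.

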