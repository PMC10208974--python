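# The tiny world: worked answers

`foodcost.fixture_tiny()` builds a deliberately stylized two-country,
four-group world in which every pipeline result can be verified by hand.
Intensities are whole numbers per kg (not realistic magnitudes) and the
monetarization factors are correspondingly tiny, so the arithmetic stays
mental.  Energy densities are 3,650 kcal/kg (so kg/yr × 10 = kcal/day)
except fruits at 365 kcal/kg (kg/yr × 1 = kcal/day).

## Inputs

Supply (kg per capita per year; kcal per capita per day):

| country | group  | domestic | import | kcal/day |
|---------|--------|---------:|-------:|---------:|
| AAA     | wheat  | 40       | 10     | 500      |
| AAA     | beans  | 10       | 0      | 100      |
| AAA     | fruits | 100      | 0      | 100      |
| AAA     | beef   | 20       | 10     | 300      |
| BBB     | wheat  | 48       | 0      | 480      |
| BBB     | beans  | 30       | 10     | 400      |
| BBB     | fruits | 80       | 20     | 100      |
| BBB     | beef   | 2        | 0      | 20       |

Both diets total 1,000 kcal/day.

Item intensities (per kg; HH in DALY, ECO in species units):

| item       | holder | HH | ECO | export weight |
|------------|--------|---:|----:|--------------:|
| beef-GLO1  | GLO    | 4  | 2   | 0.75          |
| beef-GLO2  | GLO    | 2  | 2   | 0.25          |
| beef-AAA   | AAA    | 3  | 2   | –             |
| beans-GLO  | GLO    | 1  | 1   | 1             |
| fruits-GLO | GLO    | 1  | 0   | 1             |
| wheat-GLO1 | GLO    | 2  | 1   | 0.5           |
| wheat-GLO2 | GLO    | 0  | 1   | 0.5           |

Registry: AAA (HIC) population 1,000,000, FCE 315/capita, GDP 3,150/capita;
BBB (LIC) population 2,000,000, FCE 240, GDP 2,400.  Monetarization: 2 per
DALY (bounds 1–3), 1 per species unit (bounds 0.5–2).

## Baseline impacts (per capita per year)

Domestic channel uses the country's own items when any exist (AAA has
beef-AAA), else the mean over all of the group's items; imports use the
export-weighted mean.

AAA, human health:

- beef: own item mean 3 × 20 dom + (0.75·4 + 0.25·2 = 3.5) × 10 imp = 60 + 35 = **95**
- beans: 1 × 10 = **10**; fruits: 1 × 100 = **100**
- wheat: all-item mean (2+0)/2 = 1 × 40 + 1 × 10 = **50**
- total HH = **255 DALY**

AAA, ecosystems: beef 2×20 + 2×10 = 60; beans 10; fruits 0; wheat 40+10 = 50
→ total ECO = **120**.

BBB, human health: beef all-item mean (4+2+3)/3 = 3 × 2 = 6; beans 30+10 = 40;
fruits 100; wheat 48 → **194 DALY**.  Ecosystems: beef 4; beans 40; fruits 0;
wheat 48 → **92**.

## Costs and hidden-cost factors

- AAA: 255 × 2 + 120 × 1 = **630** per capita; 630 / 315 FCE = **2.0**
- BBB: 194 × 2 + 92 × 1 = **480** per capita; 480 / 240 = **2.0**
- National: 630 M (AAA) + 960 M (BBB) = **1.59 B** global;
  global hidden-cost factor = 1.59 B / (315 M + 480 M) = **2.0**
- GDP shares: 630/3,150 = 20 % (AAA); 480/2,400 = 20 % (BBB)

## No-red-meat scenario (NRM)

Beef is removed (AAA loses 300 kcal/day, BBB 20); two-thirds of the lost
calories go to whole-food plant protein (beans), one-third to fruits and
vegetables (fruits here), converted to mass through the densities and split
domestic/import at the baseline ratio.  For AAA: beans +200 kcal/day
(+20 kg/yr, all domestic → 30 kg), fruits +100 kcal/day (+100 kg/yr).
Totals stay at 1,000 kcal/day exactly.

These numbers are asserted in `tests/test_synthetic.py` and
`tests/test_pipeline.py`.
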