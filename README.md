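# cocoazone

Ensemble habitat-suitability modelling and climate-adaptation zoning for a
perennial crop, on equal-area raster worlds with fully synthetic, ground-
truthed inputs.

The package is aimed at agro-ecologists and land-use planners who want to
ask: *given a crop's climate niche and a region's soils and
infrastructure, where should production be intensified, expanded,
diversified, converted to other crops, or avoided as the climate shifts?*
The running example is cocoa (*Theobroma cacao*) in a humid-tropics
landscape under two mid-century emissions scenarios (RCP 4.5 and 8.5).

## What it computes

* **Climate suitability** — a species-distribution ensemble. Occurrences
  are cleaned, the 19 bioclimatic predictors are pruned at |Pearson r| ≤
  0.7, pseudo-absences are drawn outside the presences' surface range
  envelope (SRE), and four learners (SRE, logistic, boosted trees,
  splines) are fitted on a stratified 75/25 split. Each learner is scored
  with the True Skill Statistic, TSS = max₍t₎ (sensitivity + specificity −
  1), and AUC; learners with TSS > 0.7 enter an unweighted ensemble that
  is projected onto the current climate and onto a per-scenario consensus
  (layer-wise mean across five GCMs).
* **Soil suitability** — a cell is plantable iff its soil is one of four
  reference groups (Acrisols, Fluvisols, Nitosols, Ferralsols) with low
  stoniness, and either eutrophic (high fertility, any territory) or
  dystrophic but inside the well-connected *network* planning territory;
  protected areas are excluded.
* **Adaptation zoning** — suitability is classed at the 20 % / 50 % cuts
  and combined with municipal crop prevalence (dominant / present /
  absent, from production rankings) in a decision table yielding five
  zones; zone areas (km² and %) are tabulated per scenario, with derived
  percentage-point change statistics and a territory × scenario ANOVA of
  per-cell suitability.

A synthetic-data module generates the whole world — correlated smooth
bioclim layers, a known true suitability surface, occurrences sampled from
it, soils, territories, municipalities with production tables, protected
areas, and per-GCM future climates shifted by reported per-variable deltas
— so every stage is testable against ground truth without downloads.

## Worked example

```python
from cocoazone import run_pipeline
from cocoazone.synthetic_data import WorldConfig

res = run_pipeline(WorldConfig(seed=1), seed=1)
print("kept predictors:", res.selection.kept)
for ev in res.ensemble.evaluations:
    flag = "in" if ev.included_in_ensemble else "out"
    print(f"  {ev.learner_name:<9s} TSS={ev.tss:.3f}  AUC={ev.auc:.3f}  [{flag}]")
print(res.zone_table.df.pivot(index="zone", columns="scenario", values="percent"))
print("combined intensification+expansion share:",
      res.change_stats.combined_int_exp_share)
```

prints

```
kept predictors: ['bio3', 'bio8', 'bio9', 'bio10', 'bio14', 'bio19']
  flexible  TSS=0.827  AUC=0.963  [in]
  linear    TSS=0.773  AUC=0.884  [in]
  smooth    TSS=0.747  AUC=0.951  [in]
  sre       TSS=0.680  AUC=0.840  [out]
scenario         RCP4.5  RCP8.5  current
zone
conversion        32.93   50.27    18.88
diversification   15.76    6.38    15.99
expansion          3.64    0.00    36.01
intensification    4.99    0.36    16.53
not_recommended   42.69   42.99    12.59
combined intensification+expansion share: {'current': 52.54, 'RCP4.5': 8.63, 'RCP8.5': 0.36}
```

Reading it: the collinearity filter kept six weakly correlated predictors
(proxies of the six layers that drive the true surface); three of the four
learners cleared the TSS > 0.7 gate and form the ensemble; and the warming/
drying deltas collapse the area worth intensifying or expanding from
52.5 % of the plantable soils today to 8.6 % (RCP 4.5) and 0.4 % (RCP 8.5),
with the slack absorbed by conversion and not-recommended zones.

The same analysis runs from the shell on a directory of rasters and CSVs:

```bash
cocoazone simulate --seed 1 --out world/
cocoazone fit world/ --out fit/ --seed 1
cocoazone zone world/ fit/ --out zones/
cocoazone report zones/ --out report/ --world-dir world/ --fit-dir fit/
```

`cocoazone report --from-areas areas.csv --out report/` replays the
reporting conventions on an externally published per-zone area table
(see `cocoazone.datasets`).

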