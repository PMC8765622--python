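# Methods

`cocoazone` implements an edaphoclimatic suitability and climate-adaptation
zoning analysis for a perennial tropical crop (the running example is cocoa,
*Theobroma cacao*): an ensemble species-distribution model (SDM) projects
climate suitability under current and mid-century emissions scenarios, a
soil-by-infrastructure rule delimits plantable soils, and a decision table
classifies the plantable landscape into adaptation zones whose areas are
tabulated and compared across scenarios.

## The modelling pipeline

1. **Occurrence cleaning.** Records with malformed or out-of-range
   coordinates are removed first, then exact coordinate duplicates are
   collapsed to their first occurrence; both counts are logged.
2. **Predictor selection.** Pairwise Pearson correlations between the 19
   bioclimatic layers are computed over all shared non-nodata cells. While
   any pair exceeds |r| = 0.7, the member of the worst pair with the larger
   mean |r| against the remaining layers is dropped (ties drop the later
   name in canonical bio1…bio19 order). The 0.7 bound is the standard
   collinearity remedy in correlative SDMs; the elimination order is our
   choice (deterministic, insertion-order independent). Zero-variance
   layers are excluded up front.
3. **Pseudo-absences.** A surface range envelope (SRE) is fitted on the
   presence climates: per selected variable, the [q, 1−q] empirical
   quantiles with q = 0.025 by default. 300 pseudo-absences are drawn
   uniformly without replacement from non-presence cells outside the
   envelope — background points climatically unlike the occurrences.
   Fewer eligible cells than requested sets an explicit shortfall flag;
   zero eligible cells is an error advising a smaller q.
4. **Ensemble.** The labelled set is split 75/25 stratified by label. Four
   learners are fitted behind one contract (`score(x) ∈ [0, 1]`,
   deterministic given a seed): `sre` (envelope membership, 0/1), `linear`
   (logistic regression on standardized predictors), `flexible` (gradient
   boosted trees), `smooth` (cubic-spline basis + logistic regression).
   Each is evaluated on the held-out quarter with the True Skill Statistic
   TSS = max over thresholds of (sensitivity + specificity − 1), the
   maximum taken exactly over all midpoints of distinct sorted scores, and
   AUC as the tie-corrected rank statistic. Learners with TSS > 0.7 enter
   the ensemble; the projected suitability is their unweighted mean.
   An optional replicate mode repeats the split/fit/evaluate cycle on
   independent seeded splits; a learner's TSS is then the replicate mean
   and all replicate models of passing learners join the ensemble. The
   default is a single seeded split.
5. **Scenario projection.** For each emissions scenario the per-GCM stacks
   are first averaged layer-by-layer into one consensus stack (nodata
   wherever any member is nodata), and the fitted ensemble is then
   projected onto the consensus — consensus of variables before
   projection, not an average of projections.
6. **Soil suitability.** A cell's soil is plantable iff its reference group
   is one of {Acrisol, Fluvisol, Nitosol, Ferralsol}, stoniness is low, and
   fertility satisfies the infrastructure rule: eutrophic (high-fertility)
   soils qualify in every planning territory, dystrophic soils only inside
   the network territory (consolidated infrastructure); protected cells
   (indigenous lands and conservation units, merged) are excluded. The
   conjunction is order-independent.
7. **Zoning.** Continuous suitability is cut at 0.20 and 0.50 into very
   low / low-to-medium / medium-to-high classes; both cut values fall in
   the middle class (the published bands read "<20%", "20 to 50%", ">50%").
   Municipal crop prevalence comes from production rankings: rank ≤ 2 with
   positive value → dominant; rank ≥ 3 with positive value → present;
   zero or no production → absent; value ties share the better rank. The
   decision table maps (current class, future class, prevalence) to
   intensification / expansion / diversification / conversion /
   not-recommended zones. The published table covers 14 of the 27 possible
   triples; a conservative completion rule resolves the rest (improvement
   from a very-low current base is not recommended unless the future is
   medium-to-high on an established base; low-to-medium futures with no
   current production are not recommended) and logs each firing so its
   footprint is auditable. The current-scenario map uses a single-column
   variant of the table — the only reading under which the current
   scenario can have a nonzero conversion area, as the published area
   table does.
8. **Reporting.** Zone areas are exact cell counts × the constant per-cell
   area; percents are 100·area/total rounded half-up to two decimals
   (`decimal.Decimal`; banker's rounding cannot reproduce the published
   presentation). Combined intensification+expansion and
   diversification+conversion shares are computed from raw areas and then
   rounded; the "reduction"/"increase" statistics are percentage-point
   differences of the already-rounded per-zone percents. This mixed
   convention is deliberate: it is the only one under which every derived
   number quoted alongside the published area table reproduces exactly
   (e.g. 81.47 − 44.72 = 36.75 while the combined share itself prints as
   44.73). Reductions are percentage-point differences of shares, not
   relative changes.
9. **ANOVA.** A two-way fixed-effects main-effects ANOVA (no interaction)
   of per-cell ensemble suitability on the plantable-soil mask, grouped by
   territory and scenario, computed from explicit sums of squares
   (SS_factor = Σ n_level(mean_level − grand mean)²; residual by
   subtraction; exact decomposition in the balanced case). A factor with a
   single level is dropped, degenerating to a one-way ANOVA. The sampling
   unit (cells on the soil mask, default 1000 per scenario) is our choice.

## The synthetic world

All inputs can be generated with known ground truth, so the full pipeline
is testable without downloads.

* **Climate.** 19 layers on a 120 × 120 equal-area grid (25 km²/cell).
  Six latent fields are built by low-pass filtering white noise (Gaussian
  kernel of width grid/10 — spatial autocorrelation is required for
  plausible envelopes), QR-orthogonalized, then passed through
  z + 0.7 z³ and re-standardized. The cubic term fattens the marginal
  tails: a continental extent holds much land climatically far outside
  any one crop's niche, which unit-Gaussian fields understate. After the
  transform the latents are no longer exactly uncorrelated (empirically
  |r| ≲ 0.35, far below the 0.7 filter). The six latents become bio2,
  bio3, bio8, bio9, bio14, bio15 with plausible tropical means and
  spreads; the other 13 codes are mixtures dominated by one latent
  (weights 0.95/0.2/0.15-noise), hence collinear (|r| ≈ 0.95) with it —
  the correlation filter has real work to do, and at the defaults it
  typically keeps exactly the six latent-backed layers.
* **Truth and occurrences.** True suitability is
  logistic(−4.0 − 3.2·z(bio2) + 2.0·z(bio3) − 2.4·z(bio8) − 4.0·z(bio9)
  + 4.8·z(bio14) − 3.2·z(bio15)), each layer standardized on the grid.
  The large coefficient magnitudes give the crop a well-defined niche —
  suitability near 0 or 1 over most of the map with a narrow transition
  band — and the negative intercept makes clearly suitable habitat about
  a third of the landscape. This sharpness matters: occurrences are
  sampled (without replacement, 300 by default) with probability
  proportional to suitability, and with a diffuse surface a large share
  of presences would sit in the transition band, capping even the true
  surface's achievable TSS near 0.7. A crop with a distinct climate
  niche is also the realistic case for this kind of zoning analysis.
* **Future scenarios.** Two scenarios ("RCP4.5", "RCP8.5"), five pseudo-
  GCMs each. Every GCM stack is current + per-variable delta + zero-mean
  noise (per-variable spreads of 0.08–2 in native units). The default
  deltas are the reported mid-century shifts for the selected variables:
  bio2 +0.25/+0.31 °C, bio8 +1.45/+2.94 °C, bio9 +2.0/+2.67 °C,
  bio14 −9/−19.6 mm/month, bio15 +4/+7.7 CV units (RCP4.5/RCP8.5), so the
  synthetic future stresses suitability through the same drying/warming
  pattern.
* **Context.** Soil attributes come from independent smooth fields cut at
  fixed quantiles (reference groups 25/10/15/25/25 %, eutrophic 40 %, low
  stoniness 70 %); the territory is a contiguous three-seed Voronoi
  partition (network/zone/border); ~30 municipalities form a Voronoi
  mosaic; production values are engineered so dominant, present and
  absent prevalence classes all occur (including a zero-cocoa
  municipality); the protected mask is the top decile of one more smooth
  field.

**What the generator does not emulate:** real climatologies or GCM physics,
real Brazilian geography or soil maps, spatial sampling bias in occurrence
archives, coordinate uncertainty, or non-climatic drivers of occurrence.
Passing tests therefore demonstrate that the pipeline's logic is correct
and that it recovers a known truth under its own assumptions — not that
the real-data skill figures of any particular study are reproducible.

## Numerical conventions and edge cases

* Grids are projected and equal-area; row 0 is the northernmost row; a
  point belongs to a cell via half-open intervals [x, x+Δ). Geodesic cell
  areas are out of scope.
* Nodata propagates pessimistically through every stage.
* TSS threshold search enumerates midpoints of distinct scores exactly; a
  constant score vector has TSS 0 at that score. AUC uses average ranks
  (ties count half).
* Suitability stays on [0, 1] everywhere; integer scalings are an I/O
  formatting concern only.
* Pseudo-absence eligibility excludes presence cells, avoiding
  contradictory labels on one cell.
* Rounding of reported areas/percents is half-up to 2 decimals.
* Problem sizes: the default study conditions are a 120 × 120 grid, 300
  occurrences, 300 pseudo-absences, 5 GCMs per scenario and 1000
  ANOVA cells per scenario; the test suite additionally uses 48 × 48
  worlds where only structure, not model skill, is being checked.

## Known limitations

* The learner registry ships four algorithms, not the ten of large SDM
  frameworks; the contract (fit/score/evaluate/gate) is what is under
  test, and additional learners can be registered.
* The SRE-based pseudo-absence design places truncation noise near the
  envelope boundary: cells just outside the presence envelope can be
  climatically suitable yet labelled absent. This caps achievable TSS
  below 1 by construction and is inherent to the strategy, not a defect
  of the implementation.
* With a single 75/25 split, per-learner TSS on 150 test rows carries
  noticeable sampling variance (±0.05 is common); the replicate mode
  averages it away at the cost of runtime.
* The ANOVA omits the territory × scenario interaction and treats cells
  as independent observations; spatial autocorrelation inflates its
  nominal significance, so its p-values should be read as descriptive.
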