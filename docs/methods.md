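# Methods

This note documents the models, the synthetic study system, the numerical
conventions, and the design choices that were genuinely open.

## Study design

The analysis follows the standard consensus-SDM design for a presence-only
species: replicate pseudo-absence sets stand in for true absences, many
algorithms are fitted and scored on repeated held-out splits, skilful runs
are blended into a weighted ensemble, and the climatic ensemble is gated
by static biotic layers (soil, vegetation) before areas are accounted and
scenarios projected. The protocol constants are: 3 pseudo-absence
replicates × 500 points; 200 km great-circle buffer around the occurrence
convex hull; stratified 70/30 splits repeated 10 times per
(replicate, algorithm); equal total class weights; mean-TSS ≥ 0.5
algorithm screen; per-run TSS weights; class thresholds 0.3 and 0.5;
soil model on 75/25 splits with 10 replicates; scenario grid of
2 periods × 4 pathways × 3 climate models.

## The synthetic world

All continuous fields are Gaussian random fields: white noise smoothed
with a Gaussian kernel of bandwidth `autocorr_length` cells (default 5)
and rescaled to unit variance, then placed on deterministic structure.
The default world is a 100×100 grid of 0.1° cells spanning 95–105°E,
28–38°N — a coarse-grained stand-in for a mountainous study region.

* **Elevation** is a pure random field (mean 3000 m, sd 1100 m, floor
  200 m). **Slope/aspect** come from Horn's eight-neighbour finite
  differences with replicated borders; east–west spacing uses the cosine
  of each row's latitude; aspect is the downslope azimuth in degrees
  [0, 360), with −1 as the flat-cell sentinel.
* **Temperature layers** (annual mean bio1, warmest/coldest-quarter means
  bio10/bio11, warmest-month max bio5) share a latitudinal gradient
  (−0.45 °C per degree north) and an elevational lapse (−5.5 °C/km) plus
  independent noise; **seasonality** (bio4) rises gently with latitude.
  **Precipitation layers** (bio12, bio13, bio19, seasonality bio15) are
  nonnegative with a wet-south, orographic tilt. bio5 and bio13 are
  deliberately collinear with bio10 and bio12 so the correlation screen
  has real work to do.
* **Soil and vegetation mosaics** are quantile bins of
  elevation-plus-noise scores (10 soil classes, 8 vegetation classes), so
  both are spatially coherent and tied to elevation bands, as in real
  montane landscapes. The species' suitable vegetation defaults to the
  mid/upper bands {4, 5, 6} (the analogue of alpine forest, shrubland and
  alpine meadow).
* **Scenario deltas** are spatially uniform per layer: temperature layers
  shift by a pathway-dependent warming (1.0–3.6 °C) plus a small
  per-model offset (−0.25 to +0.3 °C); seasonality rises by 0.15 °C per
  degree of warming; precipitation layers scale by +2.5 % per degree
  (high-altitude wetting). Soil, vegetation and topography never change,
  which encodes the lag of soil/vegetation turnover behind climate.

## The virtual species

True suitability is a product of per-variable Gaussian responses
`exp(−(x−μ)²/2σ²)` over bio1 (μ = 5 °C, σ = 1.4), bio10 (13, 1.8),
bio11 (−4, 2.0) and bio12 (800 mm, 260): a cold-humid alpine herb whose
niche is temperature-driven (narrow σ relative to landscape spread) with
only a broad precipitation dependence. The niche optimum was placed, once,
at the climate of the mid/upper-elevation vegetation band, so that (a) the
species is internally coherent (its climate, soils and vegetation
co-occur), and (b) warming moves the climatic optimum upslope off the
static vegetation/soil bands — the structural mechanism by which the
suitable class must shrink under warming. These choices were fixed before
the test suite was frozen and are not revisited; they were calibrated so
that model skill lands in the regime reported for real consensus studies
of narrow-ranged species (single-model AUC near 0.9, ensemble near 0.95,
envelope model clearly weakest) rather than in a trivially easy or
impossibly hard regime.

Occurrences are sampled without replacement with probability proportional
to suitability (times a prevalence factor), and cell centers are
returned — so presences contain marginal-habitat records, as real
herbarium data do. The default count is 99 (the reference study's
occurrence count); parameter-recovery analyses use 200.

What the generator does **not** emulate: geographic sampling bias,
coordinate error, spatially structured residuals in the niche (the true
response is exactly product-Gaussian), land-use change, and dispersal
limits beyond the vegetation gate. Passing recovery tests therefore show
that the pipeline is correct and statistically well-behaved under its own
assumptions, not that any real species obeys them.

## Algorithms

The SRE (BIOCLIM envelope) and the categorical soil maximum-entropy model
are implemented from scratch; the other learners are scikit-learn
estimators behind a uniform wrapper that returns suitabilities in [0, 1]:

| id | implementation | output transform |
|----|----------------|------------------|
| GLM | logistic regression on linear+quadratic features, effectively unpenalized (C=1000) | probability |
| MAXENT | the presence-background maximum-entropy equivalence: regularized logistic regression (C=1) on linear+quadratic features | probability |
| GAM | cubic B-spline basis (6 knots) per variable + logistic regression | probability |
| MARS | hinge (piecewise-linear) basis at the 0.2/0.4/0.6/0.8 training quantiles + logistic regression | probability |
| FDA | linear discriminant analysis on the same hinge basis | probability |
| CTA | decision tree (min leaf 10) | leaf class probability |
| RF | random forest (100 trees, min leaf 2) | vote fraction |
| GBM | gradient boosting (100 stages) | probability |
| ANN | multilayer perceptron (one hidden layer of 8, α=1e−3) | probability |
| SRE | per-variable presence quantile envelope, tail 0.025 per side | binary {0, 1} |

Case weights (presence 1, absence n_p/n_a) are passed to every estimator
whose `fit` accepts them; ANN and FDA do not and are fitted unweighted.
A failed fit is flagged and excluded downstream (shrinking *h*) rather
than aborting the protocol. The SRE tail of 0.025 per side is the common
envelope-model default.

## Evaluation conventions

* Predictions are positive iff score ≥ threshold.
* The TSS-optimal threshold is found by scanning 0.00–1.00 in steps of
  0.01, ties broken toward the lower threshold. The reported r_j for the
  ensemble weights is each run's held-out TSS at that threshold.
* AUC is the weighted, tie-corrected Mann–Whitney area
  (`sklearn.metrics.roc_auc_score`); the test suite checks it against an
  exhaustive presence×absence pair enumeration.
* "Repeated bootstrapping" is realized as repeated random stratified
  70/30 splits (the held-out 30 % is genuinely unseen), not resampling
  with replacement.
* The ensemble is evaluated twice: pooled over all presences and all
  1500 pseudo-absences (a calibration score, comparable to consensus-
  platform practice), and on an independent holdout of freshly sampled
  virtual-species presences plus a fresh background replicate (a true
  out-of-sample score, possible only because the species is synthetic).

## Soil model

For a single categorical predictor the maximum-entropy solution is
closed-form: the cell weight of category *k* is proportional to the
relative occurrence rate ρ_k = P(k|presence)/P(k|background). Counts are
add-1 smoothed per category on both sides, and the logistic output at
τ = 0.5 maps ρ to S_k = ρ/(ρ+1), giving 0.5 exactly where presences match
the background rate. The background is the same buffered-hull region used
for pseudo-absences, keeping presence/background geography consistent.
Categories never seen in training get the neutral prior 0.5. Replicate
AUCs hold out 25 % of presences against the full background.

## CHS classification

The three-class rule uses ≥ semantics at both thresholds, and the
suitable class requires the vegetation gate (V = 1) even though a literal
reading of the printed class definitions omits it — the overlay is an
intersection BT ∩ S ∩ V and the species only grows in the listed
vegetation, so a V = 0 cell cannot be suitable. Cells missing any input
carry the CHS NoData code (−1).

## Numerics and conventions

* Grids are WGS84 lon/lat; row 0 is northernmost; a cell contains its
  upper-left corner (half-open indexing), used consistently for
  extraction, presence-cell mapping and pseudo-absence exclusion.
* Rasters are ESRI ASCII grids written at 17 significant digits
  (lossless for float64). The format carries no CRS; reading without an
  explicit label warns and tags "unknown".
* Great-circle distances use the haversine formula on a 6371 km sphere;
  the hull buffer densifies the hull boundary at cell/8 resolution, so
  the 200 km contour is honoured to well under a cell width.
* Cell areas are exact spherical quadrilaterals,
  A = R²·Δλ·(sin φ_top − sin φ_bottom); zonal tables keep full precision
  and round only at serialization (2 decimals).
* Duplicate occurrences are exact coordinate matches (no fuzzy radius);
  points on NoData cells are dropped with a logged count.
* Aspect is circular: the correlation screen encodes it as (cos, sin)
  and collapses the pair to the stronger channel, so the 0/360 wrap
  cannot create artifactual correlations.
* All randomness flows from one master seed; stage and replicate streams
  are derived by a CRC-32 hash of (seed, stage label, indices), so stages
  are independently reproducible and reordering one never perturbs
  another.

## Predictor choice

The default predictor set is the nine-variable reference preset (bio1,
bio4, bio10, bio11, bio12, bio15, bio19, slope, aspect) — the set used
in the reference study — because a data-driven screen cannot reproduce an
unpublished selection. The PCA-guided Pearson screen (threshold 0.80,
priority = explained-variance-weighted loadings, alphabetical
tie-breaks) is fully implemented and can be switched on
(`variables="screen"`); on this world it collapses the strongly
inter-correlated temperature/elevation block, which is exactly what a
0.8 pairwise screen must do when |r(bio1, bio10)| ≈ 0.99.

## Problem sizes

The reference configuration used by the analysis drivers, the acceptance
script and the end-to-end tests is the 100×100 world with 200 presences
and the full 3 × 10 × 10 protocol and 24-member scenario grid (~2 minutes
on one core). Unit tests use 40×40 worlds and reduced replication chosen
to keep each check sharp.

## Known limitations

* The soil model's discriminative ceiling is set by the categorical
  resolution of the soil mosaic; with 10 classes its holdout AUC
  (~0.64 on the default world) is well below what a rich real soil map
  supports.
* Scenario deltas are spatially uniform, so projected change patterns are
  driven entirely by the current spatial structure, not by heterogeneous
  climate-change velocity.
* The "local adaptive" refinement of the buffered-hull background tool is
  unpublished; the plain buffered convex hull (interior included) is used.
* Future ensembles project current fits onto shifted layers (standard SDM
  transfer); no refitting under future climates is attempted.
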