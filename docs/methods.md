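# Methods

`benthoscape` implements a stacked species-distribution-model (SSDM)
workflow for benthic image surveys in abyssal nodule provinces, together
with a synthetic seascape generator that reproduces the statistical
structure such surveys exhibit, so the whole pipeline can be exercised
and validated without access to proprietary survey data.

## The analysis pipeline

The pipeline proceeds in seven stages, each an importable module:

1. **Rasters** (`grids`). All spatial data are square-celled, north-up
   grids in one planar metric CRS; nodata is NaN internally and a
   sentinel on disk (ESRI ASCII or single-band float32 GeoTIFF).  Cell
   centres sit at `origin + (i + 0.5)·cell`; point-in-cell tests use
   half-open intervals so every survey image falls in exactly one cell.
   Resampling to a coarser grid assigns each source cell to the target
   cell containing its centre; source and target resolutions therefore
   need not nest as integer multiples (the workflow mixes 121-m and
   715-m grids, which do not).  Nodata propagates conjunctively through
   multi-layer stacks.

2. **Terrain derivatives** (`terrain`).  Slope and aspect by Horn's 3×3
   finite-difference gradient on elevation (the default of common raster
   tooling); aspect enters all downstream analyses as its (sin, cos)
   pair to avoid the 0°/360° discontinuity, with (0, 0) marking flat
   cells.  The bathymetric position index at radius *r* is the cell's
   elevation minus the mean elevation over a filled disc of radius *r*
   (centre excluded); an annulus (inner radius) is available for
   sensitivity checks.  Radii in metres convert to cells by rounding to
   the nearest integer ≥ 1.  Default scales: 1 km and 17 km, separating
   ridge texture from seamount-scale relief.

3. **Survey cleaning** (`survey`).  Overlapping frames are removed
   greedily in acquisition order: a frame is dropped when its centre
   lies within `factor · (side_i + side_j)/2` of a retained frame's
   centre, side = √area (square footprint, factor 1 by default).  Counts
   are converted to presence/absence, and morphotypes observed in fewer
   than 10 images are excluded before modelling (the boundary is
   configurable: ≥ 10 by default, since "fewer than 10 excluded" and
   "more than 10 used" leave exactly-10 ambiguous; the 208 − 140 = 68
   bookkeeping is unaffected).  Survey summaries report specimens,
   imaged area, density, richness, and singletons (morphotypes with
   exactly one specimen overall).

4. **Stratified subsampling** (`stratify`).  To equalise sampling effort
   across terrain, the terrain stack (z-scored: depth, backscatter,
   slope, aspect pair, BPI at two scales have incommensurate units) is
   clustered into k strata — k-means, or k-medoids via the CLARA scheme
   (PAM on random subsets, keeping the medoid set with least total
   dissimilarity over all cells; PAM itself is a BUILD + SWAP
   implementation).  k is an explicit parameter, never auto-selected
   here.  Images are then drawn uniformly within strata with sizes
   proportional to areal coverage, anchored on the stratum minimising
   `available/coverage`, which is allocated in full; other strata get
   `round(available_anchor · coverage_c / coverage_anchor)` capped at
   availability (nearest integer, ties up — consistent with exact
   proportionality at 50.5 images per percent coverage in the worked
   allocation 303/1212/1414/1818 over 6/24/28/36 %).

5. **Distribution models** (`sdm`).  One presence/absence random-forest
   classifier per morphotype on the environmental predictors sampled at
   each image's cell.  Settings pin the classic randomForest defaults:
   500 trees, `mtry = floor(√p)`, bootstrap sampling, no class
   weighting (class imbalance is deliberately not corrected; a balanced
   mode exists for sensitivity analysis only).  The predicted
   probability at a cell is the fraction of trees voting presence
   (terminal-node frequencies are the other convention; vote fraction
   was chosen and is recorded in model provenance).  Out-of-bag error is
   the per-model performance estimate.  Per-morphotype seeds derive from
   (global seed, morphotype id) via CRC-32, so results are independent
   of column order.  Point-sampled variables (boxcores) are carried to
   grids by a random-forest regression on the covariate layers (OOB R²
   reported, ≥ 10 on-grid points required).

6. **Community maps** (`community_maps`).  Richness at a cell counts
   morphotypes with probability strictly greater than 0.5.  Assemblage
   maps cluster cells by their raw probability vectors (all in [0, 1],
   commensurate); habitat maps concatenate z-scored environmental
   variables (units differ), optionally masking cells shallower than
   3000 m and/or block-mean resampling to a comparison resolution (715 m)
   *before* clustering.  Cluster counts come from a k-means cascade
   (Lloyd, Euclidean, best of 25 starts per k) scored by the
   Calinski–Harabasz criterion CH = [B/(k−1)]/[W/(n−k)]; CH at W = 0 is
   reported as +∞ and excluded from the argmax unless all scores are
   infinite.  Labels are canonicalised 1..k by descending cluster size
   so runs are comparable.

7. **Statistics and comparison** (`stats_compare`).  Pairwise PERMANOVA
   on the per-cell probability vectors: from squared distances,
   SS_total = (1/N)Σ_{i<j}d²_ij, SS_within = Σ_g (1/n_g)Σ_{i<j∈g}d²_ij,
   pseudo-F = [SS_between/(k−1)]/[SS_within/(N−k)], and
   p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1) over random label
   permutations (999 by default, one-way exchangeable design);
   Bonferroni adjustment with m = C(k,2).  Euclidean distance is the
   default (probabilities are bounded and commensurate); Bray–Curtis is
   available.  Observational units are cells; for tractability a seeded
   random subsample of cells per assemblage (500 by default) is used and
   disclosed in the result provenance.  Composition tables report each
   morphotype's occurrence fraction per assemblage (ternary coordinates
   for three assemblages).  Two label maps are compared through their
   confusion matrix over jointly valid cells with an optimal one-to-one
   label matching (assignment problem), yielding a matched agreement
   proportion and a difference map.

Orchestration (`pipeline`) derives every stage seed deterministically
from the global seed and the stage name; a run is a pure function of its
serialized YAML config, and re-running produces byte-identical tables.

## The synthetic seascape

The generator emulates the study conditions of an eastern-CCZ-style
nodule exploration area:

- **Bathymetry**: plains from 4100 to 4350 m deepening westward (250 m
  across the extent), three Gaussian seamounts rising 2200–2600 m above
  the plain (summits near 1500–2100 m), a N–S sinusoidal ridge/trough
  field (amplitude 60 m, wavelength 14 km), and smooth noise (15 m sd);
  depths are clipped to the 1400–4600 m study envelope.  Default extent
  150 × 250 cells at 715 m.
- **Environment**: nodule abundance (kg m⁻²) rises eastward as a sharp
  facies contact (sparse western fields ~2.5 kg m⁻², contiguous eastern
  fields ~20 kg m⁻²), is depleted where few-km-scale relief is strong
  (a saturating window, so gentle ridge texture keeps most of the field
  while flanks are swept bare) and is absent above 3800 m; backscatter
  is a linear function of nodule abundance plus noise; mud fraction is
  anticorrelated with slope.
- **Community**: each morphotype's per-image occurrence probability is
  `max_p · logistic(intercept + Σ β_c z_c)` with covariates z-scored
  over the seascape, so coefficients read as log-odds per SD.  The
  default 80-morphotype community (12 seamount specialists, 20
  nodule-plain, 10 trough-associated, 18 generalists, 20 rare) is
  calibrated by one common scale factor on the `max_p` values so the
  expected density equals 0.6 individuals m⁻²; at the default 5000-image
  effort roughly 60–70 morphotypes survive the 10-image prevalence
  filter, with the rare archetype sitting at that boundary by design.
- **Survey**: straight transects with random start/heading and jittered
  spacing; image areas ~N(8, 1.5²) m²; presence per image is Bernoulli
  at the planted probability of the image's cell; counts given presence
  are zero-truncated Poisson (λ = 0.3, so most detections are
  singletons — the sparse-megafauna regime); a configurable fraction of
  frames is duplicated in place as ground-truth overlaps.

### The three-zone recovery surface

`three_zone_community` defines the planted-structure benchmark: three
archetype groups anchored on the two covariate thresholds that also
define the planted zone map — the 3800-m seamount contour and the
spatial-mean nodule abundance — so that zone 1 (seamount), zone 2
(nodule-rich plain) and zone 3 (low-nodule plain/trough) carry three
distinct community profiles.  Getting the Calinski criterion to select
exactly k = 3 on the *predicted* surfaces constrains the design in
non-obvious ways, and the following choices are deliberate:

- responses are steep (20 log-odds per SD) but individual members turn
  on at staggered positions around the threshold (community turnover
  rather than a knife edge);
- group maxima are moderate (0.6–0.7), so per-image Bernoulli sampling
  noise propagates into the fitted surfaces;
- every member carries weak idiosyncratic responses (±3.5 log-odds per
  SD on two randomly chosen covariates, weighted toward fine-scale BPI),
  which gives each zone's point cloud substantial dispersion in many
  directions at once.

Without that within-zone dispersion the probability surfaces are
piecewise-constant, the only within-cluster variance lives in thin
boundary turnover bands, and the variance-ratio criterion keeps
improving as k-means splits those bands out — CH then increases
monotonically in k.  With it, the three between-zone separations
dominate and CH peaks at 3; in repeated runs across seeds the pipeline
selects k = 3 and recovers the planted zones with adjusted Rand index
0.88–0.97.

### What the generator does not emulate

Spatial autocorrelation of occurrences beyond what the covariates
induce; observation error in morphotype identification; the split
between identifiable and unidentifiable specimens; temporal dynamics;
larval dispersal; and realistic effect sizes (niche coefficients are
chosen for testability — strong, recoverable signals — not estimated
from any survey).  Passing tests therefore demonstrate that the
pipeline's machinery is correct and that planted structure of the
assumed form is recovered; they say nothing about how sharp community
boundaries are in real nodule provinces.

## Numerical choices and degenerate inputs

- Depth is stored positive-down; terrain operators convert to elevation
  internally, and BPI is reported in metres with positive = locally
  elevated.
- Slope/aspect/BPI are nodata at boundary or nodata-adjacent cells; BPI
  requires a radius of at least one cell.
- `resample` refuses to upsample; an all-nodata target block is nodata.
- Allocation rounding is nearest-integer-ties-up; the anchor stratum
  always contributes its full availability.
- A single-class response (all-presence or all-absence) skips that
  morphotype with a logged failure rather than aborting the stack.
- CH is +∞ when W = 0 (e.g. two distinct singletons); k-means ties
  break on lowest within-cluster sum of squares via the multi-start
  machinery, and cascade ties on the smallest k.
- The permutation p-value uses the add-one convention, so its floor is
  1/(n_perm + 1); with 999 permutations and three Bonferroni-adjusted
  pairs the attainable floor is exactly 0.003.
- PERMANOVA with zero within- and between-group dispersion raises a
  degenerate-data error; zero within-group dispersion alone gives
  pseudo-F = +∞.

## Problem sizes

The bundled tests and the acceptance script run entirely on synthetic
data at desk scale: seascapes up to 150 × 250 cells (the scale used for
the three-zone recovery benchmark, with 39 morphotypes and a 2000-image
survey), 5000-image surveys for density calibration checks, and
PERMANOVA on a few hundred observations with 999 permutations.  These
sizes were chosen so every stage, including the 500-tree forests, runs
in minutes on a single CPU while keeping the statistical behaviour
(prevalence boundaries, permutation floors, CH selection) at the regimes
the pipeline targets.
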