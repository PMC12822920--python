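# Methods

## The problem

Livestock censuses report animal counts per administrative unit
(municipality), but epidemiological and land-use questions need densities on
a fine, regular grid. `herdgrid` implements a dasymetric (census
disaggregation) workflow for small territories: municipal counts are turned
into a per-municipality density response, machine-learning models relate
that response to gridded environmental predictors, and predictions are
post-processed back into maps whose totals honour the census.

The analysis grid uses square pixels (225 m by default, 5.0625 ha) in one
projected CRS; row 0 is the northernmost row, pixel (0, 0) hangs from the
upper-left origin, and pixel extents are half-open so every point belongs to
exactly one pixel. No reprojection is performed: all inputs must share the
CRS. A missing-value sentinel (-9999) propagates through raster operations.

## Response preparation

**Urban redistribution.** Census counts attach animals to the breeder's
residence. Where breeders live in towns but keep animals in surrounding
countryside, urban municipalities show spuriously high counts. For each
municipality flagged urban (an explicit input column), its count C_c is
reallocated to its non-urban neighbours i proportionally to shared-border
length L_ci:

    C*_i = C_i + C_c · L_ci / Σ_j L_cj ,   C*_c = 0.

Ratios are applied exactly, with no intermediate rounding, so the territory
total is conserved to machine precision. Two adjacent urban municipalities
do not exchange animals; an urban municipality with no non-urban neighbour
is an error. Fractional adjusted counts are kept because densities are the
downstream quantity.

**Suitability mask.** Land-cover polygons are reclassified by a user table
into suitable/unsuitable; a pixel is suitable when it shares positive-area
overlap with at least one suitable polygon and with no exclusion polygon
(exclusion always wins). Boundary-only contact does not count — this keeps
pixel-aligned polygons from leaking suitability into edge-adjacent pixels.
Pixels belong to the municipality containing their centre (an unambiguous
partition; multi-municipality pixels are not split).

**Density.** adjusted_density_i = C*_i / suitable_area_i in head/ha, where
suitable area is the summed area of a municipality's suitable pixels. A
positive count with zero suitable area is an error.

**Moran's I.** Spatial autocorrelation of municipal densities is quantified
with global Moran's I under row-standardised binary contiguity weights
(contiguity = shared border of positive length) and a two-sided permutation
test, p = (1 + #{|I_perm| ≥ |I_obs|}) / (1 + n_perm), default 999
permutations, seeded. Municipalities with no neighbour are excluded and
recorded in the result. The null expectation is −1/(n−1).

## Predictors

The full stack holds 57 layers:

* **Topographic (3)** — the DEM itself, slope in degrees (Horn's 3×3
  finite-difference method, edges replicated), and the terrain ruggedness
  index (Riley's root-sum-of-squares of the 8 neighbour elevation
  differences).
* **Land cover (10)** — per-class fraction of pixel area covered, in [0, 1],
  by exact polygon-pixel clipping. Fractions (not presence flags) keep the
  layers continuous at coarse resolutions.
* **Distance (4)** — Euclidean distance (m) from pixel centres to the
  nearest barn, pond, road and river feature.
* **Temporal Fourier (4 × 10)** — each environmental series (NDVI, EVI,
  day/night land-surface temperature) is summarised by harmonic regression

      y(t) ≈ a0 + Σ_{k=1..3} A_k cos(2πkt/P) + B_k sin(2πkt/P),  P = 365.25 d,

  fitted by least squares so irregular timestamps are handled. The ten
  metrics per index are the mean (a0), annual minimum and maximum (extremes
  of the reconstructed annual cycle sampled daily; a `raw` switch uses the
  raw-series extremes instead), the raw-series SD, and amplitude
  A_k = √(A_k²+B_k²) and phase φ_k = atan2(B_k, A_k) ∈ (−π, π] of the
  annual, biannual and triannual cycles. At least 12 observations per pixel
  are required.

The reduced predictor set ("model II", 45 layers) drops everything derived
from a high-resolution land-cover product — the 10 class fractions plus barn
and pond distances — for territories without such data.

Spearman rank correlations (average-rank ties) are computed between
predictor pairs on pixel values and between municipal predictor means and
adjusted densities, as a screening diagnostic; constant predictors are
reported as missing.

## Sampling strategies

* **Average** — one sample per municipality: the mean of each predictor over
  the municipality's pixels, response = adjusted density, placed at the
  polygon centroid (a single representative location so the geographical
  model can consume both strategies uniformly). Deterministic; run once.
* **Random** — round(area_ha × d / 10 000) points per municipality at
  density d = 50 points per 10 000 ha, placed uniformly by seeded rejection
  sampling. Each point reads its pixel's predictors; its response is the
  municipal adjusted density on suitable pixels and 0 on unsuitable ones,
  which injects within-municipality heterogeneity. (A `suitable_only` flag
  restricts points to suitable pixels instead.) The count is a rounded
  expectation rather than a Poisson draw so sample size is a deterministic
  function of geometry.

Replicate r of either strategy uses seed base_seed + r; the average strategy
reuses its single deterministic sample across replicates while model seeds
differ.

## Models

Hyperparameters follow size-driven rules: ntree = max(100, ⌊n/20⌋),
node size = max(3, ⌊n/1000⌋) (mapped to the minimum node size eligible for
further splitting), mtry = min(p, max(3, ⌊p/3⌋)).

The **global model** is an ordinary regression forest (scikit-learn
`RandomForestRegressor`), seeded, with out-of-bag (OOB) predictions
reconstructed from each tree's bootstrap draw (the reconstruction is
verified against the library's own OOB output in the test suite).

The **geographical random forest** adds one local forest per training
location, fitted on that location's K nearest training samples (Euclidean
distance, self included, distance ties broken on the lower sample index).
K — the adaptive-kernel bandwidth — is tuned by a five-step grid search over
evenly spaced integers in [⌈n/3⌉, ⌊2n/3⌋]; each candidate is scored by
r² = 1 − SS_res/SS_tot between observed responses and blended
training-point predictions (OOB for the global part, each point's own local
forest for the local part — OOB limits optimism); ties keep the smallest
bandwidth. Predictions blend the global forest with the local forest whose
centre is nearest the pixel centre:

    ŷ(s) = w_g · f_global(x(s)) + w_l · f_local,nearest(s)(x(s)),

with default weights w_g = 0.75, w_l = 0.25. Nearest-centre assignment (not
distance-weighted blending) matches the reference behaviour of
geographical-forest implementations. With w_g = 1 the GRF map is
bit-identical to the plain forest's. Forest averaging bounds predictions by
the training response range, which is the mechanism behind the familiar
regression-to-the-mean pattern of census downscaling (overestimating sparse,
underestimating dense municipalities).

**Permutation variable importance** is the mean increase in global-forest
OOB mean squared error after permuting one predictor column, averaged over 5
seeded repeats, reported with a standard error and sorted descending.

## Validation and map products

Density maps (head/ha, 0 on unsuitable pixels) are converted to counts
(× 5.0625 ha), aggregated to municipalities by pixel-centre membership, and
scored against the redistributed counts C* by RMSE and Pearson correlation
(the training response derives from C*, so C* is the honest reference).
Min-max standardisation to [0, 1] is provided for cross-method comparison
plots. Per-replicate maps are ensembled into per-pixel mean and population
SD; the mean map is rescaled so its total equals the census total:

    X_i = C · x_i / Σ_j x_j ,

which conserves C to 1e-6 relative and leaves zero pixels at zero
(per-replicate adjustment is available behind a flag). Goodness-of-fit
distributions across the 2×2×2 factorial (sampling × model × predictor set)
are compared by one-way ANOVA with Tukey HSD; the compact letter display is
derived from the maximal cliques of the "not significantly different" graph,
so two combinations share a letter exactly when Tukey does not separate
them at α = 0.05. Bandwidth search runs once per sampling-strategy ×
predictor-set cell (on the first replicate's training set), not per
replicate.

## Synthetic archipelago

The generator builds a ground-truthed study area so every stage is testable
without confidential census data:

* a true density surface: a Gaussian random field with exponential
  covariance exp(−d/range), simulated by circulant embedding (cheap,
  controllable autocorrelation), min-max rescaled to [0, 0.65] head/ha — a
  realistic municipal-density span for extensive cattle systems on small
  tropical islands; default range 6 750 m on a 100×100 grid of 225 m pixels;
* a Voronoi tessellation into municipalities (default 16) from
  well-separated seed points;
* a 10-class land cover assigned per pixel from a blend of the density rank
  (weight 0.6) and an independent noise-field rank, the five highest-score
  classes being suitable — so roughly half the territory is suitable and
  suitability co-varies with density, as pasture does in reality;
* urban municipalities (default fraction 0.15, kept mutually non-adjacent)
  are fully unsuitable — their polygons double as exclusion zones — and
  their census count is assembled by taking heads from each rural neighbour
  proportionally to shared-border length (the exact inverse of the
  redistribution rule, up to integer rounding), with uptake intensity 0.5;
* predictors with known informativeness: NDVI mean is a strong monotone
  transform of the density field, the DEM is negatively associated, barns
  cluster in high-density pixels, while EVI, ponds, roads, rivers and the
  temperature fields are driven by independent noise — so the true
  variable-importance ranking is known by construction;
* seasonal series (5 years × 46 observations) with known harmonic
  amplitudes and phases plus small observation noise, stored in the scene
  for recovery tests;
* municipal true counts equal to the rounded integral of density over each
  municipality's suitable pixels.

Everything derives from one `numpy` generator, so a seed reproduces a scene
bit-identically.

What the generator does **not** emulate: measurement error in the census
itself, within-municipality reporting bias other than the urban artefact,
anisotropic or non-stationary spatial structure, correlated predictor noise,
cloud-gap patterns in satellite series, and real land-cover geometry
(classes are pixel-aligned). Passing tests therefore demonstrate that the
algorithms recover known structure under idealised but non-trivial
conditions, not that any real territory meets the model's assumptions.

## Problem sizes and numerical choices

The recovery experiment in the test suite uses the default conditions (16
municipalities, 100×100 grid, full 57-layer stack) with 10 replicates per
combination and a single predictor set — sizes chosen to exercise every code
path, including the five-step bandwidth search, at desk scale. Tie-breaks
are deterministic everywhere (stable sorts, first-index argmin/argmax);
population (divide-by-n) SD is used for ensembles and raw-series SD;
permutation tests and all samplers take explicit seeds. Degenerate inputs
fail loudly: constant responses in r², constant values in Moran's I or
min-max standardisation, unmapped land-cover classes, animals with zero
suitable area.

## Known limitations

* The local-forest registry makes GRF training O(n) forest fits;
  bandwidth search multiplies this by five. Fine at municipal scales
  (hundreds of training points), costly beyond.
* Rasters are in-memory numpy arrays; territories far larger than ~10⁷
  pixels would need tiling.
* ASCII-grid raster I/O stores no CRS; the CRS identifier is metadata the
  caller must supply consistently.
* Responses of random-sampling points are municipal constants (zeroed on
  unsuitable pixels), not pixel truths — the method's core approximation,
  inherited from the census-disaggregation setting itself.
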