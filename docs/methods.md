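# Methods

This note documents the models implemented in `heatrisk`, the choices made
where the methodology is genuinely open, and what the synthetic test bed
does and does not demonstrate.

## Risk index

The index follows the risk-triangle decomposition: risk exists where a
hazard, a vulnerable population and an exposed population coincide, so the
three assessments are multiplied rather than added —

    HHR = H × S × E

— and a cell with any component near zero is low-risk regardless of the
others. H is normalised nighttime LST; S and E are convex combinations of
their categories' normalised indicators. The raw product is min-max
rescaled to [0, 1] per assessment year. Per-year rescaling makes each
year's map span the full scale (each assessment stands on its own); a
joint rescaling across years would instead preserve absolute
comparability, and is a one-line change in `compute_hhr` callers, but is
not the default.

Normalisation maps every indicator onto [0.01, 1.01] with the direction of
the mapping encoding whether the indicator raises risk (LST, elderly
share, population density, unemployment, female share, agricultural and
construction practitioners) or protects (GDP, income, physicians, beds,
NDVI, water resources). The 0.01 offset keeps the product strictly
positive so no single indicator can zero out a cell. A constant layer is
rejected rather than silently mapped, since the formula's denominator
vanishes.

Nodata policy: the index is undefined wherever any of the 13 layers is
missing; masks propagate by union, and masked cells are excluded from
every minimum, maximum, statistic and classification.

## PCA weighting

Weights cover the 12 social-vulnerability and exposure indicators; the
single hazard indicator enters the index directly. PCA is run on the
correlation matrix of pooled unmasked cells from all years (thinned on a
regular stride, cap 50 000 per year, configurable), with components
retained by the eigenvalue > 1 rule. The loading-to-score-coefficient
conversion is

    b_ij = |a_ij| / sqrt(X_j),

the standard rescaling of a loading back to a unit-variance component
score weight. This conversion circulates in the applied literature in
ambiguous typeset forms; the absolute value is used because published
weight tables of this method contain no negative weights — directional information is already carried
by the normalisation step, so a weight only measures importance. The
alternative reading `a_ij / X_j` is available via the
`weights.b_formula: a_over_x` config key. Raw weights are the
contribution-weighted average of b_ij over retained components and are
renormalised to sum to 1 *within each category*, making S and E convex
combinations on the same [0.01, 1.01] scale.

Adequacy is checked before weighting: the Kaiser-Meyer-Olkin statistic
(from the inverse-correlation partial correlations) should exceed ~0.7 and
Bartlett's sphericity test (χ² = −(n−1−(2p+5)/6)·ln det R, df = p(p−1)/2)
should reject. No factor rotation is applied: the unrotated solution is
the reproducible default, and rotation would not change the eigenvalues or
contributions that drive the weights, only redistribute loadings.

## Classification

Jenks natural breaks are computed as the exact dynamic-programming optimum
of within-class sum of squared deviations — not the common heuristic — and
verified in tests against exhaustive search. Breaks are fitted once on the
baseline-year HHR and frozen, so later years and forecasts are graded
against a single standard and level shares are comparable across dates.
For surfaces with more than ~4 000 valid cells the break search runs on an
evenly thinned sample of the sorted values (deterministic, configurable
cap); the thinning preserves the empirical distribution and keeps the DP
quadratic cost bounded. Binning is half-open, [lower, upper): a value
exactly on a break belongs to the class above. The published five-level
grading standard (0.2/0.4/0.5/0.58) can be supplied through
`breaks: {mode: fixed}` for replication work.

Dominance subzones: within high + highest cells, H, S and E are each
min-max rescaled over that domain and a cell is attributed to the argmax.
"Leading component" has no canonical definition in this literature; the
rescaling puts the three components on a common scale so the argmax is not
an artefact of their different spreads. Ties resolve in the fixed order
hazard > social vulnerability > exposure.

## CA-Markov

The transition matrix P is the row-normalised cross-tabulation of two
dated class maps; empty rows become identity rows. Aggregate demand is
the Markov projection S_{t+1} = S_t P; cell counts are matched to demand
by largest-remainder rounding so totals are conserved exactly.

Spatial allocation, per iteration (default 10, one per simulated year):

1. demand = current areas × (I + (P − I)/iterations); the final iteration
   instead enforces the exact full-period demand S₀P. Linear
   interpolation is used because the p-th root of a stochastic matrix does
   not always exist (or is not stochastic); the interpolant is always a
   valid transition matrix and reproduces the annual-cycle behaviour.
2. a suitability atlas is rebuilt from the current map: suitability of
   class k at a cell is the fraction of valid cells of class k in the 5×5
   Moore window (centre included, edge-truncated, masked cells excluded
   from numerator and denominator).
3. a cell's score for class k is suitability_k × P[current, k], plus a
   seeded 1e-9 uniform jitter that breaks ties reproducibly.
4. cells are reassigned greedily in global score order until each class
   demand is filled. This is a deliberate simplification of IDRISI-style
   multi-objective land allocation; it is orders of magnitude simpler and,
   on the synthetic bed, conserves demand to machine precision while
   producing spatially coherent maps (tested against random allocations
   with identical class counts).

Masked cells never change class and contribute no demand. The forecast
assumes stationarity of P — the same assumption the underlying
methodology makes — and inherits its weaknesses where trends accelerate.

## Validation

Cohen's kappa is computed from the pairwise-valid confusion matrix. The
significance test uses the large-sample variance of kappa under the
independence null,

    var₀ = [p_e + p_e² − Σ_i r_i c_i (r_i + c_i)] / (n (1 − p_e)²),

with a two-sided normal p-value. n here is the number of jointly valid
cells, which are spatially autocorrelated, so the p-value is anti-
conservative and should be read as a screening statistic — the kappa value
itself, and its stability across CA iteration counts (the robustness
sweep), carry the substantive conclusion.

## Synthetic test bed

The generator emulates the structure the pipeline needs, not any real
geography: an elliptical study boundary; a smooth urbanisation field
peaking at a few seeded cores; mountain and water subregions placed by
ranked smooth scores away from the cores (realised fractions exact up to
cell counts); and 13 indicators driven by a shared latent urbanisation
factor with indicator-specific smooth fields and white noise. Signed
primary loadings follow each indicator's risk direction, so protective
indicators anticorrelate with urbanisation and composite risk concentrates
in the cores. Roughly half the stochastic variance persists across years
and the warming/densification drift (LST, population density;
0.02 sd/year) scales with urbanisation so it survives min-max
normalisation; this yields year-to-year class transitions almost entirely
between adjacent levels. Ground truth (loadings, fractions, transition
matrices) is returned with every product so tests are self-validating, and
all randomness flows from `numpy.random.default_rng` seeded by the
scenario.

What passing tests show: the estimators recover known structure
(transition matrices to ±0.02 on a 200² lattice, weight ranks with
Spearman > 0.8, hindcasts that beat shuffled baselines in ≥9/10
replicates) under clean, stationary, single-factor conditions. What they
do not show: behaviour under the messiness of real data — non-stationary
trends, census-unit blockiness, registration error, heavy-tailed
indicators, or multiple competing latent factors. The one-factor design
also means KMO on synthetic data (~0.98) is higher, and the retained
component count lower, than a real multi-factor indicator system would
produce.

## Problem sizes and numerics

Default scenario: 128×128 cells (1 km), three years, ~12 000 valid cells;
the full chain including the robustness sweep runs in a few seconds.
Jenks sampling cap 4 000; PCA observation cap 50 000 per year; CA filter
5×5; 10 iterations. GeoTIFF I/O writes float32 with the GDAL nodata tag
(sentinel −9999) and ModelPixelScale/ModelTiepoint georeferencing; ESRI
ASCII grids round-trip at full double precision. No reprojection is
performed — layers must share a `crs_tag`, mirroring workflows where
projection happens in GIS software upstream.

## Known limitations

- Uniform fill is the only admin-table rasterisation rule (no dasymetric
  refinement).
- Suitability is derived from the class maps alone; no covariate-driven
  (elevation, land-use) suitability.
- No kappa decompositions (location vs quantity) and no non-stationary
  transition modelling.
- The greedy allocator can, in principle, strand low-score cells in rare
  classes; with five classes and diagonal-dominant P this was not observed
  on the synthetic bed.
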