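# Methods

This note documents the models, conventions and numerical choices behind
`landconnect`, in the spirit of the methods sections of simulation and
statistics packages: what is computed, under which assumptions, which
knobs matter, and what the synthetic experiments do and do not show.

## Genetic distance and the population graph

Genotypes are unordered diploid allele pairs per locus; 0 is the
reserved missing code. The missing-data filter removes individuals whose
missing fraction of *allele calls* (denominator 2 × n_loci, not loci)
strictly exceeds the threshold (default 0.35) — an individual at exactly
35.0% is retained. The filter is idempotent and logs removals per site;
a site emptied by it is dropped with a warning.

The multivariate encoding assigns each observed (locus, allele) a column
holding the allele's within-individual frequency (0, 0.5, 1), so each
scored locus's columns sum to one and column means over a site equal the
site's sample allele frequencies. A missing locus is imputed with the
individual's site mean for those columns (overall mean if the whole site
lacks the locus), which leaves site centroids unbiased.

Among-site covariance is computed from grand-centered site centroids,
C = X_c X_c' / (p − 1) with p the number of allele columns, and distances
follow D_ij = C_ii + C_jj − 2 C_ij (asserted on every build to 1e-10).
Because the centered centroid rows sum to zero, **C always has a null
direction** (rank ≤ k − 1 for k sites). The pruning step therefore
derives partial correlations from an eigen-truncated pseudoinverse of
the correlation matrix: eigenvalues below 1e-10 × the largest are
treated as exact zeros. A plain inverse (or a tiny ridge) would pin all
partial correlations at ±1 and retain every edge; the truncated inverse
reduces to the ordinary inverse on full-rank input. Edge-exclusion
deviance −N ln(1 − r²) is compared to χ²₁(1 − α), α = 0.05 by default,
with N the post-filter number of individuals; decisions for all C(k,2)
pairs are recorded. Pruning is monotone in α by construction.

One caution validated during development: a site whose allele pool is an
*average* of two others is a collider, and conditioning on it induces a
strong negative partial correlation between the two parents — it does
not make their edge prunable. Conditional independence (and hence
pruning) arises along chains: if site B is a drifted copy of A, and C a
drifted copy of B, the A–C edge is pruned.

cGD is the all-pairs shortest path on the pruned graph with edge weights
as lengths; unreachable pairs are reported as infinite, never imputed.
Node connectivity defaults to the mean of 1/w over *incident retained
edges* (an all-pairs 1/cGD variant is available behind a flag); species
z-scoring uses the sample SD. Zero distances between distinct sites are
clamped to 1e-9 × max(D) with a warning.

## The lattice circuit

Cells are nodes; 4-neighbor connectivity is the default (8-neighbor
optional, diagonal resistance scaled by √2). Edge resistance is the
arithmetic mean of the two cell costs — the standard raster-circuit
convention; users wanting mean-conductance averaging can preprocess the
raster. Cell current density is half the sum of absolute currents on
incident resistors (terminal cells included), which makes a 1×3 chain
carrying 1 A read exactly (0.5, 1.0, 0.5).

Solves use a sparse LU factorization of the component Laplacian with one
node grounded by row/column deletion, cached per connected component and
reused across source/ground pairs; this is exact to machine precision
and far cheaper than iterative solves for the many-pair omnidirectional
and neighborhood workloads. Every solve is verified against the
component Laplacian at a 1e-8 relative-residual gate. Pairwise effective
resistance among m terminals uses m solves and the quadratic-form
identity R(a,b) = (e_a − e_b)' L_g⁻¹ (e_a − e_b). Terminals in different
components are an error, not a silent infinity. A configurable cell
count guard (default 4×10⁶) rejects rasters that would need tiling,
which is out of scope.

Omnidirectional maps pad the raster with a uniform buffer (default cost:
the mean study-area cost — a neutral medium that does not bias
perimeter injection), draw source/ground pairs without replacement from
the outer perimeter ring with members at least 90° apart around the
boundary (avoiding short circuits along the pad), average the per-pair
densities, clip the pad, and subtract the study-area mean so the
surface is mean-zero; the raw mean is retained. The default of 64 pairs
makes a uniform raster's interior flat to a few percent CV; the pair
count is a config because the source analyses do not fix one.

The neighborhood diagnostic masks a circle of the given radius, places 5
focal nodes equidistant (72°) on the circle of radius (radius − inset),
inset 300 m by default to keep terminals off the ragged clipped
boundary, with the starting angle drawn from the run seed. Effective
resistance is averaged over the 5 next-nearest pairs (i, i+2 mod 5) and
current density over the mask from the same five solves; a flag samples
a precomputed omnidirectional map instead. Focal points landing on
NoData are nudged to the nearest valid cell of the largest component.
Rotational symmetry on a uniform circle holds only up to lattice
discretization (~1 cell / radius, i.e. a few percent at desk scales).

## Covariates and inference

Buffer statistics use center-in-circle membership over non-NoData cells
and the population SD (the buffer is the full population of cells, not a
sample); truncation by the raster edge is flagged. The three extents are
interpreted as *radii* (6, 20, 120 km at full scale) — an `as_diameter`
switch halves them for users who read the extents as diameters.

PCA is an eigendecomposition of the covariate correlation matrix;
loadings are sign-fixed so each column's largest-magnitude element is
positive (the data-dependent signs of any particular study are not
recoverable); retention is "first 4" or "cumulative ≥ 85%" by rule.
OLS standardizes response and predictors within the modelled subset so
slopes are comparable standardized effects; confidence intervals use the
t(df) quantile rather than 1.96 because node counts are small. "X, Y"
are projected node coordinates (the analysis operates on a projected
raster). North/south subsets are configurable species lists. No
multiple-testing correction is applied. A rank-deficient design is an
error naming the collinear columns — note that a constant sample size
across sites will trigger this, since its z-score is degenerate.

## The synthetic generator

Landscapes are thresholded smoothed Gaussian noise: white noise smoothed
with a Gaussian kernel of scale `clustering` (cells) and cut at
quantiles, so realized class fractions are exact to one cell at any
autocorrelation. `habitat_fraction` goes to cost 10; the remainder is
split between 100 and 1000 by `semi_fraction` (default an even split —
no empirical class mixture is available to copy).

Genotypes follow Dirichlet drift: per locus, ancestral frequencies are
flat-Dirichlet; site i draws its frequencies from Dirichlet(c_i × p)
with concentration c_i = 1 / (drift_scale × mean effective resistance
from site i to all other sites, in ohms, computed on the landscape
circuit). Expected site differentiation is roughly 1/(1 + c_i), so with
typical desk-scale resistances of tens of ohms, drift_scale ≈ 0.01 gives
mild structure and ≈ 0.5 strong structure. The coupling constant is a
free knob: no quantitative gene-flow/resistance relation exists to
calibrate it against, and it is documented as such. Sites are placed by
uniform rejection sampling with a minimum separation (10,000-attempt
cap); the full synthetic study restricts sites to habitat cells, because
field surveys sample animals where the species occurs, not uniformly
over the cost surface. Missing data are injected per allele call,
independently, at a rate below the filter threshold by default.

What the generator does *not* emulate: coalescent or forward-time
genealogies, mutation models, linkage, migration–drift equilibrium
dynamics, sex-biased dispersal, and real land-cover geometry. Passing
recovery tests therefore show that the pipeline's plumbing and sign
conventions are coherent under a known monotone resistance–divergence
coupling — not that the ecological effect sizes of any real system are
reproduced.

### A structural limit of the drift model

The stratified recovery experiment asks whether, in low-habitat
landscapes with strong drift, node connectivity declines with buffered
current density (the "southern" pattern reported for fragmented
regions). Under this generator the answer is no, and measurably so: the
current-loaded PC slope is centered at ~0 (mean +0.05 ± ns over 90
replicates; fraction negative ≈ 0.48). The reason is structural. Here
divergence is keyed to each site's mean effective resistance, and on an
omnidirectional map high-current sites are corridor sites — sites of
*low* resistance to the rest of the landscape — so if anything the
partial effect of current on connectivity comes out weakly positive.
The negative field pattern plausibly reflects processes this model does
not encode (e.g. reduced effective size or edge effects in pinch-point
populations). The corresponding acceptance test asserts the field
direction and is expected to fail; it is kept as an honest marker of the
model's limit rather than weakened. The companion null check does pass:
with drift_scale = 0, landscape and coordinate predictors exclude zero
at close to the nominal 5% (sample size is tallied separately — small
samples inflate genetic distances, a real effect even without drift,
which is exactly why it is a covariate).

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen to
keep nodes-per-parameter and buffer-to-extent ratios in the spirit of a
regional study: 41–64-cell grids at 100 m, 8–24 sites, 6–14 loci,
omnidirectional maps from 16–64 perimeter pairs with 4–8 buffer cells,
covariate radii 0.6–2.4 km, neighborhoods of 1.8 km radius, and 24–144
replicates per experiment. Full-scale defaults (6/20/120 km radii, 64
pairs) remain the config defaults for real rasters.

## Known limitations

- ESRI ASCII grid is the only raster format; coordinate systems are
  carried as free-text tags and never reprojected.
- Very large rasters require external tiling; the cell-count guard
  refuses them.
- The node-based responses of neighboring sites share edges, so OLS
  standard errors are mildly optimistic; interpret marginal CI flags
  accordingly (the null-simulation check quantifies this at ~nominal
  rates for landscape predictors at desk scale).
- Genepop import assumes 2- or 3-digit allele codes and assigns
  block-order site labels (`Pop1`, `Pop2`, ...); coordinates must come
  from a sidecar CSV.
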