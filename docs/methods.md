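# Methods

## Model

For a gene set with expression rows \(X_1,\dots,X_g\) over \(L\) cells
at planar coordinates \((u,v)\) and a continuous per-cell phenotype
\(Y\), the local model at calibration location \(l\) is the univariate
regression of \(Y\) on the linear score \(Z = \beta'X\), fitted under
kernel weights centred at \(l\).  Only the direction \(\beta\) is
identified (any scale can be absorbed into the regression slope), so
\(\beta^*\) is reported with unit Euclidean norm and first nonzero
component positive.  The local association statistic is

ρ_l = sqrt( s_xy' Σ*⁻¹ s_xy / s_yy ),

where Σ* is the kernel-weighted shrunken covariance of the set's genes
and s_xy, s_yy the weighted phenotype cross-moments, and β* ∝ Σ*⁻¹ s_xy
is the principal eigenvector of the rank-one matrix Σ*⁻¹ s_xy s_xy'.
Every cell is a calibration location.

### Weighted moments

Kernel weights are renormalized to sum to the number m of
positive-weight cells and covariance sums use an (m − 1) denominator,
so with uniform weights every estimator reduces *exactly* to its
textbook sample counterpart.  This makes the aspatial limit exact: as
the bandwidth grows, every local statistic converges to the global LCT
statistic (verified to ~1e−9 at bandwidth 10⁴ × the data diameter).
The statistic is invariant to the overall scale of the weight vector,
to affine rescaling of Y, and to per-gene affine rescaling of X.

### Shrinkage

Σ* is formed on the correlation scale: the weighted correlation matrix
R is shrunk toward the identity, R* = (1 − λ)R + λI, and rescaled by
the weighted standard deviations (floored at 1e−12 so constant genes
cannot produce a singular scale).  The intensity λ is the analytic
Schäfer–Strimmer estimate Σ V̂ar(r_ij)/Σ r_ij² over off-diagonal pairs,
computed with weighted moments (the unweighted case recovers the
standard n/(n−1)³ formulas) and clipped to [0, 1].  R* is positive
definite for any λ > 0, which the estimator guarantees whenever the
data are not exactly noise-free.

### The range of ρ

Without shrinkage and with at least as many effective observations as
genes, ρ is the maximal weighted correlation between Y and a linear
score of the set, hence lies in [0, 1].  In the overparameterized
regime — set size comparable to or larger than the kernel window, which
is the routine situation for ~50–100-gene sets and 6–20-neighbour
adaptive bandwidths — the unregularized maximum is trivially 1 and the
shrunken statistic is a regularized association score that can exceed
1.  We deliberately do **not** clip it: clipping would collapse
observed and permuted values onto a single tied atom at 1 and destroy
the permutation test entirely in precisely the regime the method is
designed for.  Because inference is by permutation rank, no
distributional calibration of ρ is required; ρ's absolute magnitude
should be read as a score, not a correlation, whenever it exceeds 1.

### Permutation inference

The phenotype vector is permuted across all cells, globally — the null
hypothesis is "no Y–gene-set association anywhere", and global
relabeling keeps the spatial structure of X intact while making cells
exchangeable in Y.  p = (1 + #{ρ_perm ≥ ρ_obs})/(1 + B), so p has
resolution 1/(B+1) and can never be 0.  Within a run, one sequence of
permutations is drawn per gene set and shared across locations, so a
set's spatial p-value map is computed against a common null sample.
The X-side factorization (weights, covariance, shrinkage, Cholesky) is
independent of Y and computed once per location, making the B
permutations a pair of BLAS calls; a 10×10-grid, 100-gene, B=199 run
takes well under a second.

Raw p-values are reported; `run_gwlct(..., adjust="bh")` adds a
Benjamini–Hochberg column across locations within each set for users
who want location-wise error control.  Degenerate locations (fewer than
two positive-weight cells) are flagged, not fatal.

## Bandwidth

Fixed mode takes a distance; adaptive mode takes a neighbour count k
and uses the k-th nearest-neighbour distance per location (the k-th
neighbour itself receives weight 0, the compact kernel's boundary).
Cross-validation minimizes the summed leave-one-out squared error of
the local Y-on-Z prediction over cells and gene sets; at a candidate
where fewer than g + 2 cells carry positive weight the pre-shrinkage
covariance would be rank-deficient, so the candidate scores +∞ there.
Ties select the smallest bandwidth (most local model).  Default kernel:
adaptive bisquare, k = 16; k is deliberately exposed rather than fixed,
and may itself be placed among the CV candidates.

## Combined significance, stratification, cluster scan

Fisher's method uses natural logarithms throughout (X² = −2Σ ln p_k ~
χ²(2K); CS = −ln CP), keeping CS on the same scale as X²; a base-10
display flag exists.  Per-location p-values share permutations and
overlapping genes, so CP is a descriptive enrichment summary — the map
is exploratory, and no calibrated family-wise claim is attached.
Phenotype stratification uses the marker-expression thresholds Low
< 0.5 ≤ Moderate ≤ 1 < High on the normalized scale.

The GAM scan lays circle centres on a regular grid over the bounding
box (default radius 10% of the box diagonal, spacing radius/2, flag
threshold 0.002 — all overridable, since no canonical values exist) and
compares each circle's observed count with E = (global mean count) ×
(locations covered) under a homogeneous Poisson null.  In classic GAM
fashion the overlapping circles are not multiplicity-corrected; the
flagged union is a display of where counts exceed the homogeneous
baseline, not a simultaneous test.

## Preprocessing

Order matters and is enforced: (1) keep genes with mean raw expression
strictly > 1; (2) replace exact zeros by uniform jitter in (−s, s) with
s = 1e−6 × the smallest nonzero magnitude (so no reordering of nonzero
values is possible); (3) per-gene rank-based inverse-normal transform
with Blom offsets.  Jittering first prevents the massive zero tie that
would otherwise distort the rank transform.  The transform is a single
deterministic member of the monotone-to-normal family; a
cross-validated choice among transform families is intentionally out of
scope.  Marker-gene phenotypes are excluded from every tested set by
default (a set containing its own phenotype is trivially significant);
a flag disables the guard.

## Simulator

Gaussian random fields follow the variogram C(d) = psill·ρ(d/range) +
nugget·1{d=0} with defaults (10, 3, 10) and an exponential correlation
family (Gaussian and spherical available).  Sampling is by exact
Cholesky factorization of the full covariance — exact at up to ~10⁴
points, with no kriging-neighbourhood approximation parameter.  Seeds
are split counter-style from the master seed per component and per
gene, so enlarging a simulation never perturbs earlier draws.

A scenario crosses six factors — adaptive neighbour count (6/20), grid
side (10/100), gene count (100/1000), Bernoulli membership probability
(0.3/0.9), and two association levels taking noise variances
{50, 5, 0.1} (larger variance = weaker association) — 144 cells in all.
Genes share a common unit-variance spatial field G plus independent
per-gene fields of variance v_gene, giving cross-gene correlation
1/(1 + v_gene) ≈ 0.91 / 0.17 / 0.02 at the three levels.  The phenotype
is the standardized mean of the designated true set plus an independent
spatial noise field of marginal variance v_pheno.  Power is the mean
over replicates of the per-replicate rejection measure at α = 0.05:
fraction of locations rejecting for the true set (GWLCT) or the 0/1
global rejection (aspatial LCT).  Two null modes drop the signal:
`null-iid` (iid normal phenotype — exchangeable cells, the null model
the permutation test actually assumes, used for type-I calibration) and
`null-spatial` (spatially correlated noise only, probing robustness to
autocorrelated-but-independent phenotypes).

Reduced problem sizes are the package defaults for the study harness:
10×10 grid, 100 genes, K = 2 sets, B = 99–199 permutations, 50–200
replicates.  These keep a full calibration run in seconds-to-minutes
while leaving the paper-scale values (100×100, 1000 genes, B = 500)
reachable through the same configuration objects.

## What the simulations do and do not show

The simulator emulates smooth, stationary, isotropic expression
surfaces with Gaussian marginals and a phenotype linked to the set mean
homogeneously across space.  Real tissue violates most of this: counts
are discrete and zero-inflated (the preprocessing chain, not the
simulator, addresses that), spatial structure is anisotropic and
nonstationary, and biological associations can be regional.  Passing
power and type-I checks on these fields validates the statistical
machinery, not performance on any particular tissue.  Two further
caveats:

* Because the simulated phenotype–set association is spatially
  homogeneous, the aspatial LCT — which pools all cells — is at least
  as powerful as the local test under this generator.  The local test's
  advantage materializes when associations are regional; this generator
  does not create such regimes, so no GWLCT-beats-LCT comparison is
  claimed from it.
* Under the `null-spatial` mode the phenotype is smooth but independent
  of expression; permutation tests can in principle be anticonservative
  against such nulls (smooth-vs-smooth chance correlation).  With the
  default variogram (half the variance in the nugget) and shrinkage,
  rejection stays near nominal here, but users mapping strongly
  autocorrelated phenotypes should treat borderline local p-values with
  care.

## Numerical choices

* Variance floor 1e−12 on weighted gene variances; Cholesky retry with
  1e−10 jitter (and 1e−8·sill for simulated covariances, relevant only
  for coincident points with zero nugget).
* Permutation count B sets the p-value grid; with B = 199 the smallest
  achievable p is 0.005 and "p < 0.05" corresponds to rank ≤ 9.
* Ties in permuted statistics count against rejection (≥ comparison).
* Adaptive bandwidth with duplicated coordinates can be 0; the weight
  vector then collapses to the duplicates and the location is flagged
  degenerate downstream rather than raising.
* Scan circles use closed discs (d ≤ r); membership at exact-boundary
  distances is float-sensitive, which matters only for lattice data
  with radii chosen on the lattice distance spectrum.

## Known limitations

Isotropic planar kernels only (no anisotropy, no per-covariate
bandwidths); univariate phenotype; Fisher combination treats dependent
p-values as independent (descriptive use); GAM scan reports
uncorrected exceedances; exact field simulation is O(n³) in the cell
count and practical to ~10⁴ points.
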