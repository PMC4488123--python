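# Methods

## Model

Coverage around L anchored windows is treated as a sample of random
functions x_1(t), …, x_L(t) on [a, b] (default [−5000, 5000) bp relative
to the anchor, transcription-oriented). The Karhunen–Loève theorem gives,
for the centered process, x_i(t) − μ(t) = Σ_k η_ik ξ_k(t) with
orthonormal eigenfunctions ξ_k of the covariance function
v(s,t) = Σ_k λ_k ξ_k(s) ξ_k(t), scores η_ik = ∫(x_i − μ)ξ_k that are
uncorrelated across components, and eigenvalues λ_k = var(η_k) sorted
decreasingly. The model assumes square-integrable profiles on a common
interval and identically-anchored windows; it makes no distributional
assumption beyond finite second moments (significance tests below add
a bivariate-normality working assumption for score pairs).

## Estimation

1. **Smoothing.** Each binned profile (G bins, default 10 bp → G = 1000)
   is expanded in K cubic B-splines (order 4, K = 50 by default) with
   equidistant interior knots, by ordinary least squares. One
   normal-equations Cholesky factorization is shared across regions.
   No roughness penalty is applied; with G ≫ K the basis itself is the
   smoother.
2. **Eigenproblem.** With Gram matrix W = ∫φφᵀ (computed exactly by
   per-knot-span Gauss–Legendre with `order` nodes, degree-exact for the
   piecewise-polynomial integrands), coefficient mean c̄ and covariance
   S_c (divisor L − 1), the functional eigenproblem reduces to the
   symmetric matrix problem R S_c Rᵀ = U Λ Uᵀ where W = RᵀR (Cholesky).
   Eigenfunction coefficients are B = R⁻¹U, so BᵀWB = I holds to machine
   precision; scores are the exact basis-algebra projections
   η_i = (c_i − c̄)ᵀ W B. Retaining J = K components conserves the total
   functional variance: Σλ_k = trace(W S_c).
3. **Sign convention.** Eigenfunction signs are intrinsically arbitrary.
   Each ξ_k is flipped, if needed, so that its value at the point of
   maximum |ξ_k| over 2001 equidistant grid points is positive, and the
   flip is propagated to the scores. This makes results reproducible
   across linear-algebra backends. For eigenfunctions whose positive and
   negative extrema have (near-)equal magnitude — e.g. symmetric cosine-
   like modes — the argmax is a near-tie and estimation noise can decide
   the sign; the sign of any single score-correlation entry is then only
   meaningful jointly with the eigenfunction pair, which is why the
   cross-dataset report always carries both coefficients.
4. **Centering.** Profiles are centered across regions (the mean
   function is estimated and removed); no per-region vertical centering
   is applied, so a region's overall level contributes to component 1.

## Cross-dataset coefficients

For decompositions A and B on the same interval, per component pair
(j, k):

* r_ξ[j,k]: Pearson correlation of ξ^A_j and ξ^B_k evaluated on a common
  1000-point equidistant grid (co-localization of variability);
* r_η[j,k]: Pearson correlation of the score vectors over regions
  matched by id (inner join; co-variation), with two-sided p-values from
  the t-distribution with n − 2 degrees of freedom.

Significance is Bonferroni-corrected within the J_A×J_B family of one
dataset pair (α = 10⁻⁶ by default, i.e. threshold α/(J_A·J_B)); no
correction is applied across dataset pairs. Summary records report the
maximum |r_ξ| over the first J_report (default 5) components together
with the r_η at the same component pair, and vice versa, with 1-based
component indices and row-major tie-breaking.

The **ordinary coverage correlation** baseline is the Pearson
correlation of the concatenated binned window values in genome
orientation (no minus-strand flip), mirroring the convention of
coverage-correlation utilities restricted to a region set. The
orientation asymmetry with the FPCA path (transcription-oriented) is
deliberate: the baseline emulates existing practice, the functional path
aligns biology.

## Genomic conventions

Coordinates are 0-based half-open. Anchors are single bases: BED start
for `+` features, end − 1 for `-` features. Windows are
[anchor − flank, anchor + flank); entries whose window leaves the
chromosome are dropped with a logged count, duplicate
(chrom, anchor, strand) triples keep the first entry. Uncovered bases
are zeros (bedGraph convention), not missing data. Tracks are normalized
by scaling to a target genome-wide total signal ("wigsum") of 10⁸.
Regions overlapping a blacklist interval by ≥ 1 bp are removed, as are
regions on an explicit exclusion list (e.g. a ribosomal-gene id list).

## Synthetic data

The generator plants the model directly: orthonormal eigenfunction sets
(Fourier modes, shifted Legendre polynomials, or Gaussian bumps,
Gram–Schmidt-orthonormalized under trapezoid quadrature on the bin-center
grid), per-component scores drawn from bivariate normals with variances
λ_k and cross-dataset correlations ρ_k, a constant baseline, and white
Gaussian observation noise per bin. Mark B's eigenfunctions can be
circularly shifted to create variability that co-varies without
co-localizing. Defaults are the standard study conditions: ±5 kb windows
at 10 bp bins, L = 1000 regions, three components with λ = (9, 4, 1),
noise sd 0.1, first-component cross-correlation 0.8, baseline 1.
Expression is linked to mark A's scores by
RPKM_i = softplus(Σ_k w_k η_ik + ε), default weights (0.3, 1.0, 0.0) so
that expression tracks a non-primary component most strongly; softplus
keeps values non-negative while preserving monotonicity.

`write_fixture_bundle` materializes a pair as plain-text files on a toy
two-chromosome genome (non-overlapping windows, alternating strands, two
regions designated for blacklist removal, one bedGraph interval per
bin). Writing uses 17-significant-digit floats and readers parse with
round-trip precision, so extraction reproduces planted values to < 1e-9
and identical seeds give byte-identical bundles.

What the generator does **not** emulate: read-level sampling noise
(counts, mappability, GC bias), heteroskedastic or spatially correlated
noise, overlapping windows, replicate structure, and realistic
eigenfunction shapes learned from data. Passing tests therefore
demonstrate correctness of the estimation and bookkeeping machinery
under the planted model, not robustness to every artifact of real
ChIP-seq data.

## Numerical choices

* White observation noise with per-bin sd σ inflates every score
  variance by the floor σ²·Δ (Δ = bin width), because projecting white
  noise onto any unit-norm function contributes that variance. Planted
  eigenvalues are therefore recovered as λ_k + σ²Δ, and an observable
  score correlation is attenuated by λ/(λ + σ²Δ). At the default
  conditions (σ = 0.1, Δ = 10) the floor is 0.1.
* Eigenvalues below −1e-10 abort; values in (−1e-10, 0) are clipped to
  zero (numerical floor of the symmetric eigensolver).
* Ties in eigenvalues are resolved by the symmetric solver's output
  order and then the sign convention; for exactly degenerate spectra the
  returned basis of the eigenspace is arbitrary.
* Quantile binning for expression contrasts uses equal-count bins with
  any remainder assigned to the lowest bins; score ties keep the fitted
  region order (stable sort).
* The quantile contrast's primary statistic is a Welch two-sample
  t-test between the lowest and highest bins. A rank-paired variant
  (pairing order statistics after truncation to equal length) is also
  reported; with skewed expression distributions it is more sensitive,
  and neither variant is claimed to be uniquely canonical, as a "paired"
  design between quantile groups is inherently ambiguous. Degenerate
  inputs (all values equal) report p = 1 by convention.
* Expression is used on its raw (RPKM) scale by default; a log2(x+1)
  option exists.

## Problem sizes

The test-suite and acceptance-script simulations use L between 500 and
2000 regions, G between 100 and 1000 bins, and K between 12 and 60 basis
functions — sizes at which every stage (OLS smoothing, K×K eigenproblem,
correlation matrices) is exact linear algebra and the planted-parameter
sampling error is small enough for tight assertion bands. The same code
paths scale linearly in L and G for genome-scale region sets.

## Known limitations

* Penalized/smoothed FPCA, sparse or irregular sampling designs,
  functional regression and functional canonical correlation are out of
  scope.
* bigWig input is expected to be converted to bedGraph upstream; the
  core consumes text formats only.
* The eigenfunction-sign convention can flip for near-symmetric modes
  (see above); cross-dataset comparisons should always read r_ξ and r_η
  together.
* Bonferroni across the component-pair family controls the family-wise
  error per dataset pair, not across a collection of dataset pairs.
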