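# epifpca

Functional principal component analysis (a finite Karhunen–Loève
transform) of genomic coverage profiles around anchored regions, with
component-wise cross-correlation of dataset pairs.

## The problem

Pearson correlation of raw coverage (e.g. between two histone-mark
ChIP-seq tracks at TSS-flanking windows) only detects signals that rise
and fall *in the same genomic intervals*. Two marks can be tightly
co-regulated while occupying different parts of the window — a promoter
mark peaking at the TSS and a gene-body mark rising downstream — and the
coverage correlation will sit near zero.

`epifpca` decomposes the per-region coverage profiles x_i(t), observed
on a window t ∈ [−flank, +flank) around each anchor (typically a TSS),
into the Karhunen–Loève expansion

    x_i(t) = μ(t) + Σ_k η_ik ξ_k(t),

where the ξ_k are orthonormal eigenfunctions of the covariance function
v(s,t) = Σ_k λ_k ξ_k(s) ξ_k(t), the scores η_ik = ∫ (x_i − μ) ξ_k are
uncorrelated across components, and var(η_k) = λ_1 ≥ λ_2 ≥ … . Profiles
are first smoothed by a least-squares expansion in K cubic B-splines with
equidistant knots; the eigenproblem is solved exactly in basis
coordinates through the Gram matrix W = ∫ φφᵀ (Cholesky-symmetrized, so
BᵀWB = I to machine precision).

For a pair of datasets A and B the package reports, per component pair
(j, k), two coefficients:

* **eigenfunction correlation** r(ξ^A_j, ξ^B_k) — do the two components'
  regions of variability co-localize?
* **score correlation** r(η^A_j, η^B_k) — do the two marks co-vary
  across regions, each in its own variability region?

A high score correlation with a negative eigenfunction correlation is
exactly the "correlated but not co-localized" relationship that the
ordinary coverage correlation misses. Score–expression association
(per-component correlation with RPKM values, quantile contrasts) is also
included.

## Worked example

Simulate a mark pair whose first components share score correlation 0.8
while mark B's eigenfunctions are shifted by half the window (planted
structure, ±5 kb windows, 10 bp bins), then decompose and correlate:

```python
import numpy as np
from epifpca import FunctionalPCA, SimulationSpec, simulate_mark_pair
from epifpca.crosscorr import (eigenfunction_correlation, score_correlation,
                               ordinary_profile_correlation, max_summary)

spec = SimulationSpec(L=2000, eigen_family="bumps", eigen_shift_B=5000,
                      cross_rho=(0.8, 0.0, 0.0), seed=42)
prof_a, prof_b, truth = simulate_mark_pair(spec)

fpca_a = FunctionalPCA(n_components=10, n_basis=50).fit(prof_a)
fpca_b = FunctionalPCA(n_components=10, n_basis=50).fit(prof_b)

print("variance explained (A, first 3):",
      np.round(fpca_a.explained_variance_ratio_[:3], 3))
r_eta, p_eta, n = score_correlation(fpca_a, fpca_b)
r_xi = eigenfunction_correlation(fpca_a, fpca_b)
max_xi, max_eta = max_summary(r_xi, r_eta, j_report=5)
print(f"score correlation (1,1):         {r_eta[0, 0]:+.3f}")
print(f"eigenfunction correlation (1,1): {r_xi[0, 0]:+.3f}")
print(f"ordinary coverage correlation:   "
      f"{ordinary_profile_correlation(prof_a, prof_b):+.3f}")
print(f"max |score corr| {max_eta.value:.3f} at components "
      f"{max_eta.components}")
```

Output:

```
variance explained (A, first 3): [0.468 0.223 0.06 ]
score correlation (1,1):         +0.787
eigenfunction correlation (1,1): -0.246
ordinary coverage correlation:   -0.000
max |score corr| 0.787 at components (1, 1)
```

The component-wise path recovers the planted co-variation (+0.79 ≈ 0.8,
mildly attenuated by observation noise) and flags that the variability
regions do **not** co-localize (negative eigenfunction correlation),
while the flat coverage correlation (−0.000) would have reported no
relationship at all.

`FunctionalPCA` follows the scikit-learn estimator conventions
(`fit`/`transform`, `get_params`, fitted attributes such as
`eigenvalues_`, `scores_`, `explained_variance_ratio_`), so it composes
with sklearn pipelines and model selection.

## Command line

The same workflow over on-disk tracks (bedGraph), BED6 anchor files,
BED3 blacklists and expression TSVs:

```sh
epifpca simulate --outdir bundle -L 1000 --seed 1
epifpca fit bundle/markA.bedGraph bundle/regions.bed \
    --chrom-sizes bundle/chrom.sizes --blacklist bundle/blacklist.bed \
    --out-dir fitA
epifpca fit bundle/markB.bedGraph bundle/regions.bed \
    --chrom-sizes bundle/chrom.sizes --blacklist bundle/blacklist.bed \
    --out-dir fitB
epifpca correlate fitA fitB --out-dir corr
epifpca expression fitA bundle/expression.tsv --out-dir expr
epifpca coverage-corr bundle/markA.bedGraph bundle/markB.bedGraph \
    bundle/regions.bed --chrom-sizes bundle/chrom.sizes --out cov.json
```

Tracks are wigsum-normalized to a total signal of 10⁸, windows are
±5 kb by default, minus-strand profiles are transcription-oriented, and
significance uses Bonferroni correction over the J_A×J_B component-pair
family at α = 10⁻⁶.

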