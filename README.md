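# dualeigen

Polarized SVD ("dual eigen-analysis") of islet gene-expression profiles,
with cross-species integration, rank-based enrichment, resampling
stability and islet morphometry.

## The problem

Type-2 diabetes studies produce expression profiles of pancreatic islets
from very different designs — a designed rodent time course (e.g.
Goto-Kakizaki vs Wistar rats over weeks 4–24, three replicates per cell)
and observational human cadaver-donor cohorts annotated with continuous
covariates such as HbA1c.  This package implements a matrix-decomposition
route to analyzing and integrating such profiles, for computational
biologists who want each step testable against planted ground truth.

## The method

Let `E` be the log-scale expression matrix with samples in rows
(`s × g`).  Its SVD is

```
E = Σ_{k=0}^{s-1} λ_k u_k v_kᵀ
```

with decreasing singular values `λ_k`, sample-eigenvectors `u_k` and dual
gene-eigenvectors `v_k`.  Component 0 is the **baseline**: after good
between-sample normalization its sample loadings are nearly constant,
`u_{0,i} ≅ 1/√s`, so by orthogonality every later component satisfies
`Σ_i u_{k,i} ≅ 0` — an **empirical contrast** defined by the data.  Each
contrast is interpreted jointly with its dual gene-eigenvector after
**polarization** (sign fixed so a designated reference group — the
disease-susceptible genotype, or abnormal-HbA1c donors — sits at the
positive pole).  The accounting identity
`SS_contrast^(1) = Σ_j (Σ_i u_{1,i} E^(1)_{i,j})² = λ_1²` with
`Σ_{k≥1} λ_k² = ‖E^(1)‖_F²` (after baseline removal
`E^(1) = E − λ_0 u_0 v_0ᵀ`) gives each contrast its explained share of
the sum of squares.

Around that core:

- **Enrichment** (`wilcoxon_score`, `enrich_catalog`): rank-sum scoring of
  gene sets on any ranked gene vector;
  `z = (W − m(N+1)/2)/√(m(N−m)(N+1)/12)`, exact enumeration for small
  sets, BH adjustment across a GMT catalog.
- **Stability** (`resample_stability`): SVD on random subsamples without
  replacement; sign-aligned correlation of each subsample gene-eigenvector
  with the full-data one, plus per-replicate re-scoring of tracked sets.
- **Robust Rank Aggregation** (`rra_rho`, `aggregate_eigenvectors`): a
  gene's normalized ranks `r_(1) ≤ … ≤ r_(m)` across species lists are
  scored by `ρ = min_j Beta(j, m−j+1).cdf(r_(j))` with the Bonferroni
  bound `p = min(1, m·ρ)`.
- **Unified SVD** (`concatenate`, `unified_dual_eigen`): per-species
  baseline removal, homolog alignment, optional Frobenius-norm
  equalization, concatenation over samples, decomposition, and per-species
  polarization/contrast tests of the partitioned sample-eigenvectors.
- **Normalization audit** (`pairwise_mode`, `normalize_mode_zero`): the
  mode of the density of per-gene log differences between two samples
  should sit at zero; a simple normalizer shifts each sample by the median
  mode against a reference set.
- **Islet morphometry** (`analyze_islet`, `paired_signed_rank`): convex
  hull of the insulin region, signed distances of glucagon pixels to the
  rim (positive inside), and the **irregularity index** — the trimmed mean
  of those distances: near zero for core-mantle islets, large when
  alpha-cells infiltrate the core.  Cohorts compare by exact Wilcoxon
  signed-rank.
- **Synthetic data** (`simulate_dual_species`, `simulate_islet_masks`):
  two species profiles sharing a planted program through a homolog map,
  with designed/observational sample patterns, baselines, shifts, noise,
  decoy gene sets and islet masks with tunable infiltration.

## Worked example

```python
import pandas as pd
import dualeigen as de

A, B, hmap, catalog, truth = de.simulate_dual_species(de.SyntheticConfig(seed=1))
decomp = de.decompose(A)
cv, _ = de.baseline_cv(decomp)                      # 0.62 %
ds = (A.metadata["group"] == "DS").values
pol = de.polarize(decomp, 1, ds)
p = de.contrast_test(pol.u, ds)                     # 1.29e-08
ss = de.sum_of_squares(decomp)
ss.top_proportion(2)                                # 0.498
table = de.enrich_catalog(pd.Series(pol.v, index=A.gene_ids), catalog)
```

The baseline CV of 0.62 % confirms the near-constant baseline loadings, so
component 1 is an empirical contrast; its rank-sum p of 1.3×10⁻⁸ shows the
contrast separates the two genotypes; the top two components explain
49.8 % of the contrast sum of squares; and the enrichment table puts the
planted up-program at the positive pole and the down-program at the
negative pole (both p ≈ 7×10⁻⁶⁶), with decoy sets far behind.  The
scripts in `examples/` walk through each capability — integration,
stability, normalization, stratification and morphometry — and print the
numbers above.

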