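# Methods

## Model and conventions

The expression matrix `E` is log-scale with samples in rows (`s × g`);
on-disk tables use the genes-as-rows dialect and are transposed on load.
The SVD `E = Σ_{k=0}^{s-1} λ_k u_k v_kᵀ` keeps only numerically non-zero
singular values (relative threshold 1e-12).  Signs are fixed
deterministically — the baseline pair so that `u_0` has positive mean,
every other pair so that the largest-magnitude gene loading is positive —
which flips `u_k` and `v_k` together and never changes any outer product.
Polarization may flip a pair once more so a designated reference group's
mean sample loading is positive; a reference mean of exactly zero keeps
the decomposition sign with a warning.

The baseline (index 0) component models per-gene/per-sample expression
baselines; its sample-loading coefficient of variation is the normalization
quality readout (well below 1 % on well-normalized data; the
`nearly_constant` flag uses a 2 % default threshold).  Because `u_0` is
nearly constant, each later `u_k` sums to approximately zero — an
empirical contrast — and `|Σ_i u_{k,i}|` is bounded by `√s · CV(u_0)`,
which the tests verify numerically.

Sum-of-squares accounting works on the baseline-removed matrix
`E^(1) = E − λ_0 u_0 v_0ᵀ`: per-gene induced squares
`SS_j^(1) = (u_1ᵀ E^(1)_{·,j})²` sum to `λ_1²`, and
`Σ_{k≥1} λ_k² = ‖E^(1)‖_F²`.  Component proportions are reported against
this contrast total (canonical) and against the baseline-included total,
since the former is the interpretable quantity once baselines are treated
as nuisance.

Unified two-species analysis removes each species' baseline *before*
concatenation, with the baseline recomputed on the homolog-restricted
matrix by default (a `baseline="genome-wide"` flag removes the full-gene
baseline first and restricts afterwards; at realistic scale the two agree
closely).  Frobenius-norm equalization divides each block by its norm so
both species contribute equal variation; the concatenated decomposition is
indexed from 1, as no baseline remains.

## Statistical tests

- Contrast test: Wilcoxon rank-sum on sample loadings; exact null (shift
  algorithm) for total n ≤ 50 without ties, otherwise normal approximation
  with continuity correction and average ranks.
- Enrichment: rank-sum of set members' positions among all `N` genes;
  `z = (W − m(N+1)/2)/√(m(N−m)(N+1)/12)` without tie correction (the score
  definition), two-sided p from `z`, exact enumeration when `m ≤ 10`,
  `N ≤ 30` and the values are tie-free.  Direction = sign of `z`
  (positive pole = high loadings).  Catalog-wide adjustment is
  Benjamini–Hochberg by default; the stability module deliberately uses
  raw p at α = 0.05 when tracking sets across replicates, since that
  matches how pathway stability fractions are defined.
- Robust Rank Aggregation: `ρ = min_j Beta(j, m−j+1).cdf(r_(j))` over
  ascending normalized ranks, `p = min(1, m·ρ)`.  The Bonferroni bound is
  conservative under the uniform null (verified by Monte-Carlo at 10⁵
  draws).  Per-pole aggregation: the up-list ranks homologs by loading
  descending in each species, the down-list ascending; ties break by gene
  id so outputs are deterministic.  Homolog-restricted ranks are canonical;
  full-genome ranks are emitted alongside.
- Paired cohort comparison: Wilcoxon signed-rank with zero differences
  dropped.  The exact null is enumerated by a subset-sum convolution over
  doubled tie-averaged ranks for n ≤ 25 (handles ties exactly, unlike the
  common no-ties-only exact implementations); beyond that, a normal
  approximation with tie-corrected variance and continuity correction.
  One-sided "diseased > control" is the default orientation, reported as
  such.

## Resampling stability

Random subsamples of size `t = round(fraction · s)` are drawn without
replacement; the subsample SVD's `v_k^(b)` is compared with the full-data
`v_k` at the same index by Pearson correlation (Spearman optional), with
the sign aligned and the flip recorded.  Fixed-index matching is the
primary definition; a `best_match` diagnostic records when another index
correlates better (eigenvector order can swap under resampling).  The
degenerate `fraction = 1.0` returns correlations of exactly 1.

The null behavior of this statistic depends strongly on the subsample
fraction: for pure noise at `s = 20`, dropping only 10 % of samples leaves
the median correlation near 0.9 (most of the row space is retained), while
half-sampling collapses it below 0.5.  The package therefore uses
half-sampling as the null/instability probe in its own diagnostics and
tests, and 90 % subsampling (the cohort-analysis convention) for assessing
real components; tests also assert the monotone decay of the null
correlation with fraction.

## Normalization diagnostic

The mode of the density of per-gene log differences between two samples is
located by a Gaussian KDE evaluated on a 512-point grid spanning the
difference range, restricted to genes above the 10th-percentile expression
floor in both samples.  The bandwidth is Silverman's rule inflated 2.5×:
the mode of a roughly symmetric difference density is unbiased under
oversmoothing, while the estimator variance drops enough that replicate
samples (noise sd 0.3, a few thousand genes) give |mode| < 0.05
reliably — plain Silverman leaves two-to-three times that scatter.  The
normalizer shifts each sample by minus the median of its modes against the
reference samples, then re-centers the offsets to sum to zero (the overall
constant is not identifiable from pairwise differences).  This audits and
enforces the mode-zero principle on log-scale data; it does not replace
count-level or probe-level normalization of raw platform data.

## Synthetic data

`simulate_dual_species` builds each profile as
`E = gene_baseline + sample_shift + Σ_c amplitude_c · outer(p_c, q_c) + noise`
with per-gene baselines uniform on 4–12 log₂ units, per-sample shifts
N(0, 0.05) (which puts the baseline-loading CV well under 2 %, the regime
of well-normalized data), and i.i.d. Gaussian noise (sd 0.5 by default).
Sample patterns `p_c` are zero-mean with unit rms; gene programs `q_c`
are +1 on the up set, −1 on the down set, 0 elsewhere — so
`amplitude/noise_sd` is the per-gene SNR of a program gene (default 4).
The default design mirrors the study shape: species A has 2 genotypes ×
5 timepoints × 3 replicates (30 samples) with the shared program following
the group-indicator × monotone-time-ramp contrast (a progressive disease
course; a flat `"group"` pattern is available for pure rank-1-contrast
experiments); species B has 61 donors with an HbA1c-like covariate
(mean 38, sd 8 mmol/mol; ≥ 39 flags the abnormal stratum) whose
standardized values drive the shared program.  Programs are disjoint and
live inside the homolog pool; decoy sets are random same-size draws from
non-program genes.  All randomness flows through one seed.

What the generator does *not* emulate: count-level sequencing noise,
probe-level microarray effects, correlated gene-gene noise, batch
structure, and missing values.  Passing tests therefore demonstrate the
correctness and calibration of the machinery under the stated model, not
robustness to platform-specific artifacts.

`simulate_islet_masks` fills a disk of radius R with insulin pixels and
places glucagon pixels either in a ≤ 2 px mantle band at the rim
(fraction `1 − infiltration`) or uniformly over the disk (the rest).  At
full infiltration the mean signed distance to the hull is R/3 (the mean of
R − r over a uniform disk), the oracle used in tests.

## Morphometry

The islet rim is the convex hull of insulin pixel centers; glucagon pixel
distances are Euclidean distances to the hull *boundary* (polygon edges),
signed positive inside by a point-in-polygon test, and scaled by
`pixel_size` (so the index is equivariant in physical units).  The
irregularity index is the symmetric trimmed mean of the signed distances;
the trim fraction is a convention, defaulting to 0.05, and a sensitivity
report at 0, 0.025, 0.05 and 0.10 accompanies every `analyze_islet` call.
The KDE of distances is descriptive output only; the index never depends
on it.  RGB micrographs are supported through a simplified
channel-dominance rule (green → insulin, red → glucagon, ties excluded);
quantitative reproduction of published micrograph indices is not claimed,
as the original binarization thresholds are unknown.

## Problem sizes and numerical choices

Tests and the acceptance script run the pipeline at reduced scale chosen
to keep planted effects in the same SNR regime as the full-size setting:
profiles of 800–5000 genes, stability at B = 200 replicates, RRA null
calibration at 10⁵ Monte-Carlo draws, specificity controls at 40–100
simulations.  SVD identities are asserted to 1e-8 relative; equalized
block norms to 1e-10; exact test values to enumeration precision.
Degenerate inputs fail fast with named errors: non-finite matrix entries,
duplicate identifiers, empty reference/insulin/homolog sets, collinear
hulls, all-trimmed distance samples.

## Known limitations

- The mode-zero normalizer corrects additive (per-sample) offsets only;
  intensity-dependent distortions need the platform-level methods it
  audits.
- Eigen-components are matched by index with sign freedom only; no
  rotation or Procrustes alignment is attempted, so closely spaced
  singular values can swap component order between datasets or replicates
  (the `best_match` diagnostic flags this).
- RRA uses the Bonferroni bound, not the exact order-statistic correction,
  so aggregate p-values are conservative.
- The region numbering of the loading-plane quadrants II/III is a fixed
  convention; the flagged-outside-IV union statistic is invariant to it.
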