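"""Gene-eigenvector stability by re-sampling samples.

For an observational cohort there is no designed contrast to validate a
component against; instead the SVD is recomputed on random 90% subsamples
and each subsample gene-eigenvector is correlated with the full-data one.
Tracked gene sets are re-scored per replicate to measure pathway-level
stability.
"""

import dualeigen as de

A, B, hmap, catalog, truth = de.simulate_dual_species(de.SyntheticConfig(seed=3))

up = set(truth.programs["shared_program"]["up"]["B"])
down = set(truth.programs["shared_program"]["down"]["B"])
res = de.resample_stability(
    B, components=[1], fraction=0.9, B=200,
    tracked_sets={"planted_up": up, "planted_down": down},
    alpha=0.05, seed=0,
)
corr = res.correlations["k1"]
print(f"subsample size t = {res.t} of {B.n_samples} samples, B = {res.B} replicates")
print(f"gene-eigenvector correlation: median {corr.median():.3f}, "
      f"{(corr > 0.9).mean():.1%} of replicates above 0.9")
print(res.set_stability.to_string(index=False))
# a planted component at SNR 4 stays essentially identical under
# re-sampling, and its program sets stay enriched with the same pole in
# ~all replicates — the hallmark of a stable, interpretable component
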