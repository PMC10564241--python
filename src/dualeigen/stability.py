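"""Gene-eigenvector stability by re-sampling samples.

For an observational cohort there is no designed contrast to validate an
eigen-component against, so stability is assessed empirically: draw B
random subsamples of size t = round(fraction * s) without replacement,
recompute the SVD on each row-subset, and correlate each subsample
gene-eigenvector v_k^(b) with the full-data v_k at the same component
index (sign-aligned, since SVD signs are arbitrary).  Tracked gene sets
are re-scored on every replicate; the fraction of replicates in which a
set stays significantly enriched with its full-data direction measures
pathway-level stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionProfile
from .eigen import decompose
from .enrichment import wilcoxon_score

__all__ = ["StabilityResult", "resample_stability"]


@dataclass
class StabilityResult:
    """Per-replicate eigenvector correlations and tracked-set stability."""

    B: int
    t: int
    components: list[int]
    correlations: pd.DataFrame       # B rows, one column per component k
    sign_flips: pd.DataFrame         # whether alignment flipped the sign
    match_switches: pd.DataFrame | None  # best-match index != k (diagnostic)
    set_stability: pd.DataFrame      # tracked set x component: stable fraction
    seed: int = 0
    summary: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.summary is None:
            self.summary = self.correlations.describe().T


def resample_stability(
    profile: ExpressionProfile,
    components: list[int] | tuple[int, ...] = (1,),
    fraction: float = 0.9,
    B: int = 1000,
    tracked_sets: dict[str, set[str]] | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    correlation: str = "pearson",
    best_match: bool = False,
) -> StabilityResult:
    """Evaluate stability of gene-eigenvectors under sample re-sampling.

    Parameters
    ----------
    components
        Component indices k >= 1 to track (baseline convention of the
        full-data decomposition).
    fraction
        Subsample fraction of the s samples; ``1.0`` is the degenerate
        identity check (all correlations exactly 1).  Sampling is without
        replacement.
    tracked_sets
        Optional name -> gene-id-set mapping; each set is scored on every
        replicate's v_k and counted stable when its raw two-sided p < alpha
        and its pole matches the full-data pole.
    best_match
        Also record, per replicate, whether some other component index of
        the subsample SVD correlates better than index k (eigenvector order
        can swap under resampling); matching itself stays fixed-index.
    """
    s = profile.n_samples
    components = list(components)
    t = int(round(fraction * s))
    if fraction > 1.0:
        raise ValueError("fraction must be <= 1")
    if t < max(components) + 2:
        raise ValueError(f"subsample size {t} too small for components {components}")
    rng = np.random.default_rng(seed)
    full = decompose(profile)
    full_v = {k: full.v(k) for k in components}
    full_dir: dict[tuple[str, int], str] = {}
    if tracked_sets:
        for k in components:
            vals = pd.Series(full_v[k], index=profile.gene_ids)
            for name, members in tracked_sets.items():
                res = wilcoxon_score(vals, members, set_name=name)
                full_dir[(name, k)] = res.direction if res else "skipped"

    corr = np.empty((B, len(components)))
    flips = np.zeros((B, len(components)), dtype=bool)
    switches = np.zeros((B, len(components)), dtype=bool) if best_match else None
    stable_counts = {key: 0 for key in full_dir}
    E = profile.matrix
    for b in range(B):
        rows = rng.choice(s, size=t, replace=False)
        Eb = E[np.sort(rows)]
        U, lam, Vt = np.linalg.svd(Eb, full_matrices=False)
        for ci, k in enumerate(components):
            vb = Vt[k]
            r = _corr(full_v[k], vb, correlation)
            if r < 0:
                r, vb = -r, -vb
                flips[b, ci] = True
            corr[b, ci] = r
            if best_match:
                rs = np.abs(Vt[: min(len(lam), max(components) + 2)] @ full_v[k])
                switches[b, ci] = int(np.argmax(rs)) != k
            if tracked_sets:
                vals = pd.Series(vb, index=profile.gene_ids)
                for name, members in tracked_sets.items():
                    key = (name, k)
                    if full_dir[key] == "skipped":
                        continue
                    res = wilcoxon_score(vals, members, set_name=name)
                    if res and res.p < alpha and res.direction == full_dir[key]:
                        stable_counts[key] += 1

    cols = [f"k{k}" for k in components]
    set_rows = [
        {"set_name": name, "component": k,
         "full_data_direction": full_dir[(name, k)],
         "stable_fraction": stable_counts[(name, k)] / B}
        for (name, k) in full_dir
    ]
    return StabilityResult(
        B=B,
        t=t,
        components=components,
        correlations=pd.DataFrame(corr, columns=cols),
        sign_flips=pd.DataFrame(flips, columns=cols),
        match_switches=pd.DataFrame(switches, columns=cols) if best_match else None,
        set_stability=pd.DataFrame(
            set_rows, columns=["set_name", "component", "full_data_direction",
                               "stable_fraction"]
        ),
        seed=seed,
    )


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "spearman":
        from scipy.stats import rankdata

        a, b = rankdata(a), rankdata(b)
    elif method != "pearson":
        raise ValueError(f"unknown correlation {method!r}")
    # identity subsample: the correlation is 1 by construction, not 1 - eps
    if np.array_equal(a, b):
        return 1.0
    if np.array_equal(a, -b):
        return -1.0
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0
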