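"""Synthetic two-species expression profiles and islet masks with planted truth.

The generator emulates the structure of the study this package is built
around: a designed two-group time course for species A (two genotypes,
five timepoints, three replicates — a GK/Wistar-like design), a
continuous-covariate observational cohort for species B (61 donors with an
HbA1c-like covariate), one gene program shared across the species through
a homolog map (an "angiogenesis up / oxidative-phosphorylation down"
surrogate loading with opposite signs for its up and down sets), optional
species-specific programs, per-gene baselines, per-sample shifts and
i.i.d. Gaussian log-scale noise.  Islet masks place insulin pixels on a
disk and glucagon pixels in a thin mantle rim, with a tunable fraction
infiltrating the core.

Every profile is built as

    E = gene_baseline + sample_shift + sum_c amplitude_c * outer(p_c, q_c) + noise

on the log scale, where each sample pattern p_c has zero mean and unit
root-mean-square and each gene program q_c has entries +1 (up set), -1
(down set) and 0 elsewhere — so ``amplitude / noise_sd`` is the per-gene
signal-to-noise ratio of a program gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionProfile, GeneSetCatalog, HomologyMap

__all__ = [
    "PlantedComponent",
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_dual_species",
    "simulate_islet_masks",
]


@dataclass
class PlantedComponent:
    """One planted rank-1 program: a sample pattern times a gene program.

    ``species`` is ``"both"`` (shared through the homolog map), ``"A"`` or
    ``"B"``.  Species-A sample patterns (``pattern_a``):
    ``"group_time"`` (default) is the group indicator times a monotone time
    ramp, mimicking a progressive disease contrast; ``"group"`` is the flat
    two-group contrast (a pure rank-1 contrast); ``"time"`` is a pure time
    trend shared by both groups.  Species B uses the standardized covariate
    for shared components and an unrelated random pattern for B-only ones.
    """

    name: str
    n_up: int
    n_down: int
    amplitude: float
    species: str = "both"
    pattern_a: str = "group_time"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.species not in ("both", "A", "B"):
            raise ValueError("species must be 'both', 'A' or 'B'")
        if self.pattern_a not in ("group_time", "group", "time"):
            raise ValueError("pattern_a must be 'group_time', 'group' or 'time'")
        if self.n_up < 0 or self.n_down < 0 or self.n_up + self.n_down == 0:
            raise ValueError("program needs non-negative set sizes, not both zero")


@dataclass
class SyntheticConfig:
    """Study-shaped defaults: 2 groups x 5 weeks x 3 replicates vs 61 donors."""

    n_genes: int = 5000
    n_shared_homologs: int = 4000
    timepoints: tuple = (4, 6, 8, 16, 24)
    replicates: int = 3
    n_samples_b: int = 61
    covariate_mean: float = 38.0      # HbA1c-like, mmol/mol
    covariate_sd: float = 8.0
    components: list[PlantedComponent] = field(
        default_factory=lambda: [
            PlantedComponent("shared_program", n_up=100, n_down=100, amplitude=2.0),
            PlantedComponent("a_specific", n_up=80, n_down=80, amplitude=1.2, species="A"),
            PlantedComponent("b_specific", n_up=80, n_down=80, amplitude=1.2, species="B"),
        ]
    )
    baseline_range: tuple[float, float] = (4.0, 12.0)   # per-gene mean, log2 units
    sample_shift_sd: float = 0.05                       # per-sample offset
    noise_sd: float = 0.5                               # i.i.d. log-scale noise
    n_decoy_sets: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shared_homologs > self.n_genes:
            raise ValueError("n_shared_homologs must be <= n_genes")
        for name, v in (
            ("n_genes", self.n_genes),
            ("n_shared_homologs", self.n_shared_homologs),
            ("replicates", self.replicates),
            ("n_samples_b", self.n_samples_b),
        ):
            if v < 2:
                raise ValueError(f"{name} must be >= 2")
        if len(self.timepoints) < 2:
            raise ValueError("need at least 2 timepoints")
        if self.noise_sd < 0 or self.sample_shift_sd < 0:
            raise ValueError("noise/shift standard deviations must be >= 0")
        total_program = sum(c.n_up + c.n_down for c in self.components)
        if total_program > self.n_shared_homologs:
            raise ValueError("planted programs exceed the shared homolog pool")

    @property
    def n_samples_a(self) -> int:
        return 2 * len(self.timepoints) * self.replicates


@dataclass
class SyntheticTruth:
    """Planted ground truth: programs, directions and sample patterns."""

    programs: dict        # name -> {"species", "up": {A: [...], B: [...]}, "down": ...}
    patterns_a: dict      # component name -> sample pattern (zero-mean, rms 1)
    patterns_b: dict
    covariate_b: np.ndarray
    infiltration: float | None = None


def _rms_pattern(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    rms = np.sqrt((x ** 2).mean())
    return x / rms if rms > 0 else x


def simulate_dual_species(
    config: SyntheticConfig | None = None,
) -> tuple[ExpressionProfile, ExpressionProfile, HomologyMap, GeneSetCatalog, SyntheticTruth]:
    """Generate the paired species profiles, homolog map, catalog and truth.

    Deterministic given ``config.seed``.  Gene ids are ``gA#####`` /
    ``gB#####``; the first ``n_shared_homologs`` positions of each species
    are homologous in order.  Program genes live inside the homolog pool;
    shared programs load on the same homolog positions in both species.
    """
    cfg = config if config is not None else SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    g = cfg.n_genes
    genes_a = [f"gA{j:05d}" for j in range(g)]
    genes_b = [f"gB{j:05d}" for j in range(g)]
    hmap = HomologyMap(list(zip(genes_a[: cfg.n_shared_homologs],
                                genes_b[: cfg.n_shared_homologs])))

    # --- sample designs -------------------------------------------------
    t_levels = list(cfg.timepoints)
    groups, weeks, reps = [], [], []
    for grp in ("DS", "CTL"):                 # disease-susceptible vs control
        for tp in t_levels:
            for r in range(1, cfg.replicates + 1):
                groups.append(grp)
                weeks.append(tp)
                reps.append(r)
    s_a = len(groups)
    samples_a = [f"A_{g_}{t}_r{r}" for g_, t, r in zip(groups, weeks, reps)]
    meta_a = pd.DataFrame(
        {"group": groups, "week": weeks, "replicate": reps}, index=samples_a
    )
    ramp = {tp: i + 1 for i, tp in enumerate(t_levels)}   # monotone time ramp
    sign = np.where(np.array(groups) == "DS", 1.0, -1.0)
    patterns_by_name = {
        "group_time": _rms_pattern(sign * np.array([ramp[t] for t in weeks])),
        "group": _rms_pattern(sign.astype(float)),
        "time": _rms_pattern(np.array([ramp[t] for t in weeks], dtype=float)),
    }

    covariate = cfg.covariate_mean + cfg.covariate_sd * rng.standard_normal(cfg.n_samples_b)
    samples_b = [f"B_donor{i:03d}" for i in range(cfg.n_samples_b)]
    meta_b = pd.DataFrame(
        {"hba1c": covariate, "abnormal": covariate >= 39.0}, index=samples_b
    )
    pattern_cov = _rms_pattern(covariate)

    # --- planted gene programs (disjoint, inside the homolog pool) ------
    pool = rng.permutation(cfg.n_shared_homologs)
    cursor = 0
    programs: dict = {}
    EA = np.zeros((s_a, g))
    EB = np.zeros((cfg.n_samples_b, g))
    patterns_a: dict = {}
    patterns_b: dict = {}
    for comp in cfg.components:
        up_idx = np.sort(pool[cursor:cursor + comp.n_up])
        cursor += comp.n_up
        down_idx = np.sort(pool[cursor:cursor + comp.n_down])
        cursor += comp.n_down
        q = np.zeros(g)
        q[up_idx] = 1.0
        q[down_idx] = -1.0
        programs[comp.name] = {
            "species": comp.species,
            "amplitude": comp.amplitude,
            "up": {"A": [genes_a[j] for j in up_idx], "B": [genes_b[j] for j in up_idx]},
            "down": {"A": [genes_a[j] for j in down_idx], "B": [genes_b[j] for j in down_idx]},
        }
        if comp.species in ("both", "A"):
            name = comp.pattern_a if comp.species == "both" else (
                comp.pattern_a if comp.pattern_a != "group_time" else "time"
            )
            p = patterns_by_name[name]
            EA += comp.amplitude * np.outer(p, q)
            patterns_a[comp.name] = p
        if comp.species in ("both", "B"):
            p = pattern_cov if comp.species == "both" else _rms_pattern(
                rng.standard_normal(cfg.n_samples_b)
            )
            EB += comp.amplitude * np.outer(p, q)
            patterns_b[comp.name] = p

    # --- baselines, shifts, noise ---------------------------------------
    lo, hi = cfg.baseline_range
    for E, s in ((EA, s_a), (EB, cfg.n_samples_b)):
        E += rng.uniform(lo, hi, size=g)[None, :]
        E += rng.normal(0.0, cfg.sample_shift_sd, size=s)[:, None]
        if cfg.noise_sd > 0:
            E += rng.normal(0.0, cfg.noise_sd, size=E.shape)

    profile_a = ExpressionProfile(EA, genes_a, samples_a, "speciesA", meta_a)
    profile_b = ExpressionProfile(EB, genes_b, samples_b, "speciesB", meta_b)

    # --- catalog: planted sets plus random same-size decoys -------------
    sets: dict[str, set[str]] = {}
    for name, info in programs.items():
        for direction in ("up", "down"):
            for sp, key in (("A", "A"), ("B", "B")):
                if info["species"] in ("both", sp) and info[direction][key]:
                    sets[f"{name}_{direction}_{sp}"] = set(info[direction][key])
    program_idx = set(pool[:cursor])
    free = np.array(sorted(set(range(g)) - program_idx))
    decoy_size = max(
        5, int(np.mean([c.n_up + c.n_down for c in cfg.components]) // 2) or 5
    )
    for d in range(cfg.n_decoy_sets):
        for sp, ids in (("A", genes_a), ("B", genes_b)):
            pick = rng.choice(free, size=min(decoy_size, len(free)), replace=False)
            sets[f"decoy{d:02d}_{sp}"] = {ids[j] for j in pick}
    catalog = GeneSetCatalog(sets, universe=set(genes_a) | set(genes_b))

    truth = SyntheticTruth(
        programs=programs,
        patterns_a=patterns_a,
        patterns_b=patterns_b,
        covariate_b=covariate,
    )
    return profile_a, profile_b, hmap, catalog, truth


def simulate_islet_masks(
    radius_px: int = 100,
    infiltration: float = 0.0,
    n_glucagon: int = 400,
    n_insulin: int | None = None,
    seed: int = 0,
    rim_width: float = 2.0,
    margin: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary insulin/glucagon masks of a synthetic islet.

    Insulin pixels fill a disk of radius ``radius_px`` (or a random subset
    of it of size ``n_insulin``).  A fraction ``1 - infiltration`` of the
    glucagon pixels lies in the thin mantle band within ``rim_width``
    pixels of the disk boundary (the normal core-mantle architecture); the
    remainder is uniform over the disk interior (alpha-cell infiltration).
    Both masks share one frame; deterministic given ``seed``.
    """
    if radius_px < 10:
        raise ValueError("radius_px must be >= 10")
    if not (0.0 <= infiltration <= 1.0):
        raise ValueError("infiltration must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    size = 2 * (radius_px + margin) + 1
    c = radius_px + margin
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - c, xx - c)
    disk = r <= radius_px

    insulin = disk.copy()
    if n_insulin is not None:
        flat = np.flatnonzero(disk)
        if n_insulin < len(flat):
            keep = rng.choice(flat, size=n_insulin, replace=False)
            insulin = np.zeros_like(disk)
            insulin.ravel()[keep] = True

    rim = disk & (r >= radius_px - rim_width)
    interior = disk  # "uniform in the interior" = uniform over the whole disk
    n_mantle = int(round((1.0 - infiltration) * n_glucagon))
    n_core = n_glucagon - n_mantle
    glucagon = np.zeros_like(disk)
    for region, n in ((rim, n_mantle), (interior, n_core)):
        if n == 0:
            continue
        flat = np.flatnonzero(region)
        pick = rng.choice(flat, size=n, replace=n > len(flat))
        glucagon.ravel()[pick] = True
    return insulin, glucagon
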