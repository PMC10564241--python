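import numpy as np
import pytest

import dualeigen as de


@pytest.fixture(scope="session")
def small_dataset():
    """Two-species synthetic dataset at reduced scale, fixed seed.

    One shared program (100 up / 100 down, SNR 4) plus one specific
    program per species, 800 genes each, 600 homologs.
    """
    cfg = de.SyntheticConfig(n_genes=800, n_shared_homologs=600, seed=3)
    return de.simulate_dual_species(cfg)


@pytest.fixture(scope="session")
def program_vector():
    """Ternary planted-program vector (+1 up, -1 down, 0 else) builder."""

    def _build(profile, truth, name="shared_program", side="A"):
        q = np.zeros(profile.n_genes)
        gi = profile.gene_index()
        info = truth.programs[name]
        for g in info["up"][side]:
            q[gi[g]] = 1.0
        for g in info["down"][side]:
            q[gi[g]] = -1.0
        return q

    return _build


def pearson(a, b):
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
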