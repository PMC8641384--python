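import numpy as np
import pytest

from twasbench import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One-population cohort, 3 sparse genes, moderate signal."""
    cfg = SimConfig(n_samples=(200,), n_snps=60, n_genes=3, h2_cis=0.5,
                    architecture="sparse", n_causal=2, seed=11)
    panel, expr, truth = simulate_cohort(cfg)
    return cfg, panel, expr, truth


@pytest.fixture(scope="session")
def two_pop_cohort():
    """Two diverged populations (Fst 0.15) with population-specific LD."""
    cfg = SimConfig(n_samples=(250, 120), n_snps=60, n_genes=4, h2_cis=0.5,
                    fst=0.15, ld_rho=(0.9, 0.6), seed=12)
    panel, expr, truth = simulate_cohort(cfg)
    return cfg, panel, expr, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
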