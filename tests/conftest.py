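import numpy as np
import pytest

from gpcattle.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """120 animals x 300 markers, point-normal architecture, h2 = 0.5."""
    cfg = SimulationConfig(n_individuals=120, n_markers=300,
                           heritability_true=0.5, architecture="point_normal",
                           pi_true=0.9, seed=42)
    geno, pheno, truth = simulate_dataset(cfg)
    return cfg, geno, pheno, truth


@pytest.fixture(scope="session")
def equivalence_dataset():
    """50 animals x 500 markers for the GBLUP / SNP-BLUP identity."""
    cfg = SimulationConfig(n_individuals=50, n_markers=500,
                           heritability_true=0.4, architecture="normal",
                           seed=7)
    geno, pheno, truth = simulate_dataset(cfg)
    return cfg, geno, pheno, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
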