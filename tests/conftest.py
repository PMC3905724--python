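import numpy as np
import pandas as pd
import pytest

from isoshare.containers import GeneticMap, GenotypeMatrix


def make_matrix(genotypes, chrom="1", positions=None, samples=None):
    """Build a GenotypeMatrix from a plain array with sensible defaults."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "id": [f"v{j}" for j in range(m)],
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypeMatrix(genotypes, samples, variants)


@pytest.fixture
def rng():
    return np.random.default_rng(20131217)


@pytest.fixture
def uniform_map():
    return GeneticMap.uniform("1", 1_000_000, 1.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small error-free simulated cohort shared across tests."""
    from isoshare.simulate import IsolateConfig, simulate_isolate

    cfg = IsolateConfig(
        n_founders=20,
        n_generations=6,
        n_variants=120,
        chrom_length_bp=10_000_000,
        carrier_target_freq=0.05,
        freq_tol=0.03,
        genotype_error_rate=0.0,
        missing_rate=0.0,
        seed=11,
    )
    return simulate_isolate(cfg)
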