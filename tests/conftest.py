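import numpy as np
import pandas as pd
import pytest

from hybridvar import ase, normalize, simulate


@pytest.fixture(scope="session")
def bc1_dataset():
    """A small BC1 cross with a handful of cis and trans regulators."""
    design = simulate.CrossDesign("BC1", 14, n_chromosomes=8,
                                  markers_per_chromosome=30)
    truth, counts, alleles = simulate.simulate_dataset(
        design, seed=11, n_cis_regulated=6, n_trans_regulated=3, n_both=1,
        effect_size_range=(1.0, 2.0))
    return truth, counts, alleles


@pytest.fixture(scope="session")
def bc1_analysis(bc1_dataset):
    """Genotypes and normalized expression for the small BC1 cross."""
    truth, counts, alleles = bc1_dataset
    geno, complete = ase.genotype_population(*alleles)
    norm = normalize.normalize_pipeline(counts, truth.metadata())
    return truth, geno, complete, norm


@pytest.fixture
def rng():
    return np.random.default_rng(42)
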