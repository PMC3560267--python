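"""Shared fixtures: small synthetic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from amdr.datatypes import GenotypeDataset
from amdr.simulate import MODELS, SimulationScenario, simulate_dataset


@pytest.fixture
def toy_dataset() -> GenotypeDataset:
    """Eight subjects, three SNPs, handcrafted genotypes."""
    genotypes = np.array(
        [
            [0, 0, 1],
            [0, 1, 2],
            [1, 0, 0],
            [2, 2, 1],
            [0, 0, 0],
            [1, 1, 2],
            [2, 0, 1],
            [0, 2, 0],
        ],
        dtype=np.int8,
    )
    phenotype = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=np.int8)
    return GenotypeDataset(genotypes=genotypes, phenotype=phenotype)


@pytest.fixture
def xor_dataset() -> GenotypeDataset:
    """Noiseless parity signal on loci (0, 1): case iff g0 + g1 is odd."""
    rng = np.random.default_rng(7)
    genotypes = rng.choice(3, size=(200, 4), p=[0.25, 0.5, 0.25]).astype(np.int8)
    phenotype = ((genotypes[:, 0] + genotypes[:, 1]) % 2).astype(np.int8)
    return GenotypeDataset(genotypes=genotypes, phenotype=phenotype)


@pytest.fixture
def null_dataset() -> GenotypeDataset:
    """Balanced dataset whose phenotype is independent of all genotypes."""
    rng = np.random.default_rng(11)
    genotypes = rng.choice(3, size=(200, 4), p=[0.25, 0.5, 0.25]).astype(np.int8)
    phenotype = np.zeros(200, dtype=np.int8)
    phenotype[:100] = 1
    rng.shuffle(phenotype)
    return GenotypeDataset(genotypes=genotypes, phenotype=phenotype)


@pytest.fixture(scope="session")
def signal_dataset() -> GenotypeDataset:
    """Two planted interacting pairs (additive scenario), n=400."""
    scenario = SimulationScenario(
        type="C", model_pair_1=MODELS["Model1"], model_pair_2=MODELS["Model2"]
    )
    return simulate_dataset(scenario, 400, rng_seed=17)
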