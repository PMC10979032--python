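import numpy as np
import pytest

from dtafusion import chem, synth


@pytest.fixture(scope="session")
def ethanol():
    return chem.parse_molecule("CCO", "ethanol")


@pytest.fixture(scope="session")
def benzene():
    return chem.parse_molecule("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def fixture_smiles():
    """~200 valid SMILES drawn from the synthetic generator."""
    spec = synth.FixtureSpec(n_drugs=200, n_proteins=1, seed=42)
    return synth.gen_drug_set(spec)


@pytest.fixture(scope="session")
def small_protein_record():
    spec = synth.FixtureSpec(protein_length=(20, 30), seed=5)
    return synth.gen_protein_record(spec, "prot_fix")


def random_adjacency(rng, n, p=0.4):
    """Random symmetric 0/1 adjacency with zero diagonal."""
    a = (rng.random((n, n)) < p).astype(np.int64)
    a = np.triu(a, 1)
    return a + a.T


@pytest.fixture
def rng():
    return np.random.default_rng(0)
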