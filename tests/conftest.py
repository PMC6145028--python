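import numpy as np
import pytest

from parashore.datamodel import GenotypeMatrix, SampleHierarchy
from parashore.synthetic import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One-site dataset with a few strongly divergent loci planted."""
    cfg = SimConfig(
        seed=101, n_loci=400, n_per_level=20, sites=("S1",),
        refugium_of={"S1": "south"},
        n_divergent_shared_all=0, n_divergent_shared_southern=0,
        n_divergent_private=10, delta=0.9, n_balancing=0, missing_rate=0.05,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def tiny_gm():
    """Hand-written 4x3 genotype matrix with one missing call."""
    dosages = np.array(
        [[0, 1, 2], [1, 1, 0], [2, 0, -1], [0, 2, 1]], dtype=np.int8
    )
    gm = GenotypeMatrix(
        dosages, ["a1", "a2", "b1", "b2"],
        [(1, 5), (2, 0), (3, 12)],
    )
    hierarchy = SampleHierarchy.from_records(
        [("a1", "S1", "T1", "upper"), ("a2", "S1", "T1", "upper"),
         ("b1", "S1", "T1", "lower"), ("b2", "S1", "T2", "lower")]
    )
    return gm, hierarchy
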