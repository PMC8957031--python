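import numpy as np
import pytest

from drugrep import (
    FixtureSpec,
    GeneNetwork,
    GeneSet,
    GeneSignature,
    SignatureLibrary,
    make_benchmark,
)


@pytest.fixture
def path_network() -> GeneNetwork:
    """Path graph a-b-c-d."""
    return GeneNetwork.from_edges([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def toy_library() -> SignatureLibrary:
    return SignatureLibrary([
        GeneSignature(id="drugA", species="human", tissue="liver",
                      up_genes=("G1", "G2"), down_genes=("G3",)),
        GeneSignature(id="drugB", species="human", tissue="liver",
                      up_genes=("G4", "G5"), down_genes=("G6",)),
    ])


@pytest.fixture(scope="session")
def benchmark_fixture():
    """Default synthetic benchmark, shared across tests (read-only)."""
    return make_benchmark(FixtureSpec(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
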