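import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from gcmm.similarity import build_network
from gcmm.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_bundle():
    """A small planted network: 30 drugs, 20 diseases, 3 clusters."""
    return generate(
        SyntheticSpec(n_drugs=30, n_diseases=20, n_clusters=3, n_targets=9, seed=7)
    )


@pytest.fixture(scope="session")
def small_net(small_bundle):
    b = small_bundle
    return build_network(b.drugs, b.diseases, b.dag, b.target_sequences, b.assoc)


@pytest.fixture(scope="session")
def bench_bundle():
    """The default planted benchmark (100 drugs, 60 diseases, 5 clusters)."""
    return generate(SyntheticSpec())


@pytest.fixture(scope="session")
def bench_net(bench_bundle):
    b = bench_bundle
    return build_network(b.drugs, b.diseases, b.dag, b.target_sequences, b.assoc)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
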