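import numpy as np
import pytest

from neurogrn.network import (
    ParameterSet,
    literature_topology,
    nptb_to_ptb_topology,
)
from neurogrn.synth import NoiseModel, generate_dataset, make_reference_truth


@pytest.fixture(scope="session")
def lit_topo():
    return literature_topology()


@pytest.fixture(scope="session")
def nptb_topo():
    return nptb_to_ptb_topology()


@pytest.fixture(scope="session")
def truth():
    """Verified ground-truth (topology, params) for the nPTB -> PTB model."""
    return make_reference_truth("nPTB->PTB", seed=0)


@pytest.fixture(scope="session")
def noiseless_dataset(truth):
    topo, params = truth
    dataset, record = generate_dataset(
        topo, params, noise_model=NoiseModel(sigma=0.0), seed=0
    )
    return dataset, record


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_params(topology, rng, h_max=3.5):
    """A random positive parameter set for property tests."""
    pairs = {(s, t) for s, t, _ in topology.edges}
    return ParameterSet(
        alpha={n: float(rng.uniform(0.1, 3.0)) for n in topology.nodes},
        delta={n: float(rng.uniform(0.05, 1.0)) for n in topology.nodes},
        beta={n: float(rng.uniform(0.05, 2.0)) for n in topology.beta_nodes},
        k={p: float(rng.uniform(0.2, 3.0)) for p in pairs},
        h={p: float(rng.uniform(0.5, h_max)) for p in pairs},
        beta_resti=float(rng.uniform(0.5, 5.0)),
        beta_vascl1=float(rng.uniform(0.5, 5.0)),
    )
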