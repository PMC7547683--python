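import numpy as np
import pytest

from infosource.ctrnn import NetworkParams
from infosource.density import DiscreteJoint


@pytest.fixture
def single_neuron():
    """1-neuron integrator: w=0, w_in=1, tau=1, theta=0."""
    return NetworkParams(
        weights=[[0.0]], input_weights=[1.0], output_weights=[0.0], taus=[1.0], biases=[0.0]
    )


@pytest.fixture
def random_params():
    rng = np.random.default_rng(42)
    n = 3
    return NetworkParams(
        weights=rng.normal(0, 4, (n, n)),
        input_weights=rng.normal(0, 4, n),
        output_weights=rng.normal(0, 4, n),
        taus=rng.uniform(0.5, 5, n),
        biases=rng.normal(0, 4, n),
    )


def joint_from_dict(d, sizes):
    """Build a DiscreteJoint from a {outcome tuple: prob} mapping."""
    idx = np.array([list(k) for k in d], dtype=np.int64)
    probs = np.array(list(d.values()))
    return DiscreteJoint(indices=idx, probs=probs / probs.sum(), n_bins=np.asarray(sizes))
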