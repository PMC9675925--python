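import numpy as np
import pytest

import nlcopt


@pytest.fixture(scope="session")
def dataset():
    """The packaged 30-run study dataset."""
    return nlcopt.load_packaged_dataset()


@pytest.fixture(scope="session")
def printed_net():
    """The published 4-9-9-4 surrogate (actual-unit inputs)."""
    return nlcopt.printed_network()


@pytest.fixture(scope="session")
def factors():
    return nlcopt.TABLE_FACTORS


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_network(rng, layer_sizes=(3, 5, 1), scale=1.0):
    """A random fully connected tanh-half network for property tests."""
    ws, bs = [], []
    for l in range(len(layer_sizes) - 1):
        ws.append(rng.normal(0, scale, (layer_sizes[l + 1], layer_sizes[l])))
        bs.append(rng.normal(0, scale, layer_sizes[l + 1]))
    acts = ["tanh_half"] * (len(layer_sizes) - 2) + ["identity"]
    names = tuple(f"X{i+1}" for i in range(layer_sizes[0]))
    resp = tuple(f"Y{i+1}" for i in range(layer_sizes[-1]))
    return nlcopt.NeuralSurrogate(
        layer_sizes=tuple(layer_sizes),
        weights=tuple(ws),
        biases=tuple(bs),
        activations=tuple(acts),
        input_names=names,
        response_names=resp,
    )
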