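import numpy as np
import pytest

from equivnet import network as N
from equivnet import simulate as S


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_pwms():
    return S.toy_pwms()


@pytest.fixture(scope="session")
def perfect_dataset(toy_pwms):
    """Small dataset where motif presence separates the classes perfectly."""
    cfg = S.SimConfig(
        n_sequences=1000, seq_length=200, p_inject_pos=1.0, p_inject_neg=0.0, seed=2
    )
    data, log = S.simulate_dataset(cfg, toy_pwms)
    return data, log


@pytest.fixture(scope="session")
def trained_perfect(perfect_dataset):
    """Default equivariant model trained to high accuracy on the perfect dataset."""
    data, _ = perfect_dataset
    cfg = N.default_config(seed=1, epochs=20, learning_rate=2e-2, keep_p=1.0, bayesian=False)
    model = N.build_model(cfg)
    N.train(model, data)
    return model, data


def random_sequences(rng, n, length):
    return ["".join("ACGT"[i] for i in rng.integers(0, 4, length)) for _ in range(n)]


def randomize_output_layer(model, rng):
    """Replace the constant-initialized output head with random weights.

    A freshly built model is a constant function of its input (the all-ones
    output weights collapse both logits to the same channel sum), so tests of
    input-dependent behaviour on *untrained* models must randomize the head.
    """
    last = max(model.params)
    blk = model.params[last]
    blk["w"] = rng.normal(size=blk["w"].shape)
    blk["b"] = rng.normal(size=blk["b"].shape)
    return model
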