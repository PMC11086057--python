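import numpy as np
import pytest

import frycount as fc
from frycount.nn.layers import DTYPE


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model():
    """A 1/16-width network, shared across read-only model tests."""
    return fc.build_model(fc.ModelConfig(width_multiplier=1 / 16, seed=7))


@pytest.fixture(scope="session")
def easy_scene():
    """One deterministic small synthetic scene with annotations."""
    return fc.render_scene(fc.SceneSpec(width=192, height=144, n_fry=25, seed=7))


def finite_difference_grads(fn, tensors, eps=1e-6):
    """Central finite differences of a scalar-valued tensor function."""
    grads = []
    for t in tensors:
        num = np.zeros_like(t.data)
        flat = t.data.reshape(-1)
        nf = num.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            lp = fn(*tensors).item()
            flat[i] = orig - eps
            lm = fn(*tensors).item()
            flat[i] = orig
            nf[i] = (lp - lm) / (2 * eps)
        grads.append(num)
    return grads
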