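import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_map(rng):
    """A small random NHWC feature map."""
    return rng.standard_normal((1, 6, 6, 4))


def cast_model_to(model, dtype):
    """Re-cast every parameter and batch-norm buffer of a model in place
    (used to run finite-difference checks in float64)."""
    for p in model.parameters():
        p.value = p.value.astype(dtype)
        p.grad = p.grad.astype(dtype)
    for m in model.modules():
        for name in ("running_mean", "running_var"):
            if hasattr(m, name):
                setattr(m, name, getattr(m, name).astype(dtype))
    return model
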