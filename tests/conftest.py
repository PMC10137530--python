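import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_lite_model():
    """A narrow GL-YOLO-Lite (width 1/8) for forward/backward tests."""
    from glyolite.model import Model

    return Model("gl_yolo_lite", nc=1, width_multiple=0.125, seed=3)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 20-image synthetic dataset shared across tests."""
    from glyolite.data import generate_dataset

    root = tmp_path_factory.mktemp("ds")
    split = generate_dataset(20, root, image_size=320, boxes_per_image=1, seed=7)
    return root, split


def numeric_grad(f, x, eps=1e-2):
    """Central-difference gradient of scalar f wrt ndarray x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
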