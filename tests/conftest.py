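import numpy as np
import pytest

from polycage import (
    OptimizationConfig,
    embed_labeling,
    labeling_from_name,
)


@pytest.fixture(scope="session")
def pic_labeling():
    return labeling_from_name("Pic_P10_1_1_1_1_1")


@pytest.fixture(scope="session")
def pic_geometry(pic_labeling):
    """Regular icosahedral P10 cage, exactly embedded."""
    return embed_labeling(pic_labeling)


@pytest.fixture(scope="session")
def asc_labeling():
    return labeling_from_name("Asc_P11_2_1_1_1_1")


@pytest.fixture()
def noisy_pic(pic_geometry):
    rng = np.random.default_rng(42)
    geo = pic_geometry.copy()
    geo.nodes = geo.nodes + rng.normal(scale=1e-3, size=geo.nodes.shape)
    return geo


@pytest.fixture(scope="session")
def fast_config():
    """Small sweep for test-sized optimizations."""
    return OptimizationConfig(seed=0, sweep_points=3, bisection_iters=2,
                              compute_similarity=False)


def random_rigid_motion(seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=2.0, size=3)
    return Q, t
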