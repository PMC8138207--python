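import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from graphdock import make_fixture
from graphdock.cascade import InternalFFEngine


@pytest.fixture(scope="session")
def benzene():
    return make_fixture("benzene")


@pytest.fixture(scope="session")
def n_butane():
    return make_fixture("n_butane")


@pytest.fixture(scope="session")
def biphenyl():
    return make_fixture("biphenyl")


@pytest.fixture(scope="session")
def methanol():
    return make_fixture("methanol")


@pytest.fixture(scope="session")
def coronene_patch():
    return make_fixture("coronene_patch")


@pytest.fixture(scope="session")
def go_patch():
    return make_fixture("go_patch")


@pytest.fixture(scope="session")
def ff_engine():
    return InternalFFEngine()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def align_flat(coords: np.ndarray) -> np.ndarray:
    """Centre a (near-)planar molecule and rotate its plane into z = 0."""
    x = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(x)
    normal = vt[2]
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(normal, z)
    c = float(normal @ z)
    if np.linalg.norm(v) < 1e-12:
        return x if c > 0 else -x
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    r = np.eye(3) + vx + vx @ vx * ((1 - c) / (np.linalg.norm(v) ** 2))
    return x @ r.T
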