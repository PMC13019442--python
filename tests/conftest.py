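import numpy as np
import pytest

from dbfe.toy_systems import preset


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def harmonic_spec():
    return preset("pure_harmonic", seed=11)


@pytest.fixture(scope="session")
def lj_spec():
    return preset("harmonic_lj", seed=11)


def random_rotation_matrix(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    from scipy.spatial.transform import Rotation
    return Rotation.from_quat(q[[1, 2, 3, 0]]).as_matrix()
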