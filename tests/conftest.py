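import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pocketmod as pm

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def score_cfg():
    return pm.ScoreConfig()


@pytest.fixture(scope="session")
def rotamer_lib():
    return pm.default_rotamer_library()


@pytest.fixture()
def helix12():
    return pm.make_toy_template(12, "helix", seed=11)


def rigid_transform(rng):
    """Random proper rotation + translation for invariance checks."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    trans = rng.uniform(-20, 20, 3)
    return rot, trans
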