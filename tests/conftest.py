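import numpy as np
import pytest

from dqgait import model


@pytest.fixture
def params():
    return model.default_params()


@pytest.fixture
def rng():
    return np.random.default_rng(20250930)


def random_unit_quaternion(rng):
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def random_rigid_dq(rng):
    from dqgait import dual_quaternions as dqm

    return dqm.dq_from_rigid(rng.uniform(-1, 1, 3), random_unit_quaternion(rng))
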