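import numpy as np
import pytest
from itertools import product

from nid.joint import JointTable


def random_joint(rng, n, q, target=None, alpha=1.0):
    """Dirichlet-sampled dense joint over n variables of alphabet size q."""
    states = np.array(list(product(range(q), repeat=n)), dtype=np.int64)
    probs = rng.dirichlet(np.full(len(states), alpha))
    return JointTable(states, probs, (q,) * n, target_index=target)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_joint_suite():
    """A reproducible suite of small random joints for property checks."""
    rng = np.random.default_rng(777)
    suite = []
    for _ in range(50):
        n = int(rng.integers(3, 6))
        q = int(rng.integers(2, 4))
        suite.append(random_joint(rng, n, q))
    return suite
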