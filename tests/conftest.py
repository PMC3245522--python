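import numpy as np
import pytest

import chromosampler as cs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return cs.ModelParams(alpha=2.0, psi=1.0)


@pytest.fixture
def small_5c(params):
    """Noise-free 10-fragment 5C dataset with all pairs measured."""
    gold = cs.make_structure("random_walk", 10, seed=1)
    fmap = cs.make_fragment_map(10, 3500)
    data = cs.simulate_5c(gold, fmap, params, cs.NoiseSpec(mode="none"),
                          even_odd_mask=False, seed=0)
    return gold, fmap, data


@pytest.fixture
def noisy_5c(params):
    """Noisy 20-fragment masked 5C dataset (the delta-oracle workhorse)."""
    gold = cs.make_structure("random_walk", 20, seed=2)
    fmap = cs.make_fragment_map(20, 3500)
    data = cs.simulate_5c(gold, fmap, params, cs.NoiseSpec(cv=0.1),
                          even_odd_mask=True, seed=7)
    return gold, fmap, data


@pytest.fixture
def small_hic(params):
    gold = cs.make_structure("random_walk", 8, seed=3)
    data = cs.simulate_hic(gold, params, total_reads=50_000, seed=4)
    return gold, data


def random_rotation(rng):
    """Haar-ish random proper rotation matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def rigid_motion(points, rng, reflect=False):
    rot = random_rotation(rng)
    if reflect:
        rot = rot @ np.diag([1.0, 1.0, -1.0])
    return points @ rot.T + rng.standard_normal(3) * 5.0
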