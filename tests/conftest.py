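import numpy as np
import pytest

from morphgaze import shape_core as sc
from morphgaze import synth as sy


@pytest.fixture(scope="session")
def template():
    return sy.make_template()


@pytest.fixture(scope="session")
def small_population(template):
    """30 faces with the default score-linked eyebrow displacement."""
    cfg = sy.SyntheticWorldConfig(n_faces=30, seed=11)
    configs, scores, truth = sy.sample_population(cfg, template)
    return configs, scores, truth


@pytest.fixture(scope="session")
def aligned_small(small_population):
    configs, _, _ = small_population
    return sc.gpa_align(configs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_similarity(rng):
    """A random rotation + positive scale + translation."""
    th = rng.uniform(0, 2 * np.pi)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    s = rng.uniform(0.3, 3.0)
    t = rng.uniform(-50, 50, 2)
    return lambda pts: pts @ R.T * s + t
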