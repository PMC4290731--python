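import numpy as np
import pytest

from dsfiber.fiber_model import resample
from dsfiber.synthetic_data import SyntheticConfig, generate_cohort, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_fiber(rng, k=12, scale=20.0):
    """A smooth random fiber: sorted random walk resampled to k points."""
    n = int(rng.integers(6, 15))
    pts = np.cumsum(rng.normal(0, scale / n, size=(n, 3)), axis=0)
    return resample(pts, k)


@pytest.fixture
def random_fiber_factory(rng):
    return lambda k=12: random_fiber(rng, k)


@pytest.fixture(scope="session")
def small_subject():
    """One synthetic subject: 5 well-separated bundles x 20 fibers, labels."""
    cfg = SyntheticConfig(n_bundles=5, fibers_per_bundle=20, seed=42)
    tractogram, labels = generate_subject(cfg)
    fibers = [resample(f, 12) for f in tractogram.fibers]
    return fibers, labels


@pytest.fixture(scope="session")
def small_cohort():
    """4-subject cohort of rigid copies of 6 bundles, with landmarks."""
    cfg = SyntheticConfig(
        n_subjects=4, n_bundles=6, fibers_per_bundle=20, point_jitter_sd=0.0, seed=7
    )
    return generate_cohort(cfg)
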