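import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_clip_instance(rng, n_max=64):
    """A random (r, phi, kappa) triple exercising ties and repeated phases."""
    n = int(rng.integers(1, n_max + 1))
    if rng.random() < 0.5:
        r = rng.choice([0.0, 0.5, 1.0, 2.0, 5.0], size=n)
    else:
        r = rng.random(n)
    if rng.random() < 0.5:
        dphi = rng.choice([0.0, 0.5, 1.0, 3.0], size=n - 1)
    else:
        dphi = rng.random(n - 1)
    phi = np.concatenate([[0.0], np.cumsum(dphi)])
    span = phi[-1] - phi[0]
    kappa = 0.0 if rng.random() < 0.1 else float(rng.random() * 1.5 * max(span, 1e-9))
    return r, phi, kappa
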