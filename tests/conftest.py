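import numpy as np
import pytest

from dtiseg import make_phantom


@pytest.fixture(scope="session")
def phantom():
    """Default 15x15 phantom: (field, truth_mask, seed_labels)."""
    return make_phantom()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_rotation(rng):
    """Haar-ish random rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_spd(rng, scale=1.0):
    a = rng.normal(size=(3, 3))
    return scale * (a @ a.T + 0.5 * np.eye(3))
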