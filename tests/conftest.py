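import numpy as np
import pytest

from kirgate import synth


@pytest.fixture(scope="session")
def default_channel():
    """One symmetric channel with known angles and apertures."""
    params = synth.ChannelParams(
        slide_elevation=20.0,
        inner_tilt=15.0,
        outer_tilt=25.0,
        aperture_124=5.0,
        aperture_132=4.0,
    )
    return synth.build_channel(params), params


@pytest.fixture(scope="session")
def small_ensemble():
    """100-frame ensemble from an even four-state mixture."""
    mixture = synth.StateMixture(probabilities=(0.25, 0.25, 0.25, 0.25))
    return synth.sample_ensemble(mixture, 100, seed=7)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
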