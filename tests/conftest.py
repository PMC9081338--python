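import numpy as np
import pytest

from fucci_cycle.synthetic import KineticsParams


@pytest.fixture
def noiseless_kinetics():
    return KineticsParams(noise_sd_frac=0.0)


@pytest.fixture
def default_kinetics():
    return KineticsParams()


def make_disc_image(
    centers,
    radii,
    shape=(200, 200),
    value=1000.0,
    background=100.0,
    noise_sd=0.0,
    gradient=0.0,
    seed=0,
):
    """Synthetic DNA-channel image of bright discs for segmentation tests."""
    from skimage.draw import disk as draw_disk

    rng = np.random.default_rng(seed)
    img = np.full(shape, background, dtype=float)
    if gradient:
        img += gradient * np.linspace(0, 1, shape[1])[None, :]
    for (r, c), rad in zip(centers, np.broadcast_to(radii, (len(centers),))):
        rr, cc = draw_disk((r, c), rad, shape=shape)
        img[rr, cc] += value
    if noise_sd:
        img += rng.normal(0, noise_sd, shape)
    return np.clip(img, 0, None)
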