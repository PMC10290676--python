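import numpy as np
import pytest

import holomorph as hm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def paper_geo():
    return hm.paper_geometry()


@pytest.fixture(scope="session")
def flat_scene():
    """Reference-geometry scene with sharp ('flat'-boundary) letter objects."""
    obj, truth = hm.make_object(hm.standard_scene("flat", seed=0))
    return obj, truth


@pytest.fixture(scope="session")
def flat_hologram(flat_scene, paper_geo):
    obj, _ = flat_scene
    return hm.forward_hologram(obj, paper_geo["z"])


def band_limited_field(rng, shape=(64, 64), pitch=5.86e-6, wavelength=500e-9,
                       keep=0.25):
    """Random field whose spectrum is confined to the central DFT band."""
    spec = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    spec[np.hypot(fy, fx) > keep * 0.5] = 0.0
    values = np.fft.ifft2(spec)
    return hm.ComplexField(values, pitch=pitch, wavelength=wavelength)
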