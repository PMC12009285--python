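import numpy as np
import pytest

from thermofuse import GrayImage, Lesion, PhantomSpec, generate_phantom


class ForcedRng:
    """Stand-in RNG whose uniform() returns preset values in order."""

    def __init__(self, values):
        self._values = list(values)

    def uniform(self, low=0.0, high=1.0, size=None):
        v = self._values.pop(0)
        if size is not None:
            return np.full(size, v)
        return v


@pytest.fixture
def forced_rng():
    return ForcedRng


@pytest.fixture
def lesion_phantom():
    """One noiseless single-lesion phantom with its ground truth."""
    spec = PhantomSpec(lesions=(Lesion((48, 48), 8.0, 60.0),), noise_sigma=0.0, seed=3)
    return generate_phantom(spec)


@pytest.fixture
def bimodal_image():
    """Two-level image: half at 50, half at 200."""
    pixels = np.full((20, 20), 50)
    pixels[10:] = 200
    return GrayImage(pixels, 8)


@pytest.fixture
def noisy_phantoms():
    """A small bank of seeded noisy phantoms (some normal, some abnormal)."""
    images = []
    for s in range(6):
        lesions = (Lesion((40 + s, 50), 7.0, 55.0),) if s % 2 else ()
        spec = PhantomSpec(lesions=lesions, seed=100 + s)
        images.append(generate_phantom(spec)[0])
    return images
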