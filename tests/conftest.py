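import numpy as np
import pytest

from tumourgrade import synth
from tumourgrade.quant import VolumeGrid


@pytest.fixture(scope="session")
def default_phantom():
    """One noiseless default phantom, shared read-only across tests."""
    return synth.gen_phantom(synth.PhantomSpec())


@pytest.fixture(scope="session")
def noisy_phantom():
    return synth.gen_phantom(
        synth.PhantomSpec(noise_sd_adc=0.05e-3, noise_sd_cbf=3.0, seed=11)
    )


def random_mask_and_map(rng, shape=(14, 14, 3)):
    """A random blobby mask with a random map, for oracle comparisons."""
    mask = np.zeros(shape, dtype=bool)
    for _ in range(rng.integers(1, 4)):
        c = rng.integers(3, np.array(shape[:2]) - 3, size=2)
        r = int(rng.integers(2, 6))
        k = int(rng.integers(0, shape[2]))
        ii, jj = np.ogrid[:shape[0], :shape[1]]
        mask[:, :, k] |= (ii - c[0]) ** 2 + (jj - c[1]) ** 2 <= r**2
    vals = rng.normal(1.0, 0.3, shape)
    spacing = (1.0, 1.0, 4.0)
    return (VolumeGrid(mask, spacing, "mask"),
            VolumeGrid(vals, spacing, "a.u."))
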