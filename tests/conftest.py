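import numpy as np
import pytest

from fibrotex.imaging_core import BinaryMask, ImageGrid, ImageStack, MaskedImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def grid8(pixels, pixel_size_um=1.0):
    """ImageGrid from any integer array, as 8-bit."""
    return ImageGrid(np.asarray(pixels, dtype=np.uint8), 8, pixel_size_um)


def fully_valid(image):
    """MaskedImage marking every pixel valid."""
    return MaskedImage(image, np.ones(image.shape, dtype=bool))


def stack_of(arrays, z_step_um=1.0, bit_depth=8, pixel_size_um=1.0):
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    planes = tuple(
        ImageGrid(np.asarray(a, dtype=dtype), bit_depth, pixel_size_um) for a in arrays
    )
    return ImageStack(planes, z_step_um)
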