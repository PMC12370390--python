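import numpy as np
import pytest

from osteotex import HUSlice


@pytest.fixture
def toy_image_4x4():
    """A small quantized-valued HU image with all four grey tones present."""
    return np.array(
        [
            [0, 0, 1, 1],
            [0, 2, 2, 1],
            [3, 2, 0, 0],
            [3, 3, 1, 2],
        ],
        dtype=float,
    )


@pytest.fixture
def constant_slice():
    """A uniform 600-HU region: the degenerate-texture corner case."""
    return HUSlice(pixels=np.full((8, 8), 600.0))


@pytest.fixture
def checkerboard_slice():
    """Alternating 300/900 HU pixels; maximal-contrast two-phase texture."""
    pix = np.indices((4, 4)).sum(axis=0) % 2
    return HUSlice(pixels=np.where(pix == 0, 300.0, 900.0))
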