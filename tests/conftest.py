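import numpy as np
import pytest

from somseg import ClassScheme, LabelMask, Patch, SlideRecord
from somseg.synthetic import synth_scheme


@pytest.fixture
def scheme() -> ClassScheme:
    return synth_scheme()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_slide(
    scheme: ClassScheme,
    size: int = 64,
    fill_code: int = 1,
    colour=(200, 60, 60),
    slide_id: str = "s0",
    mpp: float = 1.0,
) -> SlideRecord:
    """Uniform one-class slide used by unit tests."""
    image = np.zeros((size, size, 3), dtype=np.uint8)
    image[:] = colour
    mask = LabelMask(np.full((size, size), fill_code, dtype=np.int64), scheme)
    return SlideRecord(slide_id, image, mpp, label_mask=mask)


def make_patch(pixels: np.ndarray, mask_codes=None, scheme=None, slide_id="s0", origin=(0, 0)):
    mask = None
    if mask_codes is not None:
        mask = LabelMask(np.asarray(mask_codes), scheme)
    return Patch(slide_id, origin, np.asarray(pixels), mask)


@pytest.fixture
def uniform_slide(scheme) -> SlideRecord:
    return make_slide(scheme)
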