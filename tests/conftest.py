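import numpy as np
import pytest

from stereoccm.data_model import ImageMeta, NerveAnnotation


@pytest.fixture
def meta() -> ImageMeta:
    """Default acquisition frame: 380 px, 400 µm field of view."""
    return ImageMeta(image_id="img")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def simple_annotation() -> NerveAnnotation:
    """One horizontal 400-µm main fiber through the frame center."""
    return NerveAnnotation(
        image_id="img",
        main_fibers=[np.array([[0.0, 200.0], [400.0, 200.0]])],
    )
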