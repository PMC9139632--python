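import numpy as np
import pytest

from bmseg.volume_io import ImageVolume, LabelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_label(data, spacing=(1.0, 1.0, 1.0)):
    return LabelVolume(np.asarray(data, dtype=np.uint8), spacing)


def make_image(data, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(data, dtype=np.float64), spacing)


@pytest.fixture
def small_phantom_spec():
    """Fine-spacing small phantom for geometry-sensitive tests."""
    from bmseg.phantom import PhantomSpec

    return PhantomSpec(
        shape=(20, 96, 96),
        spacing=(1.0, 0.4, 0.4),
        n_lesions=3,
        lesion_volume_range_cc=(0.02, 0.2),
        n_vessels=2,
        seed=42,
    )
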