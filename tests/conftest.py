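import numpy as np
import pytest

from wmhgrade.phantom import LesionSpec, PhantomSpec, make_phantom
from wmhgrade.volume_io import LabelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)


@pytest.fixture(scope="session")
def two_lesion_phantom():
    """Small phantom with one clearly periventricular and one deep lesion."""
    spec = PhantomSpec(
        shape=(96, 112, 20),
        spacing=(1.5, 1.5, 6.0),
        brain_semiaxes_mm=(55.0, 70.0, 50.0),
        lesions=(
            LesionSpec(4.0, 3.0, "PVH", direction=(1.0, 0.0, 0.0)),
            LesionSpec(28.0, 6.0, "DWMH", direction=(0.0, 1.0, 0.0)),
        ),
    )
    return make_phantom(spec)


def random_mask(rng, shape, p=0.05) -> np.ndarray:
    """Random sparse binary mask, possibly empty."""
    return rng.random(shape) < p


def random_label_volume(rng, shape, spacing, p=0.05) -> LabelVolume:
    return LabelVolume(random_mask(rng, shape, p), spacing, int(np.argmax(spacing)))
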