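import numpy as np
import pytest

from hemdetect.synthfundus import FundusSpec, generate_fundus


@pytest.fixture(scope="session")
def small_spec() -> FundusSpec:
    """Compact fundus spec keeping unit tests fast; lesion sizes preserved."""
    return FundusSpec(
        image_size=320,
        retina_radius=140,
        n_hemorrhages=3,
        he_size_range=(8.0, 16.0),
        n_vessels=5,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_sample(small_spec):
    return generate_fundus(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def disc_image() -> np.ndarray:
    """Bright disc of radius 200 on black, 512x512 — analytic-area fixture."""
    yy, xx = np.mgrid[0:512, 0:512]
    disc = (yy - 256) ** 2 + (xx - 256) ** 2 <= 200**2
    img = np.zeros((512, 512), dtype=np.uint8)
    img[disc] = 200
    return img
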