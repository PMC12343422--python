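import numpy as np
import pytest

from hepavol.synthetic.phantom import PhantomSpec, make_liver_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One small noise-free phantom shared across tests."""
    spec = PhantomSpec(
        grid_shape=(48, 48, 48),
        spacing_mm=(3.0, 3.0, 3.0),
        target_hvvr_pct=2.1,
        target_pvvr_pct=1.7,
        noise_sigma=0.0,
        bias_field_amplitude=0.0,
        seed=7,
    )
    image, labels, gt = make_liver_phantom(spec)
    return spec, image, labels, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
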