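import numpy as np
import pytest

from mctl3d.synthetic import PhantomParams, generate_labeled_dataset


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """Phantom settings small enough for second-scale tests."""
    return PhantomParams(
        shape=(28, 28, 6),
        lesion_radius_range=(1.2, 2.0),
        lesion_contrast=0.3,
        noise_sigma=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(small_params):
    """Six labeled noisy phantoms (3 healthy, 3 lesion)."""
    return generate_labeled_dataset(3, 3, small_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
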