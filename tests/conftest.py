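import numpy as np
import pytest

from dwiseg import PhantomSpec, generate_phantom
from dwiseg.phantom import ConfounderSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    """Clean 32x32x8 phantom: bright ellipsoid tumor, mild Rician noise."""
    spec = PhantomSpec(
        shape=(32, 32, 8),
        tumor_semiaxes=(8.0, 8.0, 2.5),
        noise_sigma=15.0,
        seed=42,
    )
    return generate_phantom(spec)


@pytest.fixture
def confounder_spec():
    """Phantom spec whose confounder dwarfs the tumor (3x the volume)."""
    return PhantomSpec(
        shape=(64, 64, 16),
        tumor_center=(18, 18, 8),
        tumor_semiaxes=(7.0, 7.0, 3.0),
        confounder=ConfounderSpec(
            center=(45, 45, 8), semiaxes=(11.0, 11.0, 4.5), intensity=520.0
        ),
        noise_sigma=15.0,
        seed=7,
    )
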