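import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from helixtemp import BasePairFrame, HelixSpec


def rot_z(deg: float) -> np.ndarray:
    return Rotation.from_euler("z", deg, degrees=True).as_matrix()


def random_frame(rng: np.random.Generator, origin_scale: float = 10.0) -> BasePairFrame:
    triad = Rotation.random(random_state=rng).as_matrix()
    return BasePairFrame(rng.normal(0.0, origin_scale, 3), triad)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)


@pytest.fixture
def ideal_spec() -> HelixSpec:
    """Noiseless 27-bp helix: every step exactly 32.7 deg / 2.8 A."""
    return HelixSpec(
        n_bp=27,
        twist_per_step=32.7,
        rise_per_step=2.8,
        twist_sd=0.0,
        rise_sd=0.0,
        tilt_sd=0.0,
        twist_temp_slope=0.0,
        broken_pair_rate=0.0,
        n_snapshots=1,
        seed=1,
    )


@pytest.fixture
def noisy_spec() -> HelixSpec:
    """Fluctuating 33-bp helix at the default study conditions."""
    return HelixSpec(n_bp=33, n_snapshots=40, seed=7)
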