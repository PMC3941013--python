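import numpy as np
import pytest

from permion import ChannelParams, PMFProfile


@pytest.fixture(scope="session")
def params() -> ChannelParams:
    """Default channel physics: 300 K, 0.15 M KCl, bulk K+ diffusion."""
    return ChannelParams()


@pytest.fixture
def flat_profile():
    def make(n: int = 1025, L: float = 17.2) -> PMFProfile:
        z = np.linspace(0.0, L, n)
        return PMFProfile(z=z, w=np.zeros(n), tag="full_channel")

    return make


@pytest.fixture
def barrier_profile():
    def make(height: float, n: int = 1025, L: float = 17.2, width: float = 1.0) -> PMFProfile:
        z = np.linspace(0.0, L, n)
        w = height * np.exp(-((z - L / 2) ** 2) / (2 * width**2))
        return PMFProfile(z=z, w=w, tag="full_channel")

    return make


def regular_hexagon(radius: float = 1.0, rotation: float = 0.0) -> np.ndarray:
    ang = np.radians(np.arange(6) * 60.0) + rotation
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])


def stretched_hexagon(a: float = 1.2) -> np.ndarray:
    """The worked example: unit hexagon with x scaled by ``a``."""
    v = regular_hexagon()
    v[:, 0] *= a
    return v
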