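import numpy as np
import pytest

from meibomaps import PhantomSpec, WindowSpec, build_maps, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """Fast window spec used by unit tests (same defaults as the package)."""
    return WindowSpec()


@pytest.fixture(scope="session")
def perfect_phantom():
    """Distortion-free vertical stripe phantom, q*=0.1, theta*=90."""
    spec = PhantomSpec(height=200, width=280, base_frequency=0.1,
                       base_orientation=90.0, seed=1)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def perfect_maps(perfect_phantom):
    img, mask, _ = perfect_phantom
    return build_maps(img, mask)


def stripe_patch(size: int, q: float, theta_deg: float, binary: bool = True) -> np.ndarray:
    """Plain constant-frequency stripe patch used across tests."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    th = np.deg2rad(theta_deg)
    phase = 2 * np.pi * q * (xx * np.sin(th) - yy * np.cos(th))
    c = np.cos(phase)
    return (c >= 0).astype(float) if binary else c
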