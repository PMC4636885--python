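import numpy as np
import pytest

from sonopore import PistonTransducer, PlanarScan


@pytest.fixture(scope="session")
def tx() -> PistonTransducer:
    """The nominal device transducer: 20-mm aperture, 1 MHz, 37 degC bath."""
    return PistonTransducer(radius_mm=10.0, frequency_hz=1e6, sound_speed_m_s=1524.0)


@pytest.fixture
def make_scan():
    """Build a PlanarScan from an explicit pressure array on a symmetric grid."""

    def _make(pressure, spacing=0.7, z=15.0):
        pressure = np.asarray(pressure, dtype=float)
        nx, ny = pressure.shape
        x = (np.arange(nx) - (nx - 1) / 2) * spacing
        y = (np.arange(ny) - (ny - 1) / 2) * spacing
        return PlanarScan(z_mm=z, x_mm=x, y_mm=y, pressure=pressure)

    return _make
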