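import numpy as np
import pytest
from hypothesis import settings

from fdmesh import DeviceSpec, VesselModel

# derandomised hypothesis runs: the suite is reproducible in CI and locally
settings.register_profile("det", derandomize=True, max_examples=60)
settings.load_profile("det")


@pytest.fixture
def spec50() -> DeviceSpec:
    """Reference device: 4 mm, 20 mm, half angle 50 degrees."""
    return DeviceSpec(
        brand_label="ref50", phi_nom=4.0, L_nom=20.0, n_wires=48,
        S=0.5, omega=0.05, alpha_nom=50.0,
    )


@pytest.fixture
def spec62() -> DeviceSpec:
    """Steep-braid device (half angle 62°), closer to the bundled presets."""
    return DeviceSpec(
        brand_label="ref62", phi_nom=4.0, L_nom=20.0, n_wires=48,
        S=0.3, omega=0.045, alpha_nom=62.0,
    )


def straight_tube(radius: float, length: float = 60.0, ds: float = 0.5) -> VesselModel:
    n = round(length / ds)
    s = np.linspace(0.0, length, n + 1)
    pos = np.column_stack([s, np.zeros_like(s), np.zeros_like(s)])
    return VesselModel(s=s, pos=pos, radius=np.full(n + 1, radius))


def arc_tube(radius: float, kappa: float, length: float = 60.0,
             ds: float = 0.2) -> VesselModel:
    R = 1.0 / kappa
    n = round(length / ds)
    s = np.linspace(0.0, length, n + 1)
    pos = np.column_stack([R * np.sin(s / R), np.zeros_like(s),
                           R * (1.0 - np.cos(s / R))])
    return VesselModel(s=s, pos=pos, radius=np.full(n + 1, radius))


@pytest.fixture
def tube_factory():
    return straight_tube


@pytest.fixture
def arc_factory():
    return arc_tube
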