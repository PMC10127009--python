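import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tardisperm import simulate_sperm, single_cell_truth

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def param_sperm():
    """Noise-free Paramacrobiotus-preset cell: 2 s at 150 fps, 49.5 Hz beat,
    259.3 um/s straight swimming."""
    truth = single_cell_truth(
        species="Paramacrobiotus", speed=259.3, frequency=49.5,
        duration=2.0, fps=150.0, noise_sd=0.0, seed=7,
    )
    trace, track = simulate_sperm(truth)
    return truth, trace, track


@pytest.fixture(scope="session")
def short_sperm():
    """Small noise-free cell (0.2 s) for cheap I/O and windowing tests."""
    truth = single_cell_truth(
        species="M. shonaicus", speed=207.6, frequency=50.0,
        duration=0.2, fps=150.0, noise_sd=0.0, seed=3,
    )
    trace, track = simulate_sperm(truth, export_spacing=0.5)
    return truth, trace, track


def circle_polyline(radius, angle_span, n=4000, clockwise=False, center=(0.0, 0.0)):
    """Dense polyline along a circular arc starting at angle 0 (CCW default)."""
    ang = np.linspace(0.0, angle_span, n)
    if clockwise:
        ang = -ang
    return np.column_stack(
        [center[0] + radius * np.cos(ang - np.pi / 2),
         center[1] + radius * np.sin(ang - np.pi / 2)]
    )
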