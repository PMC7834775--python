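"""Shared fixtures: reduced-size simulation configs and canonical scenarios.

Tests run on a 2^16-point grid over 0-10 ppm (half the library default) —
fine enough that quadrature effects stay far below every asserted tolerance,
small enough that the whole suite stays fast.
"""

import pytest
from hypothesis import settings

from qnmr import SampleTruth, SimConfig
from qnmr.synthetic_data import default_analytes

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

GRID = 2**16


@pytest.fixture
def clean_cfg() -> SimConfig:
    """Noise- and baseline-free simulation config."""
    return SimConfig(grid_points=GRID, noise_sd=0.0, baseline_poly=(), seed=11)


@pytest.fixture
def noisy_cfg() -> SimConfig:
    """Default-noise, default-baseline config at test grid size."""
    return SimConfig(grid_points=GRID, seed=11)


@pytest.fixture
def analytes():
    return default_analytes()


@pytest.fixture
def mixed_truth() -> SampleTruth:
    """A tube with all three flavonoids at mid-calibration levels."""
    return SampleTruth(
        concentrations={"liquiritin": 1.0, "isoliquiritin": 0.8, "liquiritigenin": 0.6}
    )
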