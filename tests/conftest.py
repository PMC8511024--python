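import numpy as np
import pytest

from quenchbind import SimulationConfig, simulate_titration_series

#: Binding constants (M⁻¹) by temperature (K) for the reference
#: albumin-quinoline system, used as Van't Hoff inputs.
REFERENCE_KA = {290.0: 2.502e4, 300.0: 1.706e4, 310.0: 1.195e4}

#: Stern-Volmer constants (M⁻¹) by temperature for the same system.
REFERENCE_KSV = {290.0: 2.773e4, 300.0: 1.303e4, 310.0: 1.173e4}

#: The 11-point titration design, µM.
Q_GRID_UM = (0.0, 5.0, 10.0, 30.0, 50.0, 70.0, 90.0, 110.0, 130.0, 150.0, 170.0)


@pytest.fixture
def reference_ka():
    return dict(REFERENCE_KA)


@pytest.fixture
def reference_ksv():
    return dict(REFERENCE_KSV)


@pytest.fixture
def noiseless_series():
    """Noiseless static titrations on an exact Van't Hoff line (3 temperatures)."""
    cfg = SimulationConfig(noise_rel=0.0, seed=0)
    series, truth = simulate_titration_series(cfg)
    return series, truth


def gaussian_spectrum_values(grid, center, width, amplitude=1.0):
    grid = np.asarray(grid, dtype=float)
    return amplitude * np.exp(-0.5 * ((grid - center) / width) ** 2)
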