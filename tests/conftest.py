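import numpy as np
import pytest

from saskit import synthio
from saskit.sasio import ScatteringCurve


@pytest.fixture
def s_grid():
    """Default momentum-transfer grid, Å⁻¹."""
    return np.linspace(1e-3, 0.4, 400)


@pytest.fixture
def sphere30(s_grid):
    """Analytic solid-sphere curve, R = 30 Å, I0 = 1000."""
    return synthio.sphere_curve(30.0, s_grid, i0=1000.0)


@pytest.fixture
def guinier20(s_grid):
    """Pure Guinier-law curve, Rg = 20 Å, I0 = 1000."""
    return synthio.guinier_curve(20.0, s_grid, i0=1000.0)


@pytest.fixture
def beads100():
    """100-bead random model in a 25 Å spherical envelope."""
    return synthio.random_bead_model(100, envelope_radius=25.0, seed=11)


def with_noise(curve: ScatteringCurve, rng, relative=0.01) -> ScatteringCurve:
    nm = synthio.NoiseModel(relative=relative, floor=1e-6 * float(np.max(curve.I)))
    return nm.apply(curve, rng)
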