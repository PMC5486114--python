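import numpy as np
import pytest

from nmrbind.corcema import CorcemaConditions, SpinSystem


@pytest.fixture
def toy_conditions() -> CorcemaConditions:
    """Benchmark simulation conditions (30 µM / 1.5 mM, Kd 10 µM, 600 MHz)."""
    return CorcemaConditions()


@pytest.fixture
def four_spin_system() -> SpinSystem:
    """Fixed 4-spin complex (2 ligand + 2 protein protons) used by the
    ODE-oracle and method-independence tests."""
    coords = np.array(
        [
            [0.0, 0.0, 0.0],  # L1
            [2.4, 0.3, 0.1],  # L2
            [0.5, 2.9, 0.2],  # P1
            [2.7, 3.1, -0.3],  # P2
        ]
    )
    return SpinSystem(
        labels=["L1", "L2", "P1", "P2"],
        owners=["ligand", "ligand", "protein", "protein"],
        coords_bound=coords,
        saturated=np.array([False, False, True, True]),
    )
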