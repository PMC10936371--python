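import numpy as np
import pytest

from snapsole import ArchGeometry, Material, nondimensionalize
from snapsole.pedomap import synth_gait

#: reference arch used throughout: Q = 3, mid design band
FIXTURE_L = 30e-3
FIXTURE_W = 1e-3
FIXTURE_B = 10e-3
FIXTURE_H = 3e-3
FIXTURE_E = 26e6
FIXTURE_RHO = 1210.0

#: shape-parameter grid spanning the well-conditioned snap-through band:
#: above the bifurcation threshold (~1.65, with margin so the strong
#: anharmonic mode coupling of shallow arches has decayed) and below the
#: near-separatrix regime where the return slows critically
Q_GRID = np.linspace(2.4, 3.2, 10)


@pytest.fixture(scope="session")
def fixture_arch():
    geom = ArchGeometry(L=FIXTURE_L, w=FIXTURE_W, b=FIXTURE_B, h_mid=FIXTURE_H)
    mat = Material(youngs_modulus=FIXTURE_E, density=FIXTURE_RHO)
    return geom, mat


@pytest.fixture(scope="session")
def fixture_nd(fixture_arch):
    return nondimensionalize(*fixture_arch)


def arch_with_Q(Q: float, b: float = FIXTURE_B) -> ArchGeometry:
    """Fixture-family arch with a prescribed shape parameter (h_mid = Q w)."""
    return ArchGeometry(L=FIXTURE_L, w=FIXTURE_W, b=b, h_mid=Q * FIXTURE_W)


@pytest.fixture(scope="session")
def fixture_material():
    return Material(youngs_modulus=FIXTURE_E, density=FIXTURE_RHO)


@pytest.fixture(scope="session")
def gait42():
    """Reference synthetic subject: 55 kg, size 6, seed 42."""
    return synth_gait(weight_kg=55.0, foot_size_in=6.0, seed=42)
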