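"""Shared fixtures.

Expensive magnetization solves are session-scoped and shared across
tests; the small (12, 3, 1) grid is used for property checks -- the
crosstalk percentages it yields are within ~0.1 points of the default
(24, 6, 1) production grid.
"""

import numpy as np
import pytest

import mearray as m

SMALL_GRID = (12, 3, 1)
FULL_GRID = (24, 6, 1)
SPACINGS = (5e-3, 10e-3, 20e-3, 50e-3)


@pytest.fixture(scope="session")
def sensor():
    return m.build_sensor()

@pytest.fixture(scope="session")
def beam(sensor):
    return m.CompositeBeam.from_sensor(sensor)


@pytest.fixture(scope="session")
def head():
    return m.make_sphere_head()


@pytest.fixture(scope="session")
def homogeneous_sweep_small():
    """Full 3x5 array, all four spacings, 12x3x1 cells per layer."""
    return m.run_homogeneous_sweep(spacings=SPACINGS, resolution=SMALL_GRID)


@pytest.fixture(scope="session")
def homogeneous_sweep_full():
    """Full 3x5 array at the production grid, closest/farthest spacings."""
    return m.run_homogeneous_sweep(spacings=(5e-3, 50e-3), resolution=FULL_GRID)


@pytest.fixture(scope="session")
def subarray_sweeps_full():
    """1x5 row and 3x1 column sweeps at the production grid."""
    row = m.run_homogeneous_sweep(spacings=(5e-3, 50e-3), rows=1, cols=5, resolution=FULL_GRID)
    col = m.run_homogeneous_sweep(spacings=(5e-3, 50e-3), rows=3, cols=1, resolution=FULL_GRID)
    return row, col


@pytest.fixture(scope="session")
def dipole_sweep_small(head):
    return m.run_dipole_sweep(spacings=SPACINGS, resolution=SMALL_GRID, head=head)
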