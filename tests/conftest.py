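"""Shared fixtures: coarse meshes, phase tables and wall fields.

The expensive boundary-element artifacts are session-scoped and built at
reduced resolution (coarse meshes, few beat phases, small grids); tests
that probe convergence build their own finer variants.
"""

import math

import numpy as np
import pytest

import shearswim as ss
from shearswim import phase as ph
from shearswim.geometry import build_spheroid_mesh


@pytest.fixture(scope="session")
def promastigote() -> ss.SwimmerConfig:
    return ss.SwimmerConfig()


@pytest.fixture(scope="session")
def pusher() -> ss.SwimmerConfig:
    return ss.make_fixture("pusher").swimmer_config()


@pytest.fixture(scope="session")
def coarse_table(promastigote) -> ph.BulkPhaseTable:
    """Bulk phase table at the coarse mesh level, 8 beat phases."""
    return ph.BulkPhaseTable(promastigote, n_phases=8, refinement=0)


@pytest.fixture(scope="session")
def pusher_table(pusher) -> ph.BulkPhaseTable:
    return ph.BulkPhaseTable(pusher, n_phases=8, refinement=0)


@pytest.fixture(scope="session")
def wall_field(promastigote) -> ph.PhaseField:
    """Coarse wall phase field; h extends high enough for washout loops."""
    th = np.linspace(0.0, 2.0 * math.pi, 16, endpoint=False)
    h = np.geomspace(2.5, 120.0, 12)
    return ph.wall_phase_field(th, h, promastigote, n_phases=6, refinement=0)


@pytest.fixture(scope="session")
def sphere_mesh():
    return build_spheroid_mesh(1.0, 1.0, n_az=14, n_rings=14)


@pytest.fixture(scope="session")
def spheroid_mesh_r3():
    return build_spheroid_mesh(3.0, 1.0, n_az=14, n_rings=20)
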