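"""Short-range repulsive wall forces of steric origin.

A boundary can be *passive* (no-slip only; trajectories halt at ~2 nm
clearance) or *repulsive*, carrying a force per unit area on the swimmer
surface directed along the outward wall normal n̂ = x̂1:

    f_wall(s) = g (μ/T_d) e^{−s/l} / (1 − e^{−s/l}) n̂,

where s is the local separation from the wall, g = 1250 a dimensionless
strength (strong relative to the other scales of the model), l = 0.2 μm a
decay length much smaller than the cell, μ the fluid viscosity and T_d the
flagellar beat period.  The force diverges at contact and is negligible a
few decay lengths out.  It enters the dynamics only through the net
external force and torque in the rigid-body balance; the swimmer is not
deformed by it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WallRepulsion", "repulsion_density", "net_wall_load"]

#: outward normal of the wall plane x1 = 0
WALL_NORMAL = np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class WallRepulsion:
    """Parameters of the repulsive boundary force.

    ``strength`` g is dimensionless, ``decay_length`` l in μm,
    ``beat_period`` T_d in seconds (1/f for the beating swimmer).
    """

    strength: float = 1250.0
    decay_length: float = 0.2
    beat_period: float = 1.0 / 28.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.strength <= 0 or self.decay_length <= 0 or self.beat_period <= 0:
            raise ValueError("repulsion strength, decay length and beat period must be positive")


def repulsion_density(s, rep: WallRepulsion, mu: float) -> np.ndarray:
    """Repulsive force per unit area at separation(s) ``s`` (μm), Pa·(x̂1).

    Returns an array of shape ``s.shape + (3,)`` directed along the outward
    wall normal.  Separations must be strictly positive: contact itself is
    handled by the 2 nm collision halt of the dynamics when repulsion is
    disabled.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0.0):
        raise ValueError("wall separation must be strictly positive")
    x = np.exp(-s / rep.decay_length)
    mag = rep.strength * (mu / rep.beat_period) * x / (1.0 - x)
    return mag[..., None] * WALL_NORMAL


def net_wall_load(mesh, state, rep: WallRepulsion, mu: float) -> tuple[np.ndarray, np.ndarray]:
    """Net repulsive force and torque (about x0) on the swimmer surface.

    Element-centroid quadrature of :func:`repulsion_density` over the
    laboratory-frame surface, consistent with the piecewise-constant BEM
    discretization.  Raises if any element centroid lies behind the wall.
    """
    R = state.rotation_matrix
    centroids = mesh.centroids @ R.T + state.x0
    areas = mesh.areas
    s = centroids[:, 0]
    if np.any(s <= 0.0):
        raise ValueError("swimmer element behind the wall plane x1=0")
    if not rep.enabled:
        return np.zeros(3), np.zeros(3)
    dens = repulsion_density(s, rep, mu)
    f_el = dens * areas[:, None]
    force = f_el.sum(axis=0)
    torque = np.cross(centroids - state.x0, f_el).sum(axis=0)
    return force, torque
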