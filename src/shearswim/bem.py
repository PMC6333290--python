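"""First-kind single-layer boundary-element mobility solver.

The swimmer surface velocity is kinematically prescribed (rigid body motion
plus the flagellar beat), so the disturbance flow admits a single-layer
representation

    u_d(x) = −(1/8πμ) ∫_S G(x, y) q(y) dS(y),

with G the free-space Oseen tensor or the Blake wall tensor.  The density q
is the jump in traction across the surface and integrates to the net
hydrodynamic load, so force- and torque-free swimming closes the system:

    −(1/8πμ) Σ_e ∫_e G q_e − U − Ω×(x_c − x0) = u_beat(x_c) − u_b(x_c)
    Σ_e q_e A_e = −F_ext,   Σ_e (x̄_e − x0)×q_e A_e = −T_ext.

Collocation at element centroids with piecewise-constant tractions gives a
dense (3N+6) system solved by LU factorization; the factorization is reused
across right-hand sides (different beat velocities, background flows or
external loads on the same geometry), which is what makes phase averaging
and shear-rate sweeps cheap.

The single layer on a closed surface is blind to the constant-normal
density (it generates no exterior flow), so a rank-one deflation along that
mode is added for conditioning; it leaves velocities, loads, and the
exterior flow unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .kernels import assemble_single_layer
from .walls import WallRepulsion

__all__ = [
    "FlowModel",
    "MobilitySolution",
    "MobilityProblem",
    "WallContactError",
    "solve_mobility",
    "WATER_VISCOSITY_25C",
]


class WallContactError(ValueError):
    """The swimmer surface touches or crosses the wall plane x1 = 0."""

#: dynamic viscosity of water at 25 °C, Pa·s
WATER_VISCOSITY_25C = 8.9e-4


@dataclass(frozen=True)
class FlowModel:
    """Background linear shear flow, wall presence and fluid viscosity.

    ``bulk_shear`` is u_b = γ_d (x̂2, 0, 0); ``wall_shear`` is
    u_b = γ_d (0, −x̂1, 0), which vanishes on the no-slip plane x̂1 = 0.
    ``uniform`` adds a constant background velocity (verification flows).
    Viscosity is water at 25 °C by default.  Lengths μm, times s, μ in Pa·s.
    """

    gamma_d: float = 0.0
    geometry: Literal["bulk_shear", "wall_shear"] = "bulk_shear"
    viscosity: float = WATER_VISCOSITY_25C
    wall_present: bool = False
    repulsion: Optional[WallRepulsion] = None
    uniform: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.geometry not in ("bulk_shear", "wall_shear"):
            raise ValueError(f"unknown flow geometry {self.geometry!r}")
        if self.geometry == "wall_shear" and not self.wall_present:
            raise ValueError("wall_shear flow requires wall_present=True")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if self.repulsion is not None and not self.wall_present:
            raise ValueError("wall repulsion requires wall_present=True")

    @property
    def gradient(self) -> np.ndarray:
        """Velocity gradient tensor Γ with u_b = uniform + Γ·x."""
        g = np.zeros((3, 3))
        if self.geometry == "bulk_shear":
            g[0, 1] = self.gamma_d
        else:
            g[1, 0] = -self.gamma_d
        return g

    def velocity(self, x: np.ndarray) -> np.ndarray:
        """Background velocity at laboratory points x (…, 3)."""
        x = np.asarray(x, dtype=float)
        return np.asarray(self.uniform) + x @ self.gradient.T


@dataclass
class MobilitySolution:
    """Rigid-body velocities, surface tractions and solver diagnostics."""

    U: np.ndarray
    Omega: np.ndarray
    tractions: np.ndarray
    residual: float

    def total_force(self, areas: np.ndarray) -> np.ndarray:
        return (self.tractions * areas[:, None]).sum(axis=0)

    def total_torque(self, centroids: np.ndarray, x0: np.ndarray, areas: np.ndarray) -> np.ndarray:
        r = centroids - x0
        return (np.cross(r, self.tractions) * areas[:, None]).sum(axis=0)


def _skew(r: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -r[2], r[1]], [r[2], 0.0, -r[0]], [-r[1], r[0], 0.0]])


class MobilityProblem:
    """Assembled and factorized mobility system for one rigid configuration.

    Parameters are laboratory-frame geometry: triangle vertices (N, 3, 3),
    the reference point ``x0`` about which torques are taken (the flagellar
    attachment point), viscosity, and whether the Blake wall kernel is used.
    ``solve`` may then be called repeatedly with different surface beat
    velocities, background flows and external loads.
    """

    def __init__(
        self,
        verts: np.ndarray,
        x0: np.ndarray,
        viscosity: float,
        wall: bool = False,
        eta: float = 3.0,
        max_depth: int = 3,
    ):
        verts = np.asarray(verts, dtype=float)
        self.n = len(verts)
        self.verts = verts
        self.x0 = np.asarray(x0, dtype=float)
        self.mu = viscosity
        self.wall = wall
        self.centroids = verts.mean(axis=1)
        cr = np.cross(verts[:, 1] - verts[:, 0], verts[:, 2] - verts[:, 0])
        self.areas = 0.5 * np.linalg.norm(cr, axis=1)
        self.normals = cr / (2.0 * self.areas[:, None])

        n = self.n
        G = assemble_single_layer(verts, self.centroids, wall=wall, eta=eta, max_depth=max_depth)
        A = np.zeros((3 * n + 6, 3 * n + 6))
        A[: 3 * n, : 3 * n] = -G / (8.0 * np.pi * self.mu)
        r = self.centroids - self.x0
        for c in range(n):
            A[3 * c : 3 * c + 3, 3 * n : 3 * n + 3] = -np.eye(3)
            A[3 * c : 3 * c + 3, 3 * n + 3 :] = _skew(r[c])
        # load closure rows
        for e in range(n):
            A[3 * n : 3 * n + 3, 3 * e : 3 * e + 3] = self.areas[e] * np.eye(3)
            A[3 * n + 3 :, 3 * e : 3 * e + 3] = self.areas[e] * _skew(r[e])
        # rank-one deflation of the invisible constant-normal density
        nvec = np.zeros(3 * n + 6)
        nvec[: 3 * n] = (self.normals * self.areas[:, None]).reshape(-1)
        nvec /= np.linalg.norm(nvec)
        scale = np.abs(np.diag(A)[: 3 * n]).mean()
        A += scale * np.outer(nvec, nvec)
        self._matrix = A
        self._lu = lu_factor(A)

    def solve(
        self,
        surface_velocity: np.ndarray,
        external_force: np.ndarray | None = None,
        external_torque: np.ndarray | None = None,
    ) -> MobilitySolution:
        """Solve for tractions and rigid-body velocities.

        ``surface_velocity`` is the prescribed non-rigid surface velocity at
        the collocation points minus the background flow there, i.e.
        u_beat,lab(x_c) − u_b(x_c), shape (N, 3).
        """
        n = self.n
        rhs = np.zeros(3 * n + 6)
        rhs[: 3 * n] = np.asarray(surface_velocity, dtype=float).reshape(-1)
        if external_force is not None:
            rhs[3 * n : 3 * n + 3] = -np.asarray(external_force, dtype=float)
        if external_torque is not None:
            rhs[3 * n + 3 :] = -np.asarray(external_torque, dtype=float)
        sol = lu_solve(self._lu, rhs)
        resid = float(np.linalg.norm(self._matrix @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))
        return MobilitySolution(
            U=sol[3 * n : 3 * n + 3],
            Omega=sol[3 * n + 3 :],
            tractions=sol[: 3 * n].reshape(n, 3),
            residual=resid,
        )

    def solve_resistance(self, surface_velocity: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Resistance mode: prescribe the full surface velocity, return
        (force, torque, tractions) the fluid exerts on the body.

        Solves the pure first-kind system Σ K q = u_s with no rigid-body
        unknowns: the rigid velocity columns are pinned by prescribing U = Ω
        = 0 and supplying u_s directly as the surface data.
        """
        n = self.n
        K = self._matrix[: 3 * n, : 3 * n]
        q = np.linalg.solve(K, np.asarray(surface_velocity, dtype=float).reshape(-1)).reshape(n, 3)
        force = (q * self.areas[:, None]).sum(axis=0)
        torque = (np.cross(self.centroids - self.x0, q) * self.areas[:, None]).sum(axis=0)
        return force, torque, q


def solve_mobility(
    mesh,
    state,
    flow: FlowModel,
    external_force: np.ndarray | None = None,
    external_torque: np.ndarray | None = None,
) -> MobilitySolution:
    """One-shot mobility solve for a swimmer mesh in a given state and flow.

    ``mesh`` is a swimmer-frame :class:`~shearswim.geometry.SurfaceMesh`;
    ``state`` a :class:`~shearswim.dynamics.SwimmerState` providing the
    laboratory placement.  Returns laboratory-frame (U, Ω) of the
    attachment point and element tractions.
    """
    R = state.rotation_matrix
    verts_lab = mesh.vertices_per_triangle @ R.T + state.x0
    if flow.wall_present and verts_lab[..., 0].min() <= 0.0:
        raise WallContactError("swimmer penetrates the wall plane x1=0")
    prob = MobilityProblem(verts_lab, state.x0, flow.viscosity, wall=flow.wall_present)
    u_beat_lab = mesh.centroid_velocities @ R.T
    u_s = u_beat_lab - flow.velocity(prob.centroids)
    return prob.solve(u_s, external_force, external_torque)
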