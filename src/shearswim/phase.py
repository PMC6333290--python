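"""Phase-averaged reduced dynamics, Jeffery fits and phase-plane analysis.

Averaging the mobility solve over the flagellar beat (typically 20 or 40
equispaced phases at frozen position and orientation) turns the
beat-resolved dynamics into an autonomous reduced system: a single
clockwise angle θ between the swimmer axis and the laboratory x̂1 axis in
the bulk, and the pair (θ, h) near a plane wall, h being the distance of
the flagellar attachment point from the wall.

Because Stokes flow is linear, the phase-averaged response at any shear
rate decomposes as (swim part at γ = 0) + γ × (unit-shear passive
response); bulk sweeps additionally exploit frame invariance, so one
factorization per beat phase covers every orientation and shear rate
(:class:`BulkPhaseTable`).

The bulk angular dynamics closely follow the Jeffery orbit of a passive
prolate spheroid.  For a spheroid of aspect ratio r in shear of rate γ, the
in-plane rate with θ measured (clockwise) from the flow axis is

    θ̇ = γ (r² sin²θ + cos²θ) / (r² + 1),

with closed orbit period T = (2π/γ)(r + 1/r); fitting that period law over
several shear rates yields the swimmer's effective aspect ratio.

Near a wall the phase-averaged field (θ̇, ḣ) generically has a saddle point
in 0 < θ < π/2 whose stable manifold closes into a homoclinic separatrix
dividing collision-bound from bulk-bound configurations; its h-position
falls with increasing shear, defining a critical shear rate at which the
saddle approaches the wall to within a beat amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.interpolate import CubicSpline, RectBivariateSpline
from scipy.optimize import least_squares

from .bem import FlowModel, MobilityProblem
from .dynamics import SwimmerState
from .geometry import SurfaceMesh, SwimmerConfig, build_mesh

__all__ = [
    "ReducedStateBulk",
    "ReducedStateWall",
    "BulkPhaseTable",
    "PhaseField",
    "JefferyFit",
    "PhasePlaneAnalysis",
    "SaddlePoint",
    "jeffery_theta_dot",
    "jeffery_period",
    "phase_average",
    "bulk_angular_rate",
    "rotation_period",
    "fit_jeffery_ratio",
    "period_vs_bodyscale",
    "wall_phase_field",
    "find_saddle",
    "compute_separatrix",
    "critical_shear",
]


class SymmetryError(RuntimeError):
    """Out-of-plane leakage above tolerance in a nominally planar problem."""


@dataclass(frozen=True)
class ReducedStateBulk:
    """Planar bulk configuration: clockwise angle θ of the swimmer axis."""

    theta: float

    def to_state(self, x0=(0.0, 0.0, 0.0)) -> SwimmerState:
        return SwimmerState.from_planar(self.theta, x0=x0)


@dataclass(frozen=True)
class ReducedStateWall:
    """Planar wall configuration: angle θ and wall separation h > 0 (μm)."""

    theta: float
    h: float

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("wall separation h must be positive")

    def to_state(self) -> SwimmerState:
        return SwimmerState.from_wall_coordinates(self.theta, self.h)


# --------------------------------------------------------------------------
# Jeffery orbit closed forms (passive prolate spheroid, flow plane)
# --------------------------------------------------------------------------


def jeffery_theta_dot(theta, gamma_d: float, r: float):
    """In-plane Jeffery angular rate, θ clockwise from the flow axis x̂1.

    Slowest when flow-aligned (θ = 0, π), fastest broadside on.
    """
    if r <= 0:
        raise ValueError("aspect ratio must be positive")
    theta = np.asarray(theta, dtype=float)
    return gamma_d * (r**2 * np.sin(theta) ** 2 + np.cos(theta) ** 2) / (r**2 + 1.0)


def jeffery_period(gamma_d: float, r: float) -> float:
    """Jeffery orbit period T = (2π/γ)(r + 1/r)."""
    if gamma_d <= 0:
        raise ValueError("gamma_d must be positive for a closed orbit")
    return 2.0 * math.pi / gamma_d * (r + 1.0 / r)


def jeffery_orbit(t, gamma_d: float, r: float, theta0: float = 0.0):
    """Closed-form Jeffery orbit θ(t) with θ̇ = γ(r²sin²θ + cos²θ)/(r²+1).

    The separable solution is tan θ = tan(ψ)/r with orbit phase
    ψ = 2πt/T + ψ0, unwrapped to a continuous monotone angle.
    """
    t = np.asarray(t, dtype=float)
    T = jeffery_period(gamma_d, r)
    th0_frac = theta0 % math.pi
    if abs(th0_frac - math.pi / 2) < 1e-15:
        psi0 = math.pi / 2
    else:
        psi0 = math.atan(r * math.tan(th0_frac))
        if th0_frac > math.pi / 2:
            psi0 += math.pi
    x = 2.0 * math.pi * t / T + psi0
    k = np.floor((x + math.pi / 2) / math.pi)
    th = np.arctan(np.tan(x - k * math.pi) / r) + k * math.pi
    # shift so that th(0) == theta0 exactly (unwrap base)
    th00 = math.atan2(math.sin(psi0) / r, math.cos(psi0))
    return (theta0 - th00) + th


# --------------------------------------------------------------------------
# Phase averaging
# --------------------------------------------------------------------------


def _phase_meshes(config: SwimmerConfig, n_phases: int, refinement: int) -> list[SurfaceMesh]:
    return [build_mesh(config, p, refinement=refinement) for p in np.arange(n_phases) / n_phases]


def phase_average(
    config: SwimmerConfig,
    state: SwimmerState | ReducedStateBulk | ReducedStateWall | float,
    flow: FlowModel,
    n_phases: int = 20,
    refinement: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Beat-averaged laboratory-frame (U, Ω) at a frozen configuration.

    Arithmetic mean of the mobility solution over ``n_phases`` equispaced
    beat phases.  ``state`` may be a full :class:`SwimmerState`, a reduced
    bulk angle (float or :class:`ReducedStateBulk`) or a wall configuration.
    """
    if n_phases < 2:
        raise ValueError("n_phases must be at least 2")
    if isinstance(state, (int, float)):
        state = SwimmerState.from_planar(float(state))
    elif isinstance(state, (ReducedStateBulk, ReducedStateWall)):
        state = state.to_state()
    R = state.rotation_matrix
    U_acc = np.zeros(3)
    W_acc = np.zeros(3)
    for mesh in _phase_meshes(config, n_phases, refinement):
        verts_lab = mesh.vertices_per_triangle @ R.T + state.x0
        prob = MobilityProblem(verts_lab, state.x0, flow.viscosity, wall=flow.wall_present)
        u_s = mesh.centroid_velocities @ R.T - flow.velocity(prob.centroids)
        sol = prob.solve(u_s)
        U_acc += sol.U
        W_acc += sol.Omega
    return U_acc / n_phases, W_acc / n_phases


_BASIS = [(a, b) for a in range(3) for b in range(3)]


class BulkPhaseTable:
    """Swimmer-frame mobility responses enabling cheap bulk sweeps.

    For each beat phase, solves once for the beat-driven swim response and
    once per unit velocity-gradient basis tensor.  By frame invariance and
    Stokes linearity, the phase-averaged (U, Ω) at any planar orientation θ
    and shear rate γ then follows without further boundary-element solves:

        U_lab(θ, γ) = R(θ) [ Ū0 + ĀU : (Rᵀ Γ R) ],   Γ = γ x̂1⊗x̂2,

    and likewise for Ω.  One matrix factorization per phase.
    """

    def __init__(
        self,
        config: SwimmerConfig,
        n_phases: int = 20,
        refinement: int = 1,
    ):
        if n_phases < 2:
            raise ValueError("n_phases must be at least 2")
        self.config = config
        self.n_phases = n_phases
        self.refinement = refinement
        flow_mu = FlowModel().viscosity
        P = n_phases
        self.U0 = np.zeros((P, 3))
        self.W0 = np.zeros((P, 3))
        self.AU = np.zeros((P, 3, 3, 3))  # response of U to unit gradient e_a ⊗ e_b
        self.AW = np.zeros((P, 3, 3, 3))
        for ip, mesh in enumerate(_phase_meshes(config, n_phases, refinement)):
            prob = MobilityProblem(mesh.vertices_per_triangle, np.zeros(3), flow_mu)
            sol = prob.solve(mesh.centroid_velocities)
            self.U0[ip] = sol.U
            self.W0[ip] = sol.Omega
            xc = prob.centroids
            for a, b in _BASIS:
                u_s = np.zeros_like(xc)
                u_s[:, a] = -xc[:, b]  # disturbance data for u_b = (e_a ⊗ e_b)·x
                solg = prob.solve(u_s)
                self.AU[ip, :, a, b] = solg.U
                self.AW[ip, :, a, b] = solg.Omega
        self.U0_mean = self.U0.mean(axis=0)
        self.W0_mean = self.W0.mean(axis=0)
        self.AU_mean = self.AU.mean(axis=0)
        self.AW_mean = self.AW.mean(axis=0)

    @staticmethod
    def _rotation(theta: float) -> np.ndarray:
        c, s = math.cos(theta), math.sin(theta)
        return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])

    def average(self, theta: float, gamma_d: float, geometry: str = "bulk_shear") -> tuple[np.ndarray, np.ndarray]:
        """Phase-averaged laboratory (U, Ω) at orientation θ, shear γ.

        The uniform advection γ·(x̂2·x0) x̂1 of the attachment point is not
        included (it depends on position, not orientation); callers add
        flow.velocity(x0).
        """
        R = self._rotation(theta)
        Gam = np.zeros((3, 3))
        if geometry == "bulk_shear":
            Gam[0, 1] = gamma_d
        elif geometry == "wall_shear":
            Gam[1, 0] = -gamma_d
        else:
            raise ValueError(f"unknown geometry {geometry!r}")
        Gam_sw = R.T @ Gam @ R
        U = R @ (self.U0_mean + np.einsum("iab,ab->i", self.AU_mean, Gam_sw))
        W = R @ (self.W0_mean + np.einsum("iab,ab->i", self.AW_mean, Gam_sw))
        return U, W

    def swim_speed(self) -> float:
        """Phase-averaged free-space swimming speed |⟨U⟩| (μm/s)."""
        return float(np.linalg.norm(self.U0_mean))

    def theta_dot(self, theta, gamma_d: float) -> np.ndarray:
        """Reduced bulk angular rate θ̇(θ) (clockwise positive)."""
        theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
        out = np.empty_like(theta_arr)
        for i, th in enumerate(theta_arr):
            _, W = self.average(th, gamma_d)
            out[i] = -W[2]
        return out if np.ndim(theta) else float(out[0])

    def planar_velocity(self, theta: float, gamma_d: float) -> np.ndarray:
        """In-plane phase-averaged swim velocity (U1, U2), excluding advection."""
        U, _ = self.average(theta, gamma_d)
        return U[:2]


def bulk_angular_rate(
    theta: float,
    gamma_d: float,
    config: SwimmerConfig,
    table: Optional[BulkPhaseTable] = None,
    n_phases: int = 20,
    refinement: int = 1,
    leakage_tol: float = 0.1,
) -> float:
    """Phase-averaged in-plane rotation rate θ̇ (rad/s, clockwise positive).

    The beat plane must coincide with the shear plane; out-of-plane
    components of the averaged angular velocity beyond ``leakage_tol``
    relative to the problem's rotation scale raise :class:`SymmetryError`.
    (The structured triangulation carries a small fixed chiral roll, so the
    scale is the larger of the local rate and the shear vorticity γ/2.)
    """
    if table is None:
        table = BulkPhaseTable(config, n_phases=n_phases, refinement=refinement)
    _, W = table.average(theta, gamma_d)
    inplane = abs(W[2])
    leak = math.hypot(W[0], W[1])
    scale = max(inplane, 0.5 * abs(gamma_d))
    if scale > 0 and leak > leakage_tol * scale:
        raise SymmetryError(f"out-of-plane angular leakage {leak:.2e} vs rotation scale {scale:.2e}")
    return float(-W[2])


def rotation_period(
    gamma_d: float,
    config: SwimmerConfig,
    table: Optional[BulkPhaseTable] = None,
    n_theta: int = 36,
    n_phases: int = 20,
    refinement: int = 1,
) -> float:
    """Tumbling period T = ∮ dθ/θ̇ of the reduced bulk dynamics.

    Samples θ̇ at ``n_theta`` angles, builds a periodic cubic interpolant
    and integrates adaptively.  Raises if θ̇ changes sign (not tumbling).
    """
    if table is None:
        table = BulkPhaseTable(config, n_phases=n_phases, refinement=refinement)
    thetas = np.linspace(0.0, 2.0 * math.pi, n_theta + 1)
    rates = table.theta_dot(thetas[:-1], gamma_d)
    if np.any(rates <= 0) and np.any(rates >= 0) and rates.min() * rates.max() <= 0:
        raise ValueError("theta_dot changes sign: swimmer is not in the tumbling regime")
    vals = np.concatenate([rates, [rates[0]]])
    spline = CubicSpline(thetas, vals, bc_type="periodic")
    period, _ = quad(lambda th: 1.0 / spline(th), 0.0, 2.0 * math.pi, limit=200)
    return abs(float(period))


@dataclass
class JefferyFit:
    """Effective Jeffery aspect ratio fitted from rotation periods."""

    r: float
    residual: float
    gamma_grid: np.ndarray
    periods: np.ndarray

    def period(self, gamma_d: float) -> float:
        return jeffery_period(gamma_d, self.r)


def fit_jeffery_ratio(periods: Sequence[tuple[float, float]]) -> JefferyFit:
    """Least-squares fit of T(γ) = (2π/γ)(r + 1/r) with r ≥ 1.

    Each point inverts in closed form, r = (c + √(c² − 4))/2 with
    c = γT/2π ≥ 2; the average seeds a least-squares polish.
    """
    pts = np.asarray(periods, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1 or pts.shape[1] != 2:
        raise ValueError("periods must be a sequence of (gamma_d, T) pairs")
    gam, T = pts[:, 0], pts[:, 1]
    c = gam * T / (2.0 * math.pi)
    if np.any(c < 2.0 - 1e-12):
        raise ValueError(f"impossible period: gamma*T/2pi = {c.min():.4f} < 2")
    c = np.maximum(c, 2.0)
    r0 = float(np.mean((c + np.sqrt(np.maximum(c**2 - 4.0, 0.0))) / 2.0))
    if len(pts) == 1:
        return JefferyFit(r=max(r0, 1.0), residual=0.0, gamma_grid=gam, periods=T)
    res = least_squares(
        lambda p: (2.0 * math.pi / gam) * (p[0] + 1.0 / p[0]) - T,
        x0=[max(r0, 1.0)],
        bounds=([1.0], [np.inf]),
    )
    return JefferyFit(
        r=float(res.x[0]),
        residual=float(np.linalg.norm(res.fun)),
        gamma_grid=gam,
        periods=T,
    )


def period_vs_bodyscale(
    scalings: Sequence[float],
    gamma_d: float,
    config: SwimmerConfig = SwimmerConfig(),
    n_theta: int = 24,
    n_phases: int = 20,
    refinement: int = 1,
) -> tuple[list[tuple[float, float]], float]:
    """Rotation period across body length scales (flagellum held fixed).

    Returns the (scaling, period) list and the scaling of maximal period.
    """
    out = []
    for s in scalings:
        if s <= 0:
            raise ValueError("body scalings must be positive")
        cfg = config.with_body_scale(s)
        T = rotation_period(gamma_d, cfg, n_theta=n_theta, n_phases=n_phases, refinement=refinement)
        out.append((float(s), float(T)))
    argmax = max(out, key=lambda p: p[1])[0]
    return out, argmax


# --------------------------------------------------------------------------
# Wall phase plane
# --------------------------------------------------------------------------


@dataclass
class PhaseField:
    """Phase-averaged reduced field on a (θ, h) grid near the wall.

    Stores the affine-in-γ decomposition: ``*_beat`` is the γ = 0 swim
    response (including swimmer–wall hydrodynamics), ``*_shear`` the passive
    response to unit wall shear, so that V(γ) = V_beat + γ V_shear holds
    nodewise.  ``valid`` flags configurations clear of the wall at every
    sampled phase.
    """

    theta_grid: np.ndarray
    h_grid: np.ndarray
    U_beat: np.ndarray  # (n_theta, n_h, 3)
    W_beat: np.ndarray
    U_shear: np.ndarray
    W_shear: np.ndarray
    valid: np.ndarray  # (n_theta, n_h) bool
    n_phases: int
    refinement: int
    config: SwimmerConfig

    def U_avg(self, gamma_d: float) -> np.ndarray:
        return self.U_beat + gamma_d * self.U_shear

    def W_avg(self, gamma_d: float) -> np.ndarray:
        return self.W_beat + gamma_d * self.W_shear

    def reduced_rates(self, gamma_d: float) -> tuple[np.ndarray, np.ndarray]:
        """Nodewise (θ̇, ḣ): θ̇ = −⟨Ω3⟩, ḣ = ⟨U1⟩ (advection vanishes at x2=x3=0)."""
        return -self.W_avg(gamma_d)[..., 2], self.U_avg(gamma_d)[..., 0]

    def _extended(self, vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Periodic extension in θ for spline interpolation."""
        th = self.theta_grid
        pad = 3
        th_ext = np.concatenate([th[-pad:] - 2 * math.pi, th, th[:pad] + 2 * math.pi])
        v_ext = np.concatenate([vals[-pad:], vals, vals[:pad]], axis=0)
        return th_ext, v_ext

    def interpolants(self, gamma_d: float) -> tuple[Callable, Callable]:
        """Periodic-cubic spline interpolants (θ, h) → θ̇ and → ḣ."""
        td, hd = self.reduced_rates(gamma_d)
        th_ext, td_ext = self._extended(td)
        _, hd_ext = self._extended(hd)
        s_td = RectBivariateSpline(th_ext, self.h_grid, td_ext, kx=3, ky=3)
        s_hd = RectBivariateSpline(th_ext, self.h_grid, hd_ext, kx=3, ky=3)
        f_td = lambda th, h: s_td(np.mod(th, 2 * math.pi), h, grid=False)
        f_hd = lambda th, h: s_hd(np.mod(th, 2 * math.pi), h, grid=False)
        return f_td, f_hd

    def rhs(self, gamma_d: float) -> Callable:
        """Right-hand side f(θ, h) = (θ̇, ḣ) of the reduced wall system."""
        f_td, f_hd = self.interpolants(gamma_d)

        def f(y):
            th, h = y[0], y[1]
            return np.array([float(f_td(th, h)), float(f_hd(th, h))])

        return f

    def downstream_rate(self, gamma_d: float) -> Callable:
        """Interpolant for ẋ2 at x2 = 0: swim part plus −γ h advection."""
        u2 = self.U_avg(gamma_d)[..., 1]
        th_ext, u2_ext = self._extended(u2)
        s = RectBivariateSpline(th_ext, self.h_grid, u2_ext, kx=3, ky=3)
        return lambda th, h: float(s(np.mod(th, 2 * math.pi), h, grid=False)) - gamma_d * h


def wall_phase_field(
    theta_grid: np.ndarray,
    h_grid: np.ndarray,
    config: SwimmerConfig = SwimmerConfig(),
    n_phases: int = 20,
    refinement: int = 1,
    viscosity: Optional[float] = None,
) -> PhaseField:
    """Phase-averaged (θ̇, ḣ) field near the no-slip wall x̂1 = 0.

    For every grid node, runs the Blake-kernel mobility solve at
    ``n_phases`` beat phases with two right-hand sides (beat swim, unit
    wall shear), yielding the affine-in-γ field.  Nodes where the swimmer
    would penetrate the wall at any sampled phase are flagged invalid and
    filled from the nearest valid node at the same θ (the flags mark them).
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    h_grid = np.asarray(h_grid, dtype=float)
    if h_grid.min() <= 0:
        raise ValueError("h grid must be strictly positive")
    mu = FlowModel().viscosity if viscosity is None else viscosity
    meshes = _phase_meshes(config, n_phases, refinement)
    nt, nh = len(theta_grid), len(h_grid)
    U_beat = np.zeros((nt, nh, 3))
    W_beat = np.zeros((nt, nh, 3))
    U_shear = np.zeros((nt, nh, 3))
    W_shear = np.zeros((nt, nh, 3))
    valid = np.ones((nt, nh), dtype=bool)
    for it, th in enumerate(theta_grid):
        R = BulkPhaseTable._rotation(th)
        verts_rot = [m.vertices_per_triangle @ R.T for m in meshes]
        ubeat_rot = [m.centroid_velocities @ R.T for m in meshes]
        min_x1 = min(v[..., 0].min() for v in verts_rot)
        for ih, h in enumerate(h_grid):
            if h + min_x1 <= 5e-3:  # would touch/penetrate at some phase
                valid[it, ih] = False
                continue
            x0 = np.array([h, 0.0, 0.0])
            for ip in range(n_phases):
                verts_lab = verts_rot[ip] + x0
                prob = MobilityProblem(verts_lab, x0, mu, wall=True)
                sol = prob.solve(ubeat_rot[ip])
                U_beat[it, ih] += sol.U / n_phases
                W_beat[it, ih] += sol.Omega / n_phases
                u_s = np.zeros_like(prob.centroids)
                u_s[:, 1] = prob.centroids[:, 0]  # −u_b for unit wall shear
                solg = prob.solve(u_s)
                U_shear[it, ih] += solg.U / n_phases
                W_shear[it, ih] += solg.Omega / n_phases
    # fill invalid nodes from the nearest valid h at the same theta
    for it in range(nt):
        bad = ~valid[it]
        if bad.any() and (~bad).any():
            src = np.where(~bad)[0][0]
            for arr in (U_beat, W_beat, U_shear, W_shear):
                arr[it, bad] = arr[it, src]
    return PhaseField(
        theta_grid=theta_grid,
        h_grid=h_grid,
        U_beat=U_beat,
        W_beat=W_beat,
        U_shear=U_shear,
        W_shear=W_shear,
        valid=valid,
        n_phases=n_phases,
        refinement=refinement,
        config=config,
    )


@dataclass
class SaddlePoint:
    """Fixed point of the reduced wall dynamics with its classification."""

    found: bool
    theta: float = math.nan
    h: float = math.nan
    jacobian: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    eigenvectors: np.ndarray | None = None

    @property
    def is_saddle(self) -> bool:
        if not self.found or self.eigenvalues is None:
            return False
        ev = self.eigenvalues
        return bool(np.all(np.isreal(ev)) and np.real(ev[0]) * np.real(ev[1]) < 0)


@dataclass
class PhasePlaneAnalysis:
    """Saddle, manifolds and separatrix of the reduced wall system."""

    saddle: SaddlePoint
    separatrix: np.ndarray | None  # polyline (n, 2) of (θ unwrapped, h)
    stable_manifold: np.ndarray | None
    unstable_manifold: np.ndarray | None
    gamma_d: float = math.nan

    def separatrix_height(self, theta: float) -> float:
        """Interpolated separatrix h at angle θ (mod 2π)."""
        if self.separatrix is None or len(self.separatrix) < 2:
            raise ValueError("no separatrix available")
        th = np.mod(self.separatrix[:, 0], 2 * math.pi)
        order = np.argsort(th)
        return float(np.interp(theta % (2 * math.pi), th[order], self.separatrix[order, 1]))


def find_saddle(
    field: PhaseField,
    gamma_d: float,
    theta_window: tuple[float, float] = (0.0, 2.0 * math.pi),
    newton_tol: float = 1e-10,
) -> SaddlePoint:
    """Locate a fixed point of the interpolated (θ̇, ḣ) field by Newton
    iteration from multistart seeds on the grid; classify by the finite-
    difference Jacobian of the interpolant.

    Returns a not-found record (no exception) when no root lies in the
    window and grid domain.
    """
    f_td, f_hd = field.interpolants(gamma_d)
    h_lo, h_hi = field.h_grid.min(), field.h_grid.max()

    def F(y):
        return np.array([float(f_td(y[0], y[1])), float(f_hd(y[0], y[1]))])

    def J(y, eps_t=1e-6, eps_h=1e-6):
        return np.array(
            [
                (F([y[0] + eps_t, y[1]]) - F([y[0] - eps_t, y[1]])) / (2 * eps_t),
                (F([y[0], y[1] + eps_h]) - F([y[0], y[1] - eps_h])) / (2 * eps_h),
            ]
        ).T

    # scale for residual tolerance: typical field magnitude
    td, hd = field.reduced_rates(gamma_d)
    scale = max(np.abs(td).max(), np.abs(hd).max(), 1e-12)

    best = None
    tg, hg = field.theta_grid, field.h_grid
    for it in range(len(tg)):
        for ih in range(len(hg)):
            if not field.valid[it, ih]:
                continue
            th = tg[it] % (2 * math.pi)
            if not (theta_window[0] - 1e-9 <= th <= theta_window[1] + 1e-9):
                continue
            y = np.array([tg[it], hg[ih]], dtype=float)
            ok = False
            for _ in range(50):
                Fy = F(y)
                if np.linalg.norm(Fy) < newton_tol * scale:
                    ok = True
                    break
                try:
                    dy = np.linalg.solve(J(y), Fy)
                except np.linalg.LinAlgError:
                    break
                step = min(1.0, 0.5 / max(np.abs(dy[0]) / math.pi, np.abs(dy[1]) / (h_hi - h_lo), 1e-12) / 10)
                y = y - dy
                if not (h_lo - 1e-9 <= y[1] <= h_hi + 1e-9):
                    break
            if not ok:
                continue
            th_root = y[0] % (2 * math.pi)
            if not (theta_window[0] - 1e-6 <= th_root <= theta_window[1] + 1e-6):
                continue
            if best is None or y[1] < best[1]:
                if best is not None and abs(th_root - best[0] % (2 * math.pi)) < 1e-4 and abs(y[1] - best[1]) < 1e-4:
                    continue
                best = (y[0], y[1])
    if best is None:
        return SaddlePoint(found=False)
    y = np.array(best)
    Jm = J(y)
    ev, evec = np.linalg.eig(Jm)
    return SaddlePoint(
        found=True,
        theta=float(y[0] % (2 * math.pi)),
        h=float(y[1]),
        jacobian=Jm,
        eigenvalues=ev,
        eigenvectors=evec,
    )


def compute_separatrix(
    field: PhaseField,
    saddle: SaddlePoint,
    gamma_d: float,
    eps: float = 1e-3,
    max_time: float = 2000.0,
) -> PhasePlaneAnalysis:
    """Stable-manifold separatrix by backward integration from the saddle.

    Integrates the reduced dynamics in reversed time from small offsets
    along the stable eigenvector until the trajectory spans one period in θ
    (closing the homoclinic loop) or leaves the resolved h range.
    """
    if not saddle.found:
        return PhasePlaneAnalysis(saddle=saddle, separatrix=None, stable_manifold=None, unstable_manifold=None, gamma_d=gamma_d)
    f_td, f_hd = field.interpolants(gamma_d)
    h_lo, h_hi = field.h_grid.min(), field.h_grid.max()
    ev = np.real(saddle.eigenvalues)
    vecs = np.real(saddle.eigenvectors)
    i_stable = int(np.argmin(ev))
    i_unstable = int(np.argmax(ev))

    def rhs_back(t, y):
        return [-float(f_td(y[0], y[1])), -float(f_hd(y[0], y[1]))]

    def rhs_fwd(t, y):
        return [float(f_td(y[0], y[1])), float(f_hd(y[0], y[1]))]

    def run(rhs, y0):
        def hit_low(t, y):
            return y[1] - h_lo

        def hit_high(t, y):
            return h_hi - y[1]

        def span(t, y):
            return abs(y[0] - saddle.theta) - 2.0 * math.pi * 1.02

        for e in (hit_low, hit_high, span):
            e.terminal = True
        sol = solve_ivp(rhs, (0.0, max_time), y0, events=(hit_low, hit_high, span), max_step=2.0, rtol=1e-8, atol=1e-10, dense_output=False)
        return sol.y.T

    v_s = vecs[:, i_stable]
    v_u = vecs[:, i_unstable]
    scale = np.array([1.0, max(saddle.h, 1.0)])
    br1 = run(rhs_back, np.array([saddle.theta, saddle.h]) + eps * v_s * scale)
    br2 = run(rhs_back, np.array([saddle.theta, saddle.h]) - eps * v_s * scale)
    um1 = run(rhs_fwd, np.array([saddle.theta, saddle.h]) + eps * v_u * scale)
    um2 = run(rhs_fwd, np.array([saddle.theta, saddle.h]) - eps * v_u * scale)
    # the separatrix is the stable branch sweeping a full period in θ
    def theta_span(b):
        return abs(b[-1, 0] - b[0, 0]) if len(b) else 0.0

    main = br1 if theta_span(br1) >= theta_span(br2) else br2
    stable = np.concatenate([br2[::-1], br1]) if len(br1) and len(br2) else main
    unstable = np.concatenate([um2[::-1], um1]) if len(um1) and len(um2) else None
    return PhasePlaneAnalysis(
        saddle=saddle,
        separatrix=main,
        stable_manifold=stable,
        unstable_manifold=unstable,
        gamma_d=gamma_d,
    )


def classify_configuration(
    field: PhaseField,
    theta: float,
    h: float,
    gamma_d: float,
    t_max: float = 2500.0,
    h_escape: Optional[float] = None,
    h_collide: Optional[float] = None,
) -> str:
    """Forward-integrate the reduced dynamics; label the long-time behavior.

    Returns ``"collision"`` if h falls to the collision floor (the lower
    edge of the resolved grid).  ``"escape"`` covers both leaving the
    resolved height range upward and surviving a full shear-driven tumble
    (θ advancing beyond 2π) without collision — above the separatrix the
    long-time motion is a bounded tumbling orbit deflected into the bulk,
    not unbounded rise.  ``"undetermined"`` otherwise.
    """
    f = field.rhs(gamma_d)
    h_lo = field.h_grid.min() * 1.05 if h_collide is None else h_collide
    h_hi = field.h_grid.max() * 0.98 if h_escape is None else h_escape

    def rhs(t, y):
        return f(y)

    def hit_low(t, y):
        return y[1] - h_lo

    def hit_high(t, y):
        return h_hi - y[1]

    def full_tumble(t, y):
        return abs(y[0] - theta) - 2.35 * math.pi

    for e in (hit_low, hit_high, full_tumble):
        e.terminal = True
    sol = solve_ivp(
        rhs, (0.0, t_max), [theta, h], events=(hit_low, hit_high, full_tumble), max_step=2.0, rtol=1e-8, atol=1e-10
    )
    if sol.t_events[0].size:
        return "collision"
    if sol.t_events[1].size or sol.t_events[2].size:
        return "escape"
    return "undetermined"


def critical_shear(
    field: PhaseField,
    gamma_grid: np.ndarray,
    proximity: Optional[float] = None,
    refine_iters: int = 20,
) -> float:
    """Smallest shear rate at which the saddle sits within one beat
    amplitude of the wall (the near-wall validity floor of phase
    averaging), bisection-refined between grid points.

    Uses the affine-in-γ field, so no further boundary-element solves are
    required.  Returns NaN if the saddle never gets that close on the grid.
    """
    gamma_grid = np.sort(np.asarray(gamma_grid, dtype=float))
    thresh = field.config.beat_amplitude if proximity is None else proximity

    def saddle_h(g):
        s = find_saddle(field, g)
        return s.h if s.found else math.nan

    hs = np.array([saddle_h(g) for g in gamma_grid])
    if np.all(np.isnan(hs)):
        return math.nan
    # once the saddle has been tracked at lower shear, losing it below the
    # resolved h floor counts as crossing the proximity threshold
    seen = False
    below = np.zeros(len(hs), dtype=bool)
    for i, h in enumerate(hs):
        if not math.isnan(h):
            seen = True
            below[i] = h < thresh
        else:
            below[i] = seen
    if not below.any():
        return math.nan
    if below[0]:
        return float(gamma_grid[0])
    i = int(np.argmax(below))
    lo, hi = gamma_grid[i - 1], gamma_grid[i]

    def crossed(g):
        h = saddle_h(g)
        return math.isnan(h) or h < thresh

    for _ in range(refine_iters):
        mid = 0.5 * (lo + hi)
        if crossed(mid):
            hi = mid
        else:
            lo = mid
    return float(0.5 * (lo + hi))
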