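"""Virtual-monoflagellate surface geometry.

The swimmer is a prolate spheroidal cell body with a single anterior
flagellum, modelled on the *Leishmania mexicana* promastigote: body major and
minor axes 11 and 3.5 μm, flagellum length ``L`` = 13 μm.  The flagellar
centerline beats in the plane ``x3 = 0`` of the swimmer-fixed frame as a
travelling sine wave

    x1 = ξ,   x2 = A [ sin(2πξ/λ + 2πft) − sin(2πft) ],   x3 = 0,

with amplitude ``A`` = 1.8 μm, wavelength ``λ`` = 13 μm and frequency
``f`` = 28 Hz.  The subtraction of ``sin(2πft)`` pins the flagellar base to
the body for all time, and the upper parameter bound ``ξ*`` is chosen at
every instant so that the centerline arclength equals ``L`` (an
inextensible flagellum).

The beat travels from the flagellar tip towards the base, which makes the
swimmer a hydrodynamic *puller*; reversing the propagation direction yields
the morphologically identical *pusher*.

Meshes are watertight genus-0 triangulations built from structured rings:
far body pole → body rings → attachment rim → flagellar tube rings → tip.
Flagellum nodes carry material coordinates (arclength fraction ``s/L``,
tube azimuth), so beat-induced node velocities follow from central finite
differences of node position over a small fraction of the beat period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "SwimmerConfig",
    "BeatPhase",
    "SurfaceMesh",
    "GeometryError",
    "centerline_point",
    "xi_star",
    "build_mesh",
    "beat_surface_velocity",
    "body_semi_axes",
]

#: Beat phase, dimensionless in [0, 1): phase = f·t mod 1.
BeatPhase = float


class GeometryError(ValueError):
    """Raised for invalid or self-intersecting swimmer configurations."""


@dataclass(frozen=True)
class SwimmerConfig:
    """Morphology and beat kinematics of the virtual monoflagellate.

    Lengths in μm, frequency in Hz.  ``beat_direction`` selects the wave
    propagation sense: ``"puller"`` is the tip-to-base beat of the
    promastigote, ``"pusher"`` the reversed beat.  ``body_scale`` multiplies
    both body semi-axes while leaving the flagellum untouched.
    """

    body_major_axis: float = 11.0
    body_minor_axis: float = 3.5
    flagellum_length: float = 13.0
    flagellum_radius: float = 0.25
    beat_amplitude: float = 1.8
    beat_wavelength: float = 13.0
    beat_frequency: float = 28.0
    beat_direction: Literal["puller", "pusher"] = "puller"
    body_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "body_major_axis",
            "body_minor_axis",
            "flagellum_length",
            "flagellum_radius",
            "beat_wavelength",
            "beat_frequency",
            "body_scale",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive, got {getattr(self, name)}")
        if self.beat_amplitude < 0:
            raise GeometryError("beat_amplitude must be non-negative")
        if self.beat_amplitude >= self.flagellum_length:
            raise GeometryError("beat_amplitude must be smaller than the flagellum length")
        if self.beat_direction not in ("puller", "pusher"):
            raise GeometryError(f"unknown beat_direction {self.beat_direction!r}")

    @property
    def beat_period(self) -> float:
        """Beat period 1/f in seconds."""
        return 1.0 / self.beat_frequency

    def with_body_scale(self, scale: float) -> "SwimmerConfig":
        return replace(self, body_scale=scale)


def body_semi_axes(config: SwimmerConfig) -> tuple[float, float]:
    """Scaled body semi-axes (a along x1, b transverse), μm."""
    return (
        0.5 * config.body_major_axis * config.body_scale,
        0.5 * config.body_minor_axis * config.body_scale,
    )


# --------------------------------------------------------------------------
# Centerline kinematics
# --------------------------------------------------------------------------


def _phase_sign(config: SwimmerConfig) -> float:
    # The pusher is the time reversal of the puller: run the beat backwards.
    return 1.0 if config.beat_direction == "puller" else -1.0


def centerline_point(config: SwimmerConfig, phase: BeatPhase, xi: float) -> np.ndarray:
    """Point on the flagellar centerline at parameter ``xi``, swimmer frame.

    ``xi`` must lie in ``[0, xi_star(config, phase)]``.
    """
    xs = xi_star(config, phase)
    if not (0.0 <= xi <= xs * (1 + 1e-12)):
        raise GeometryError(f"xi={xi} outside [0, xi_star={xs}]")
    return _centerline(config, phase, np.asarray(float(xi)))


def _centerline(config: SwimmerConfig, phase: float, xi: np.ndarray) -> np.ndarray:
    """Vectorized Eq.-of-beat centerline; xi may be any array."""
    t = 2.0 * math.pi * _phase_sign(config) * phase
    k = 2.0 * math.pi / config.beat_wavelength
    x2 = config.beat_amplitude * (np.sin(k * xi + t) - math.sin(t))
    out = np.zeros(np.shape(xi) + (3,))
    out[..., 0] = xi
    out[..., 1] = x2
    return out


def _slope(config: SwimmerConfig, phase: float, xi: np.ndarray) -> np.ndarray:
    """d x2 / d xi along the centerline."""
    t = 2.0 * math.pi * _phase_sign(config) * phase
    k = 2.0 * math.pi / config.beat_wavelength
    return config.beat_amplitude * k * np.cos(k * xi + t)


def _arclength(config: SwimmerConfig, phase: float, xi: float) -> float:
    """Arclength of the centerline from 0 to xi (adaptive quadrature)."""
    val, _ = quad(
        lambda x: math.hypot(1.0, float(_slope(config, phase, np.asarray(x)))),
        0.0,
        xi,
        epsabs=1e-12,
        epsrel=1e-12,
        limit=200,
    )
    return val


def xi_star(config: SwimmerConfig, phase: BeatPhase) -> float:
    """Upper centerline parameter bound conserving flagellar arclength.

    Solves ``arclength(ξ*) = L`` by bracketed root finding; for a straight
    centerline (A = 0) this is exactly L.
    """
    L = config.flagellum_length
    if config.beat_amplitude == 0.0:
        return L
    # max slope bounds arclength: xi* >= L / sqrt(1 + m^2)
    m = config.beat_amplitude * 2.0 * math.pi / config.beat_wavelength
    lo = L / math.hypot(1.0, m) * 0.999
    f = lambda xi: _arclength(config, phase, xi) - L
    flo, fhi = f(lo), f(L)
    if flo > 0 or fhi < 0:  # pragma: no cover - bracket is analytic
        raise GeometryError(f"xi_star bracketing failed: f({lo})={flo}, f({L})={fhi}")
    return brentq(f, lo, L, xtol=1e-12, rtol=1e-12)


def _xi_of_arclength(config: SwimmerConfig, phase: float, n_fine: int = 2048):
    """Dense monotone map s ↦ ξ on [0, L] via cumulative trapezoid."""
    xs = xi_star(config, phase)
    xi = np.linspace(0.0, xs, n_fine)
    ds = np.hypot(1.0, _slope(config, phase, xi))
    s = np.concatenate(([0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(xi))))
    # rescale the tiny quadrature drift so s[-1] == L exactly
    s *= config.flagellum_length / s[-1]
    return s, xi


# --------------------------------------------------------------------------
# Mesh construction
# --------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Closed triangulated swimmer surface with beat node velocities.

    ``nodes`` are swimmer-frame coordinates (μm); ``node_velocities`` are the
    beat-induced material velocities in the swimmer frame (μm/s; zero on the
    rigid body).  ``element_region``/``node_region`` flag body (0) versus
    flagellum (1) parts.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    node_velocities: np.ndarray
    element_region: np.ndarray
    node_region: np.ndarray

    @property
    def element_count(self) -> int:
        return len(self.triangles)

    @property
    def vertices_per_triangle(self) -> np.ndarray:
        """(M, 3, 3) array of triangle vertex coordinates."""
        return self.nodes[self.triangles]

    @property
    def centroids(self) -> np.ndarray:
        return self.vertices_per_triangle.mean(axis=1)

    @property
    def areas(self) -> np.ndarray:
        v = self.vertices_per_triangle
        cr = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return 0.5 * np.linalg.norm(cr, axis=1)

    @property
    def normals(self) -> np.ndarray:
        """Outward unit normals per element."""
        v = self.vertices_per_triangle
        cr = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return cr / np.linalg.norm(cr, axis=1)[:, None]

    @property
    def centroid_velocities(self) -> np.ndarray:
        return self.node_velocities[self.triangles].mean(axis=1)

    def signed_volume(self) -> float:
        v = self.vertices_per_triangle
        return float(np.einsum("ij,ij->", v[:, 0], np.cross(v[:, 1], v[:, 2]))) / 6.0

    def total_area(self) -> float:
        return float(self.areas.sum())

    def is_watertight(self) -> bool:
        """Every directed edge appears exactly once (closed, oriented)."""
        tri = self.triangles
        edges = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        fwd = {tuple(e) for e in edges.tolist()}
        if len(fwd) != len(edges):
            return False
        return all((b, a) in fwd for a, b in fwd)

    def euler_characteristic(self) -> int:
        tri = self.triangles
        edges = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        und = {tuple(sorted(e)) for e in edges.tolist()}
        return len(self.nodes) - len(und) + len(tri)


#: ring/segment counts per refinement level: (tube azimuth, tube rings,
#: body azimuth, body rings).  Level 1 reproduces the ~644-element default.
_LEVELS = {
    0: (4, 9, 8, 7),
    1: (6, 22, 12, 16),
    2: (8, 30, 18, 22),
    3: (10, 44, 24, 32),
}


def _level_counts(refinement: int) -> tuple[int, int, int, int]:
    if refinement not in _LEVELS:
        raise GeometryError(f"unknown refinement level {refinement}; valid: {sorted(_LEVELS)}")
    return _LEVELS[refinement]


def _zipper(ring_a: np.ndarray, az_a: np.ndarray, ring_b: np.ndarray, az_b: np.ndarray) -> list:
    """Bridge two closed node rings (consistent sweep orientation).

    Greedy azimuthal merge; produces len(a)+len(b) triangles.  Triangle
    winding follows the sweep convention: within-ring edges of the previous
    ring appear reversed, of the next ring forward.
    """
    m, n = len(ring_a), len(ring_b)
    tris = []
    i = j = 0
    aa = np.concatenate([az_a, [az_a[0] + 2 * math.pi]])
    bb = np.concatenate([az_b, [az_b[0] + 2 * math.pi]])
    while i < m or j < n:
        adv_a = i < m and (j >= n or aa[i + 1] <= bb[j + 1])
        if adv_a:
            tris.append((ring_a[i % m], ring_b[j % n], ring_a[(i + 1) % m]))
            i += 1
        else:
            tris.append((ring_a[i % m], ring_b[j % n], ring_b[(j + 1) % n]))
            j += 1
    return tris


def _chord_compensation(n_az: int) -> float:
    """Radius inflation making an n-gon ring match the circle circumference.

    A polygonal cross-section through on-surface nodes underestimates arc
    length by sin(c)/c per chord; inflating node radii by the reciprocal
    keeps the discrete surface area (and hence viscous drag) consistent with
    the smooth body at coarse azimuthal resolution.
    """
    c = math.pi / n_az
    return c / math.sin(c)


def _flagellum_ring_positions(
    config: SwimmerConfig, phase: float, s_rings: np.ndarray, azimuths: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Flagellum tube ring nodes plus tip node at material coordinates.

    Returns (ring nodes of shape (n_rings, n_az, 3), tip node (3,)).
    Ring frames use the planar-curve normal and the out-of-plane binormal
    ẑ, so there is no frame twist for the planar beat.
    """
    s_map, xi_map = _xi_of_arclength(config, phase)
    xi_r = np.interp(s_rings, s_map, xi_map)
    c = _centerline(config, phase, xi_r)
    yp = _slope(config, phase, xi_r)
    norm = np.hypot(1.0, yp)
    # tangent (1, y', 0)/norm ; in-plane normal (-y', 1, 0)/norm ; binormal ẑ
    n_hat = np.stack([-yp / norm, 1.0 / norm, np.zeros_like(yp)], axis=-1)
    rho = config.flagellum_radius * _chord_compensation(len(azimuths))
    cosb = np.cos(azimuths)[None, :, None]
    sinb = np.sin(azimuths)[None, :, None]
    zhat = np.array([0.0, 0.0, 1.0])
    rings = c[:, None, :] + rho * (cosb * n_hat[:, None, :] + sinb * zhat)
    # tip: centerline end extended by one radius along the tangent (rounded cap)
    xi_end = np.interp(config.flagellum_length, s_map, xi_map)
    c_end = _centerline(config, phase, np.asarray(xi_end))
    yp_e = float(_slope(config, phase, np.asarray(xi_end)))
    t_hat = np.array([1.0, yp_e, 0.0]) / math.hypot(1.0, yp_e)
    tip = c_end + rho * t_hat
    return rings, tip


def _mesh_topology(config: SwimmerConfig, refinement: int):
    """Node layout (material coordinates) and triangle list, phase-free."""
    n_az_t, n_s, n_az_b, n_beta = _level_counts(refinement)
    a, b = body_semi_axes(config)
    comp_b = _chord_compensation(n_az_b)
    comp_t = _chord_compensation(n_az_t)
    rho = config.flagellum_radius * comp_t
    if rho >= b:
        raise GeometryError("flagellum radius exceeds body minor semi-axis; no attachment rim")
    beta0 = math.asin(rho / (b * comp_b))  # pole-hole colatitude from the +x1 pole

    az_b = 2 * math.pi * np.arange(n_az_b) / n_az_b
    az_t = 2 * math.pi * np.arange(n_az_t) / n_az_t

    nodes = [np.array([-2.0 * a, 0.0, 0.0])]  # far body pole
    node_region = [0]
    ring_specs = []  # (indices, azimuths)
    # body rings swept from far pole towards the attachment rim
    betas = np.linspace(math.pi, beta0, n_beta + 1)[1:-1]
    for beta in betas:
        idx = np.arange(len(nodes), len(nodes) + n_az_b)
        r = comp_b * b * math.sin(beta)
        x = -a + a * math.cos(beta)
        ring = np.stack([np.full(n_az_b, x), r * np.cos(az_b), r * np.sin(az_b)], axis=-1)
        nodes.extend(ring)
        node_region.extend([0] * n_az_b)
        ring_specs.append((idx, az_b))
    # attachment rim (body nodes, tube azimuth count)
    rim_idx = np.arange(len(nodes), len(nodes) + n_az_t)
    r = comp_b * b * math.sin(beta0)
    x = -a + a * math.cos(beta0)
    rim = np.stack([np.full(n_az_t, x), r * np.cos(az_t), r * np.sin(az_t)], axis=-1)
    nodes.extend(rim)
    node_region.extend([0] * n_az_t)
    ring_specs.append((rim_idx, az_t))
    n_body_nodes = len(nodes)

    # flagellum tube rings at material arclengths s_j = j L / n_s, j = 1..n_s
    s_rings = config.flagellum_length * np.arange(1, n_s + 1) / n_s
    tube_start = len(nodes)
    for j in range(n_s):
        idx = np.arange(len(nodes), len(nodes) + n_az_t)
        nodes.extend(np.zeros((n_az_t, 3)))  # positions filled per phase
        node_region.extend([1] * n_az_t)
        ring_specs.append((idx, az_t))
    tip_idx = len(nodes)
    nodes.append(np.zeros(3))
    node_region.append(1)

    tris = []
    tri_region = []
    # far pole fan
    first_ring, first_az = ring_specs[0]
    for k in range(len(first_ring)):
        tris.append((0, first_ring[k], first_ring[(k + 1) % len(first_ring)]))
        tri_region.append(0)
    # bands
    n_body_rings = n_beta  # betas rings + rim
    for rb in range(len(ring_specs) - 1):
        ra_idx, ra_az = ring_specs[rb]
        rb_idx, rb_az = ring_specs[rb + 1]
        band = _zipper(ra_idx, ra_az, rb_idx, rb_az)
        tris.extend(band)
        # a band is flagellar once it is past the rim
        region = 1 if rb >= n_body_rings - 1 else 0
        tri_region.extend([region] * len(band))
    # tip fan
    last_ring, _ = ring_specs[-1]
    nlr = len(last_ring)
    for k in range(nlr):
        tris.append((last_ring[(k + 1) % nlr], last_ring[k], tip_idx))
        tri_region.append(1)

    return {
        "nodes0": np.array(nodes),
        "node_region": np.array(node_region, dtype=np.int8),
        "triangles": np.array(tris, dtype=np.int64),
        "tri_region": np.array(tri_region, dtype=np.int8),
        "s_rings": s_rings,
        "az_t": az_t,
        "tube_start": tube_start,
        "tip_idx": tip_idx,
        "n_az_t": n_az_t,
        "n_s": n_s,
    }


def _fill_positions(config: SwimmerConfig, phase: float, topo: dict) -> np.ndarray:
    nodes = topo["nodes0"].copy()
    rings, tip = _flagellum_ring_positions(config, phase, topo["s_rings"], topo["az_t"])
    n_az_t, n_s = topo["n_az_t"], topo["n_s"]
    nodes[topo["tube_start"] : topo["tube_start"] + n_s * n_az_t] = rings.reshape(-1, 3)
    nodes[topo["tip_idx"]] = tip
    return nodes


def _check_no_body_intersection(config: SwimmerConfig, nodes: np.ndarray, topo: dict) -> None:
    """Flag flagellum nodes (beyond the junction region) inside the body."""
    a, b = body_semi_axes(config)
    start = topo["tube_start"] + 2 * topo["n_az_t"]  # junction rings may overlap by design
    fl = nodes[start:]
    q = ((fl[:, 0] + a) / a) ** 2 + (fl[:, 1] / b) ** 2 + (fl[:, 2] / b) ** 2
    if np.any(q < 1.0):
        raise GeometryError("flagellum self-intersects the cell body for this configuration")


def build_mesh(config: SwimmerConfig, phase: BeatPhase = 0.0, refinement: int = 1) -> SurfaceMesh:
    """Watertight triangulated swimmer surface at a given beat phase.

    ``refinement`` selects a discretization level; the default (1) gives
    ~644 elements, the count used for the virtual promastigote.  Node
    velocities are beat material velocities from central finite differences
    over ``1e-3`` of a beat period.
    """
    # curvature bound: tube cross-sections must not fold over
    kmax = config.beat_amplitude * (2 * math.pi / config.beat_wavelength) ** 2
    if config.flagellum_radius * kmax >= 1.0:
        raise GeometryError("beat curvature too large for the tube radius (folding cross-sections)")
    topo = _mesh_topology(config, refinement)
    nodes = _fill_positions(config, phase, topo)
    _check_no_body_intersection(config, nodes, topo)
    vel = beat_surface_velocity(config, phase, topo=topo)
    mesh = SurfaceMesh(
        nodes=nodes,
        triangles=topo["triangles"],
        node_velocities=vel,
        element_region=topo["tri_region"],
        node_region=topo["node_region"],
    )
    if mesh.signed_volume() < 0:  # enforce outward orientation
        mesh.triangles = mesh.triangles[:, [0, 2, 1]]
    if np.any(mesh.areas <= 0):
        raise GeometryError("mesh contains degenerate triangles")
    return mesh


def build_spheroid_mesh(a: float, b: float, n_az: int = 16, n_rings: int = 20) -> SurfaceMesh:
    """Closed prolate-spheroid mesh (semi-axes a along x1, b transverse).

    Passive verification body (no flagellum, zero surface velocity), centered
    at the origin.  Ring radii are chord-compensated like the swimmer body.
    """
    if a <= 0 or b <= 0:
        raise GeometryError("semi-axes must be positive")
    comp = _chord_compensation(n_az)
    az = 2 * math.pi * np.arange(n_az) / n_az
    betas = np.linspace(math.pi, 0.0, n_rings + 2)[1:-1]
    nodes = [np.array([-a, 0.0, 0.0])]
    rings = []
    for beta in betas:
        idx = np.arange(len(nodes), len(nodes) + n_az)
        r = comp * b * math.sin(beta)
        x = a * math.cos(beta)
        nodes.extend(np.stack([np.full(n_az, x), r * np.cos(az), r * np.sin(az)], axis=-1))
        rings.append(idx)
    tip = len(nodes)
    nodes.append(np.array([a, 0.0, 0.0]))
    tris = []
    for k in range(n_az):
        tris.append((0, rings[0][k], rings[0][(k + 1) % n_az]))
    for rb in range(len(rings) - 1):
        tris.extend(_zipper(rings[rb], az, rings[rb + 1], az))
    for k in range(n_az):
        tris.append((rings[-1][(k + 1) % n_az], rings[-1][k], tip))
    nodes = np.array(nodes)
    mesh = SurfaceMesh(
        nodes=nodes,
        triangles=np.array(tris, dtype=np.int64),
        node_velocities=np.zeros_like(nodes),
        element_region=np.zeros(len(tris), dtype=np.int8),
        node_region=np.zeros(len(nodes), dtype=np.int8),
    )
    if mesh.signed_volume() < 0:
        mesh.triangles = mesh.triangles[:, [0, 2, 1]]
    return mesh


def beat_surface_velocity(
    config: SwimmerConfig,
    phase: BeatPhase,
    dt_frac: float = 1e-3,
    refinement: int = 1,
    topo: dict | None = None,
) -> np.ndarray:
    """Per-node beat velocities (μm/s, swimmer frame) at fixed material coords.

    Central finite difference of node position over ``dt_frac`` of a beat
    period; body nodes are rigid and return zero.
    """
    if topo is None:
        topo = _mesh_topology(config, refinement)
    dp = dt_frac  # phase step
    dt = dt_frac * config.beat_period
    plus = _fill_positions(config, phase + 0.5 * dp, topo)
    minus = _fill_positions(config, phase - 0.5 * dp, topo)
    vel = (plus - minus) / dt
    vel[topo["node_region"] == 0] = 0.0
    return vel
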