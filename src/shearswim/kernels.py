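"""Green's-function kernels and boundary-element matrix assembly.

Free-space Stokes kernels (Oseen tensor / stresslet) and the Blake image
system enforcing no-slip on the plane wall ``x1 = 0``, plus the numba
routines that assemble the dense single-layer influence matrix

    A[3c:3c+3, 3e:3e+3] = ∫_elem_e  G(x_c, y) dS(y),

collocating at element centroids with piecewise-constant tractions.
Singular self-element integrals use a polar (Duffy) transformation that
cancels the 1/r singularity exactly; near-singular pairs (including image
proximity for the wall kernel) use adaptive 4-way subdivision.

All formulas are in the convention G_ij = δ_ij/r + r_i r_j / r³, so the
single-layer velocity is u_i = −(1/8πμ) ∫ G_ij f_j dS.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "stokeslet",
    "stresslet",
    "blake_velocity_kernel",
    "KernelSet",
    "free_space_kernels",
    "blake_wall_kernels",
    "assemble_single_layer",
]


# --------------------------------------------------------------------------
# Point kernels (public, numpy)
# --------------------------------------------------------------------------


def stokeslet(x: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Oseen tensor G_ij = δ_ij/|r| + r_i r_j/|r|³ with r = x − x0."""
    r = np.asarray(x, dtype=float) - np.asarray(x0, dtype=float)
    d = np.linalg.norm(r)
    if d == 0.0:
        raise ZeroDivisionError("stokeslet evaluated at coincident points")
    return np.eye(3) / d + np.outer(r, r) / d**3


def stresslet(x: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Stress kernel T_ijk = −6 r_i r_j r_k/|r|⁵ (fully symmetric)."""
    r = np.asarray(x, dtype=float) - np.asarray(x0, dtype=float)
    d = np.linalg.norm(r)
    if d == 0.0:
        raise ZeroDivisionError("stresslet evaluated at coincident points")
    return -6.0 * np.einsum("i,j,k->ijk", r, r, r) / d**5


@njit(cache=True)
def _blake_G(x: np.ndarray, y: np.ndarray, out: np.ndarray) -> None:
    """Blake tensor for a no-slip wall at x1 = 0 (fluid in x1 > 0).

    Written in wall-adapted coordinates (wall normal last) and permuted
    back: ours (x1, x2, x3) ↔ Blake's (X, Y, Z=x1).
    """
    # permute: blake coord k maps to our coord P[k]
    # blake (0,1,2) = ours (1,2,0)
    xb0, xb1, xb2 = x[1], x[2], x[0]
    yb0, yb1, yb2 = y[1], y[2], y[0]
    h = yb2
    r0, r1, r2 = xb0 - yb0, xb1 - yb1, xb2 - yb2
    R0, R1, R2 = r0, r1, xb2 + yb2
    rr = math.sqrt(r0 * r0 + r1 * r1 + r2 * r2)
    RR = math.sqrt(R0 * R0 + R1 * R1 + R2 * R2)
    r3 = rr * rr * rr
    R3 = RR * RR * RR
    R5 = R3 * RR * RR
    rv = (r0, r1, r2)
    Rv = (R0, R1, R2)
    for i in range(3):
        for j in range(3):
            sj = 1.0 if j < 2 else -1.0
            dij = 1.0 if i == j else 0.0
            di2 = 1.0 if i == 2 else 0.0
            dj2 = 1.0 if j == 2 else 0.0
            g = dij / rr + rv[i] * rv[j] / r3
            g -= dij / RR + Rv[i] * Rv[j] / R3
            # image system: 2h s_j d/dR_j [ h R_i/R^3 - (d_i2/R + R_i R_2 / R^3) ]
            term = h * (dij / R3 - 3.0 * Rv[i] * Rv[j] / R5)
            term += di2 * Rv[j] / R3
            term -= (dij * Rv[2] + dj2 * Rv[i]) / R3
            term += 3.0 * Rv[i] * Rv[2] * Rv[j] / R5
            g += 2.0 * h * sj * term
            out[i, j] = g
    # permute back: G_ours[i,j] = G_blake[pb[i], pb[j]], pb = (2,0,1)
    g00, g01, g02 = out[2, 2], out[2, 0], out[2, 1]
    g10, g11, g12 = out[0, 2], out[0, 0], out[0, 1]
    g20, g21, g22 = out[1, 2], out[1, 0], out[1, 1]
    out[0, 0], out[0, 1], out[0, 2] = g00, g01, g02
    out[1, 0], out[1, 1], out[1, 2] = g10, g11, g12
    out[2, 0], out[2, 1], out[2, 2] = g20, g21, g22


def blake_velocity_kernel(x: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Blake image-system velocity Green's function, wall at x1 = 0.

    Both the field point ``x`` and the source ``x0`` must lie strictly on
    the fluid side (x1 > 0) — the image construction is undefined otherwise.
    The induced velocity of any point force vanishes identically on the
    wall plane, and the kernel reduces to the free-space stokeslet as the
    source recedes from the wall.
    """
    x = np.asarray(x, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if x0[0] <= 0.0 or x[0] < 0.0:
        raise ValueError("blake kernel requires points on the fluid side of the wall x1=0")
    out = np.empty((3, 3))
    _blake_G(x, x0, out)
    return out


class KernelSet:
    """Velocity/stress Green's function pair for one flow geometry.

    ``variant`` is ``"free_space"`` or ``"blake_wall"`` (no-slip plane at
    x1 = 0).  The stress kernel of the image system is not required by the
    single-layer formulation and is provided for the free-space variant
    only.
    """

    def __init__(self, variant: str):
        if variant not in ("free_space", "blake_wall"):
            raise ValueError(f"unknown kernel variant {variant!r}")
        self.variant = variant
        self.wall_plane = "x1=0" if variant == "blake_wall" else None

    def velocity_kernel(self, x, x0) -> np.ndarray:
        if self.variant == "free_space":
            return stokeslet(x, x0)
        return blake_velocity_kernel(x, x0)

    def stress_kernel(self, x, x0) -> np.ndarray:
        if self.variant == "free_space":
            return stresslet(x, x0)
        raise NotImplementedError("image-system stress kernel is not assembled (single-layer formulation)")


def free_space_kernels() -> KernelSet:
    return KernelSet("free_space")


def blake_wall_kernels() -> KernelSet:
    return KernelSet("blake_wall")


# --------------------------------------------------------------------------
# numba quadrature + assembly
# --------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _G_eval(x: np.ndarray, y: np.ndarray, wall: bool, out: np.ndarray) -> None:
    if wall:
        _blake_G(x, y, out)
    else:
        r0, r1, r2 = x[0] - y[0], x[1] - y[1], x[2] - y[2]
        rr = math.sqrt(r0 * r0 + r1 * r1 + r2 * r2)
        r3 = rr * rr * rr
        out[0, 0] = 1.0 / rr + r0 * r0 / r3
        out[1, 1] = 1.0 / rr + r1 * r1 / r3
        out[2, 2] = 1.0 / rr + r2 * r2 / r3
        out[0, 1] = r0 * r1 / r3
        out[0, 2] = r0 * r2 / r3
        out[1, 2] = r1 * r2 / r3
        out[1, 0] = out[0, 1]
        out[2, 0] = out[0, 2]
        out[2, 1] = out[1, 2]


# 3-point (degree-2) Gauss rule on the unit triangle, barycentric
_TRI_B = np.array(
    [
        [2.0 / 3.0, 1.0 / 6.0, 1.0 / 6.0],
        [1.0 / 6.0, 2.0 / 3.0, 1.0 / 6.0],
        [1.0 / 6.0, 1.0 / 6.0, 2.0 / 3.0],
    ]
)
_TRI_W = np.array([1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0])

# 4-point Gauss-Legendre on [0, 1]
_GL_X = 0.5 * (np.array([-0.8611363115940526, -0.3399810435848563, 0.3399810435848563, 0.8611363115940526]) + 1.0)
_GL_W = 0.5 * np.array([0.3478548451374538, 0.6521451548625461, 0.6521451548625461, 0.3478548451374538])


@njit(cache=True, inline="always")
def _quad_regular(xc, stk, row, wall, out, gtmp, y):
    """3-point Gauss integral of G over one flat triangle; adds into out.

    The triangle vertices live in ``stk[row, 1:10]``.
    """
    v0x, v0y, v0z = stk[row, 1], stk[row, 2], stk[row, 3]
    v1x, v1y, v1z = stk[row, 4], stk[row, 5], stk[row, 6]
    v2x, v2y, v2z = stk[row, 7], stk[row, 8], stk[row, 9]
    cx = (v1y - v0y) * (v2z - v0z) - (v1z - v0z) * (v2y - v0y)
    cy = (v1z - v0z) * (v2x - v0x) - (v1x - v0x) * (v2z - v0z)
    cz = (v1x - v0x) * (v2y - v0y) - (v1y - v0y) * (v2x - v0x)
    area = 0.5 * math.sqrt(cx * cx + cy * cy + cz * cz)
    for q in range(3):
        b0, b1, b2 = _TRI_B[q, 0], _TRI_B[q, 1], _TRI_B[q, 2]
        y[0] = b0 * v0x + b1 * v1x + b2 * v2x
        y[1] = b0 * v0y + b1 * v1y + b2 * v2y
        y[2] = b0 * v0z + b1 * v1z + b2 * v2z
        _G_eval(xc, y, wall, gtmp)
        w = _TRI_W[q] * area
        for i in range(3):
            for j in range(3):
                out[i, j] += w * gtmp[i, j]


@njit(cache=True)
def _quad_adaptive(xc, verts, e, wall, eta, max_depth, out, gtmp, y, stk):
    """Adaptive 4-way subdivision: subdivide while the collocation point
    (or, for the wall kernel, its mirror image) is close to the panel."""
    stk[0, 0] = 0.0
    for k in range(3):
        stk[0, 1 + k] = verts[e, 0, k]
        stk[0, 4 + k] = verts[e, 1, k]
        stk[0, 7 + k] = verts[e, 2, k]
    top = 1
    xm0 = -xc[0]  # mirror of the collocation point in the wall x1 = 0
    while top > 0:
        top -= 1
        row = top
        depth = int(stk[row, 0])
        cx = (stk[row, 1] + stk[row, 4] + stk[row, 7]) / 3.0
        cy = (stk[row, 2] + stk[row, 5] + stk[row, 8]) / 3.0
        cz = (stk[row, 3] + stk[row, 6] + stk[row, 9]) / 3.0
        e0 = (
            (stk[row, 1] - stk[row, 4]) ** 2
            + (stk[row, 2] - stk[row, 5]) ** 2
            + (stk[row, 3] - stk[row, 6]) ** 2
        )
        e1 = (
            (stk[row, 4] - stk[row, 7]) ** 2
            + (stk[row, 5] - stk[row, 8]) ** 2
            + (stk[row, 6] - stk[row, 9]) ** 2
        )
        e2 = (
            (stk[row, 7] - stk[row, 1]) ** 2
            + (stk[row, 8] - stk[row, 2]) ** 2
            + (stk[row, 9] - stk[row, 3]) ** 2
        )
        size2 = max(e0, max(e1, e2))
        d2 = (xc[0] - cx) ** 2 + (xc[1] - cy) ** 2 + (xc[2] - cz) ** 2
        if wall:
            dm2 = (xm0 - cx) ** 2 + (xc[1] - cy) ** 2 + (xc[2] - cz) ** 2
            if dm2 < d2:
                d2 = dm2
        if depth >= max_depth or d2 > eta * eta * size2:
            _quad_regular(xc, stk, row, wall, out, gtmp, y)
        else:
            # vertices a (1:4), b (4:7), c (7:10); children overwrite in place
            ax, ay, az = stk[row, 1], stk[row, 2], stk[row, 3]
            bx, by, bz = stk[row, 4], stk[row, 5], stk[row, 6]
            cxx, cyy, czz = stk[row, 7], stk[row, 8], stk[row, 9]
            abx, aby, abz = 0.5 * (ax + bx), 0.5 * (ay + by), 0.5 * (az + bz)
            bcx, bcy, bcz = 0.5 * (bx + cxx), 0.5 * (by + cyy), 0.5 * (bz + czz)
            cax, cay, caz = 0.5 * (cxx + ax), 0.5 * (cyy + ay), 0.5 * (czz + az)
            d1 = float(depth + 1)
            stk[top, 0] = d1
            stk[top, 1], stk[top, 2], stk[top, 3] = ax, ay, az
            stk[top, 4], stk[top, 5], stk[top, 6] = abx, aby, abz
            stk[top, 7], stk[top, 8], stk[top, 9] = cax, cay, caz
            top += 1
            stk[top, 0] = d1
            stk[top, 1], stk[top, 2], stk[top, 3] = abx, aby, abz
            stk[top, 4], stk[top, 5], stk[top, 6] = bx, by, bz
            stk[top, 7], stk[top, 8], stk[top, 9] = bcx, bcy, bcz
            top += 1
            stk[top, 0] = d1
            stk[top, 1], stk[top, 2], stk[top, 3] = cax, cay, caz
            stk[top, 4], stk[top, 5], stk[top, 6] = bcx, bcy, bcz
            stk[top, 7], stk[top, 8], stk[top, 9] = cxx, cyy, czz
            top += 1
            stk[top, 0] = d1
            stk[top, 1], stk[top, 2], stk[top, 3] = abx, aby, abz
            stk[top, 4], stk[top, 5], stk[top, 6] = bcx, bcy, bcz
            stk[top, 7], stk[top, 8], stk[top, 9] = cax, cay, caz
            top += 1


@njit(cache=True)
def _quad_self(xc, verts, e, wall, out, gtmp, y):
    """Singular integral over the element containing the collocation point.

    Split at the collocation point (the centroid) into 3 subtriangles; on
    each, the polar/Duffy map x(u,v) = p + u[(1−v)(a−p) + v(b−p)] has
    surface Jacobian u|(a−p)×(b−p)|, cancelling the 1/|x−p| singularity.
    """
    for sub in range(3):
        i0 = sub
        i1 = (sub + 1) % 3
        ax, ay, az = verts[e, i0, 0] - xc[0], verts[e, i0, 1] - xc[1], verts[e, i0, 2] - xc[2]
        bx, by, bz = verts[e, i1, 0] - xc[0], verts[e, i1, 1] - xc[1], verts[e, i1, 2] - xc[2]
        cxp = ay * bz - az * by
        cyp = az * bx - ax * bz
        czp = ax * by - ay * bx
        jac = math.sqrt(cxp * cxp + cyp * cyp + czp * czp)  # = 2*area(sub)
        for iu in range(4):
            u = _GL_X[iu]
            wu = _GL_W[iu]
            for iv in range(4):
                v = _GL_X[iv]
                wv = _GL_W[iv]
                y[0] = xc[0] + u * ((1.0 - v) * ax + v * bx)
                y[1] = xc[1] + u * ((1.0 - v) * ay + v * by)
                y[2] = xc[2] + u * ((1.0 - v) * az + v * bz)
                _G_eval(xc, y, wall, gtmp)
                w = wu * wv * u * jac
                for i in range(3):
                    for j in range(3):
                        out[i, j] += w * gtmp[i, j]


@njit(cache=True)
def _assemble(verts, centroids, wall, eta, max_depth):
    n = centroids.shape[0]
    A = np.zeros((3 * n, 3 * n))
    block = np.empty((3, 3))
    gtmp = np.empty((3, 3))
    y = np.empty(3)
    stk = np.empty((3 * (max_depth + 1) + 8, 10))
    sizes = np.empty(n)
    for e in range(n):
        e0 = (
            (verts[e, 0, 0] - verts[e, 1, 0]) ** 2
            + (verts[e, 0, 1] - verts[e, 1, 1]) ** 2
            + (verts[e, 0, 2] - verts[e, 1, 2]) ** 2
        )
        e1 = (
            (verts[e, 1, 0] - verts[e, 2, 0]) ** 2
            + (verts[e, 1, 1] - verts[e, 2, 1]) ** 2
            + (verts[e, 1, 2] - verts[e, 2, 2]) ** 2
        )
        e2 = (
            (verts[e, 2, 0] - verts[e, 0, 0]) ** 2
            + (verts[e, 2, 1] - verts[e, 0, 1]) ** 2
            + (verts[e, 2, 2] - verts[e, 0, 2]) ** 2
        )
        sizes[e] = max(e0, max(e1, e2))
    eta2 = eta * eta
    for c in range(n):
        xc = centroids[c]
        xm0 = -xc[0]
        for e in range(n):
            for i in range(3):
                for j in range(3):
                    block[i, j] = 0.0
            if e == c:
                _quad_self(xc, verts, e, wall, block, gtmp, y)
            else:
                ex = (verts[e, 0, 0] + verts[e, 1, 0] + verts[e, 2, 0]) / 3.0
                ey = (verts[e, 0, 1] + verts[e, 1, 1] + verts[e, 2, 1]) / 3.0
                ez = (verts[e, 0, 2] + verts[e, 1, 2] + verts[e, 2, 2]) / 3.0
                d2 = (xc[0] - ex) ** 2 + (xc[1] - ey) ** 2 + (xc[2] - ez) ** 2
                if wall:
                    dm2 = (xm0 - ex) ** 2 + (xc[1] - ey) ** 2 + (xc[2] - ez) ** 2
                    if dm2 < d2:
                        d2 = dm2
                if d2 > eta2 * sizes[e]:
                    _quad_regular_direct(xc, verts, e, wall, block, gtmp, y)
                else:
                    _quad_adaptive(xc, verts, e, wall, eta, max_depth, block, gtmp, y, stk)
            for i in range(3):
                for j in range(3):
                    A[3 * c + i, 3 * e + j] = block[i, j]
    return A


@njit(cache=True, inline="always")
def _quad_regular_direct(xc, verts, e, wall, out, gtmp, y):
    """3-point Gauss rule applied to an unsubdivided panel."""
    v0x, v0y, v0z = verts[e, 0, 0], verts[e, 0, 1], verts[e, 0, 2]
    v1x, v1y, v1z = verts[e, 1, 0], verts[e, 1, 1], verts[e, 1, 2]
    v2x, v2y, v2z = verts[e, 2, 0], verts[e, 2, 1], verts[e, 2, 2]
    cx = (v1y - v0y) * (v2z - v0z) - (v1z - v0z) * (v2y - v0y)
    cy = (v1z - v0z) * (v2x - v0x) - (v1x - v0x) * (v2z - v0z)
    cz = (v1x - v0x) * (v2y - v0y) - (v1y - v0y) * (v2x - v0x)
    area = 0.5 * math.sqrt(cx * cx + cy * cy + cz * cz)
    for q in range(3):
        b0, b1, b2 = _TRI_B[q, 0], _TRI_B[q, 1], _TRI_B[q, 2]
        y[0] = b0 * v0x + b1 * v1x + b2 * v2x
        y[1] = b0 * v0y + b1 * v1y + b2 * v2y
        y[2] = b0 * v0z + b1 * v1z + b2 * v2z
        _G_eval(xc, y, wall, gtmp)
        w = _TRI_W[q] * area
        for i in range(3):
            for j in range(3):
                out[i, j] += w * gtmp[i, j]


def assemble_single_layer(
    verts: np.ndarray,
    centroids: np.ndarray,
    wall: bool = False,
    eta: float = 3.0,
    max_depth: int = 3,
) -> np.ndarray:
    """Dense matrix of panel integrals ∫_e G(x_c, y) dS(y), shape (3N, 3N).

    ``verts`` is (N, 3, 3) triangle vertices in laboratory coordinates,
    ``centroids`` the (N, 3) collocation points.  With ``wall=True`` the
    Blake kernel for the plane x1 = 0 is used; all geometry must then lie
    strictly in x1 > 0.
    """
    verts = np.ascontiguousarray(verts, dtype=np.float64)
    centroids = np.ascontiguousarray(centroids, dtype=np.float64)
    if wall and (np.any(verts[..., 0] <= 0.0) or np.any(centroids[..., 0] <= 0.0)):
        raise ValueError("wall kernel requires all geometry strictly in x1 > 0")
    return _assemble(verts, centroids, wall, eta, max_depth)
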