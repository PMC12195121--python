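"""Low-level geometry kernels.

Two point-in-solid tests are provided on purpose: the generalized winding
number (van Oosterom & Strackee solid angles, robust to near-degenerate
triangles) is the production inside test, and parity ray casting
(Möller–Trumbore crossing count) is kept as an independent oracle.

Kernels are JIT-compiled with numba when available; a vectorized numpy
fallback keeps the package importable without it.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


_TWO_PI = 2.0 * math.pi


@njit(cache=True, fastmath=True)
def _winding_numbers_jit(points, tri):  # pragma: no cover - compiled
    n = points.shape[0]
    m = tri.shape[0]
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        px = points[i, 0]
        py = points[i, 1]
        pz = points[i, 2]
        acc = 0.0
        for j in range(m):
            ax = tri[j, 0, 0] - px
            ay = tri[j, 0, 1] - py
            az = tri[j, 0, 2] - pz
            bx = tri[j, 1, 0] - px
            by = tri[j, 1, 1] - py
            bz = tri[j, 1, 2] - pz
            cx = tri[j, 2, 0] - px
            cy = tri[j, 2, 1] - py
            cz = tri[j, 2, 2] - pz
            la = math.sqrt(ax * ax + ay * ay + az * az)
            lb = math.sqrt(bx * bx + by * by + bz * bz)
            lc = math.sqrt(cx * cx + cy * cy + cz * cz)
            det = (
                ax * (by * cz - bz * cy)
                - ay * (bx * cz - bz * cx)
                + az * (bx * cy - by * cx)
            )
            ab = ax * bx + ay * by + az * bz
            bc = bx * cx + by * cy + bz * cz
            ca = cx * ax + cy * ay + cz * az
            denom = la * lb * lc + ab * lc + bc * la + ca * lb
            acc += math.atan2(det, denom)
        out[i] = acc / _TWO_PI
    return out


def _winding_numbers_numpy(points, tri):
    out = np.empty(len(points), dtype=np.float64)
    # chunk points to bound the (points x faces) temporaries
    chunk = max(1, int(2_000_000 / max(1, len(tri))))
    for s in range(0, len(points), chunk):
        p = points[s : s + chunk]
        a = tri[None, :, 0, :] - p[:, None, :]
        b = tri[None, :, 1, :] - p[:, None, :]
        c = tri[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        det = np.einsum("pfi,pfi->pf", a, np.cross(b, c))
        denom = (
            la * lb * lc
            + np.einsum("pfi,pfi->pf", a, b) * lc
            + np.einsum("pfi,pfi->pf", b, c) * la
            + np.einsum("pfi,pfi->pf", c, a) * lb
        )
        out[s : s + chunk] = np.arctan2(det, denom).sum(axis=1) / _TWO_PI
    return out


def winding_numbers(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Generalized winding number of ``points`` w.r.t. a triangle soup.

    Parameters
    ----------
    points : (n, 3) float array
    triangles : (m, 3, 3) float array of triangle vertices

    Returns
    -------
    (n,) float array; ~1 inside a (consistently oriented) closed solid,
    ~0 outside.
    """
    points = np.ascontiguousarray(points, dtype=np.float64)
    triangles = np.ascontiguousarray(triangles, dtype=np.float64)
    if len(points) == 0:
        return np.zeros(0)
    if HAVE_NUMBA:
        return _winding_numbers_jit(points, triangles)
    return _winding_numbers_numpy(points, triangles)


@njit(cache=True, fastmath=True)
def _line_hits_jit(origin, direction, tri, ts):  # pragma: no cover - compiled
    m = tri.shape[0]
    count = 0
    for j in range(m):
        e1x = tri[j, 1, 0] - tri[j, 0, 0]
        e1y = tri[j, 1, 1] - tri[j, 0, 1]
        e1z = tri[j, 1, 2] - tri[j, 0, 2]
        e2x = tri[j, 2, 0] - tri[j, 0, 0]
        e2y = tri[j, 2, 1] - tri[j, 0, 1]
        e2z = tri[j, 2, 2] - tri[j, 0, 2]
        # h = d x e2
        hx = direction[1] * e2z - direction[2] * e2y
        hy = direction[2] * e2x - direction[0] * e2z
        hz = direction[0] * e2y - direction[1] * e2x
        a = e1x * hx + e1y * hy + e1z * hz
        if abs(a) < 1e-12:
            continue
        f = 1.0 / a
        sx = origin[0] - tri[j, 0, 0]
        sy = origin[1] - tri[j, 0, 1]
        sz = origin[2] - tri[j, 0, 2]
        u = f * (sx * hx + sy * hy + sz * hz)
        if u < 0.0 or u > 1.0:
            continue
        qx = sy * e1z - sz * e1y
        qy = sz * e1x - sx * e1z
        qz = sx * e1y - sy * e1x
        v = f * (direction[0] * qx + direction[1] * qy + direction[2] * qz)
        if v < 0.0 or u + v > 1.0:
            continue
        ts[count] = f * (e2x * qx + e2y * qy + e2z * qz)
        count += 1
    return count


def _line_hits_numpy(origin, direction, tri):
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    h = np.cross(direction[None, :], e2)
    a = np.einsum("fi,fi->f", e1, h)
    ok = np.abs(a) > 1e-12
    f = np.zeros_like(a)
    f[ok] = 1.0 / a[ok]
    s = origin[None, :] - v0
    u = f * np.einsum("fi,fi->f", s, h)
    q = np.cross(s, e1)
    v = f * (q @ direction)
    t = f * np.einsum("fi,fi->f", e2, q)
    hit = ok & (u >= 0) & (u <= 1) & (v >= 0) & (u + v <= 1)
    return t[hit]


def line_mesh_intersections(
    origin: np.ndarray, direction: np.ndarray, triangles: np.ndarray
) -> np.ndarray:
    """Signed parameters ``t`` of every intersection of the (unbounded) line
    ``origin + t * direction`` with a triangle soup (Möller–Trumbore)."""
    origin = np.ascontiguousarray(origin, dtype=np.float64)
    direction = np.ascontiguousarray(direction, dtype=np.float64)
    triangles = np.ascontiguousarray(triangles, dtype=np.float64)
    if HAVE_NUMBA:
        ts = np.empty(len(triangles), dtype=np.float64)
        count = _line_hits_jit(origin, direction, triangles, ts)
        return ts[:count]
    return _line_hits_numpy(origin, direction, triangles)


def parity_inside(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Point-in-solid by ray-crossing parity (independent oracle).

    Uses a fixed, deliberately skew ray direction so that rays do not run
    parallel to axis-aligned faces or through mesh edges in practice.
    """
    direction = np.array([0.5310293, 0.2871177, 0.7972351], dtype=np.float64)
    direction /= np.linalg.norm(direction)
    points = np.asarray(points, dtype=np.float64)
    out = np.zeros(len(points), dtype=bool)
    for i, p in enumerate(points):
        ts = line_mesh_intersections(p, direction, triangles)
        out[i] = (np.count_nonzero(ts > 0.0) % 2) == 1
    return out
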