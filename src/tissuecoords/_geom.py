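"""Low-level geometry kernels shared across modules.

Everything here operates on plain numpy arrays: vertices ``(N, 3)`` float64,
triangles ``(M, 3)`` int.  All lengths are in micrometres.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "triangle_areas",
    "triangle_normals",
    "triangle_centroids",
    "area_weighted_normal",
    "tangent_basis",
    "polygon_area_3d",
    "ray_mesh_hits",
    "plane_cross_section_area",
    "fibonacci_hemisphere",
    "mesh_volume_centroid",
]


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def triangle_normals(vertices: np.ndarray, triangles: np.ndarray, normalize: bool = True) -> np.ndarray:
    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]
    n = np.cross(b - a, c - a)
    if normalize:
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        n = n / norms
    return n


def triangle_centroids(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    return vertices[triangles].mean(axis=1)


def area_weighted_normal(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Unit normal of a (nearly planar) triangle patch, weighted by area."""
    n = triangle_normals(vertices, triangles, normalize=False).sum(axis=0)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("degenerate patch: zero total normal")
    return n / norm


def tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed orthonormal basis (e1, e2) of the plane orthogonal to *normal*."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(helper, n)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def polygon_area_3d(points: np.ndarray) -> float:
    """Area of a closed (not necessarily convex) planar polygon embedded in 3D."""
    p = np.asarray(points, dtype=float)
    s = np.cross(p, np.roll(p, -1, axis=0)).sum(axis=0)
    return 0.5 * float(np.linalg.norm(s))


def ray_mesh_hits(
    origin: np.ndarray,
    direction: np.ndarray,
    vertices: np.ndarray,
    triangles: np.ndarray,
    eps: float = 1e-12,
) -> np.ndarray:
    """Sorted positive hit distances of a ray against a triangle soup.

    Vectorised Moller-Trumbore.  Returns an array of ``t`` values (may be
    empty).  Hits closer than ``1e-9`` to the origin are kept — callers that
    cast from a surface point should filter themselves.
    """
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    v0 = vertices[triangles[:, 0]]
    e1 = vertices[triangles[:, 1]] - v0
    e2 = vertices[triangles[:, 2]] - v0
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > eps
    inv_det = np.zeros_like(det)
    inv_det[ok] = 1.0 / det[ok]
    tvec = o - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1)
    v = np.einsum("j,ij->i", d, qvec) * inv_det
    t = np.einsum("ij,ij->i", e2, qvec) * inv_det
    hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > 1e-9)
    return np.sort(t[hit])


def plane_cross_section_area(
    vertices: np.ndarray,
    triangles: np.ndarray,
    point: np.ndarray,
    normal: np.ndarray,
) -> float:
    """Area of the planar cross-section of a closed, outward-oriented mesh.

    Each triangle crossing the plane contributes one oriented segment of the
    intersection curve; by Stokes' theorem the enclosed (possibly
    multi-component) area is half the magnitude of the summed cross products.
    Non-convex cells with several disjoint section polygons sum their areas.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    p0 = np.asarray(point, dtype=float)
    v = vertices - p0
    d = v @ n
    tri_d = d[triangles]
    signs = tri_d > 0
    npos = signs.sum(axis=1)
    crossing = (npos == 1) | (npos == 2)
    if not np.any(crossing):
        return 0.0
    total = np.zeros(3)
    for ti in np.nonzero(crossing)[0]:
        idx = triangles[ti]
        dd = tri_d[ti]
        pos = dd > 0
        # the lone vertex on one side; segment endpoints ordered following
        # the triangle's winding so outward orientation induces a consistent
        # curve orientation
        if pos.sum() == 1:
            k = int(np.nonzero(pos)[0][0])
        else:
            k = int(np.nonzero(~pos)[0][0])
        a, b, c = idx[(k) % 3], idx[(k + 1) % 3], idx[(k + 2) % 3]
        da, db, dc = dd[k % 3], dd[(k + 1) % 3], dd[(k + 2) % 3]
        # intersections on edges (a,b) and (c,a)
        t1 = da / (da - db)
        p1 = vertices[a] + t1 * (vertices[b] - vertices[a])
        t2 = dc / (dc - da)
        p2 = vertices[c] + t2 * (vertices[a] - vertices[c])
        if pos.sum() == 1:
            seg = (p1 - p0, p2 - p0)
        else:
            seg = (p2 - p0, p1 - p0)
        total += np.cross(seg[0], seg[1])
    return 0.5 * abs(float(total @ n))


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """``n`` approximately equally distributed unit directions on a hemisphere.

    Golden-angle spiral on z >= 0; directions are pairwise distinct.
    """
    i = np.arange(n)
    z = (i + 0.5) / n          # uniform in z -> uniform in solid angle
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def mesh_volume_centroid(vertices: np.ndarray, triangles: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed volume and volume centroid of a closed outward-oriented mesh.

    Divergence theorem over signed tetrahedra against the origin.
    """
    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]
    cross = np.cross(b - a, c - a)
    vol6 = np.einsum("ij,ij->i", a, cross)
    volume = vol6.sum() / 6.0
    centroid = ((a + b + c) / 4.0 * vol6[:, None]).sum(axis=0) / (vol6.sum() if vol6.sum() != 0 else 1.0)
    return float(volume), centroid
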