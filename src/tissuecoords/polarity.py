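"""Signal polarity and fibril (microtubule) orientation per cell.

Border polarity bins the signal along a cell's outline by angle about the
cell centre and reports the circular resultant: its direction is the
predominant polarity, its normalised length (0..1) the polarity strength.
Fibril orientation adapts image-gradient fibril analysis to surfaces: the
per-triangle in-plane signal gradient feeds a nematic (second-moment)
tensor; fibrils run along the eigenvector of the SMALLER eigenvalue
(perpendicular to the dominant gradient), with anisotropy
(λ₁−λ₂)/(λ₁+λ₂).  Volumetric cells get a 3D wall-signal polarity vector.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _geom
from .core import CellSurface, SurfaceCellMesh

__all__ = [
    "PolarityVector",
    "FibrilOrientation",
    "border_polarity",
    "fibril_orientation",
    "polarity_3d",
    "direction_angle",
]


@dataclass
class PolarityVector:
    direction: np.ndarray | None   # unit; None when magnitude below threshold
    magnitude: float               # resultant length, [0, 1]
    total_signal: float            # a.u.


@dataclass
class FibrilOrientation:
    orientation: np.ndarray        # axial (defined up to sign), unit
    anisotropy: float              # [0, 1]


def border_polarity(mesh: SurfaceCellMesh, label: int, n_bins: int = 72,
                    border_width: float = 1.0,
                    magnitude_threshold: float = 0.05) -> PolarityVector:
    """Polarity of the border signal of one surface cell.

    Border vertices (within ``border_width`` µm geodesic of the outline) are
    binned by angle about the cell centroid in the tangent plane; the
    signal-weighted vector resultant Σ sᵢ(cosθᵢ, sinθᵢ)/Σ sᵢ gives direction
    and magnitude.  Magnitude is 0 for uniform signal; the direction is
    flagged ``None`` below ``magnitude_threshold``.
    """
    if mesh.vertex_signal is None:
        raise ValueError("mesh has no vertex signal")
    if n_bins < 4:
        raise ValueError("need at least 4 angular bins")
    loop = mesh.cell_boundary_loop(label)
    # border band: cell triangles whose vertices all lie within border_width
    # of the outline; sampled by edge-midpoint quadrature (area weights), so
    # the angular bin means are area-fair estimates of the border signal
    from scipy.spatial import cKDTree
    pts = mesh.vertices[loop]
    tree = cKDTree(pts)
    idx = mesh.cell_triangle_indices(label)
    tri = mesh.triangles[idx]
    verts = np.unique(tri)
    d_out, _ = tree.query(mesh.vertices[verts])
    near = dict(zip(verts.tolist(), (d_out <= border_width + 1e-12).tolist()))
    band = np.array([all(near[int(v_)] for v_ in t) for t in tri])
    if not band.any():
        band = np.ones(len(tri), dtype=bool)   # border wider than the cell
    btri = tri[band]
    areas = _geom.triangle_areas(mesh.vertices, btri)
    va, vb, vc = (mesh.vertices[btri[:, k]] for k in range(3))
    sa, sb, sc = (mesh.vertex_signal[btri[:, k]] for k in range(3))
    sample_pts = np.concatenate([(va + vb) / 2, (vb + vc) / 2, (vc + va) / 2])
    s = np.concatenate([(sa + sb) / 2, (sb + sc) / 2, (sc + sa) / 2])
    wq = np.tile(areas / 3.0, 3)
    c = mesh.cell_centroid(label)
    n = mesh.cell_normal(label)
    e1, e2 = _geom.tangent_basis(n)
    rel = sample_pts - c
    u = rel @ e1
    v = rel @ e2
    theta = np.arctan2(v, u)
    total = float(s.sum())
    if total <= 0:
        return PolarityVector(direction=None, magnitude=0.0, total_signal=0.0)
    # per-bin area-weighted MEAN signal: uneven sampling density then cannot
    # masquerade as polarity (uniform signal gives identical bin means,
    # resultant 0)
    bins = np.floor((theta + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    sums = np.bincount(bins, weights=s * wq, minlength=n_bins)
    counts = np.bincount(bins, weights=wq, minlength=n_bins)
    covered = counts > 0
    means = np.zeros(n_bins)
    means[covered] = sums[covered] / counts[covered]
    centers = (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins - np.pi
    # centre the bin means so incomplete angular coverage cannot masquerade
    # as polarity: uniform signal gives exactly zero resultant
    centered = means[covered] - means[covered].mean()
    rx = float((centered * np.cos(centers[covered])).sum())
    ry = float((centered * np.sin(centers[covered])).sum())
    mag = np.hypot(rx, ry) / max(means[covered].sum(), 1e-300)
    if mag < magnitude_threshold:
        return PolarityVector(direction=None, magnitude=float(mag), total_signal=total)
    d3 = rx * e1 + ry * e2
    return PolarityVector(direction=d3 / np.linalg.norm(d3),
                          magnitude=float(mag), total_signal=total)


def fibril_orientation(mesh: SurfaceCellMesh, label: int,
                       min_gradient: float = 1e-12) -> FibrilOrientation | None:
    """Fibril orientation of one cell from the nematic tensor of per-triangle
    signal gradients (linear shape functions); ``None`` for constant signal.
    """
    if mesh.vertex_signal is None:
        raise ValueError("mesh has no vertex signal")
    idx = mesh.cell_triangle_indices(label)
    tri = mesh.triangles[idx]
    n = mesh.cell_normal(label)
    e1, e2 = _geom.tangent_basis(n)
    B = np.column_stack([e1, e2])
    areas = _geom.triangle_areas(mesh.vertices, tri)
    T = np.zeros((2, 2))
    total_area = 0.0
    for t, a in zip(tri, areas):
        p = (mesh.vertices[t]) @ B          # 3x2 in tangent coords
        s = mesh.vertex_signal[t]
        # gradient of the linear interpolant on the triangle
        M = np.column_stack([p[1] - p[0], p[2] - p[0]])
        try:
            g = np.linalg.solve(M.T, np.array([s[1] - s[0], s[2] - s[0]]))
        except np.linalg.LinAlgError:
            continue
        norm = np.linalg.norm(g)
        if norm <= min_gradient:
            continue
        ghat = g / norm
        T += a * np.outer(ghat, ghat)
        total_area += a
    if total_area == 0:
        return None
    T /= total_area
    w, v = np.linalg.eigh(T)
    lam_small, lam_big = w[0], w[1]
    aniso = (lam_big - lam_small) / (lam_big + lam_small) if (lam_big + lam_small) > 0 else 0.0
    fib2 = v[:, 0]                          # eigenvector of the SMALLER eigenvalue
    fib3 = fib2[0] * e1 + fib2[1] * e2
    return FibrilOrientation(orientation=fib3 / np.linalg.norm(fib3),
                             anisotropy=float(aniso))


def polarity_3d(cell: CellSurface, wall_signal: np.ndarray,
                magnitude_threshold: float = 0.05) -> PolarityVector:
    """3D polarity of a volumetric cell from per-wall-triangle signal:
    direction of Σ sᵢ·aᵢ·(pᵢ − centroid), magnitude normalised by
    Σ sᵢ·aᵢ·|pᵢ − centroid| (area-weighted)."""
    s = np.asarray(wall_signal, dtype=float)
    if len(s) != len(cell.triangles):
        raise ValueError("wall_signal must have one value per wall triangle")
    total = float(s.sum())
    if total <= 0:
        return PolarityVector(direction=None, magnitude=0.0, total_signal=0.0)
    c = cell.centroid()
    pts = _geom.triangle_centroids(cell.vertices, cell.triangles) - c
    areas = _geom.triangle_areas(cell.vertices, cell.triangles)
    w = s * areas
    resultant = (pts * w[:, None]).sum(axis=0)
    norm = float((np.linalg.norm(pts, axis=1) * w).sum())
    mag = float(np.linalg.norm(resultant) / norm) if norm > 0 else 0.0
    if mag < magnitude_threshold:
        return PolarityVector(direction=None, magnitude=mag, total_signal=total)
    return PolarityVector(direction=resultant / np.linalg.norm(resultant),
                          magnitude=mag, total_signal=total)


def direction_angle(direction, axis, axial: bool = False) -> float:
    """Angle in degrees between a cell direction and a reference axis.

    Polar vectors give [0, 180]; axial directions (fibrils, undirected axes)
    are folded to [0, 90].
    """
    d = np.asarray(direction, dtype=float)
    a = np.asarray(axis, dtype=float)
    cosang = float(d @ a / (np.linalg.norm(d) * np.linalg.norm(a)))
    if axial:
        cosang = abs(cosang)
    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return ang
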