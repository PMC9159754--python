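"""Cell-division analysis in 2.5D and 3D.

Given a lineage, each once-divided mother cell is analysed: the actual
division wall is approximated by a PCA plane (3D) or line (2.5D) through the
shared-wall vertices of the two daughters; candidate division planes through
the mother's centroid are simulated (1000 equally distributed directions on
the hemisphere by default, or 1° chord sweeps in 2.5D) and ranked by
cross-section area / chord length, exposing the shortest-wall candidates and
local minima; daughter size asymmetry and angles between planes and organ
axes complete the record.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _geom
from .core import CellSurface, ParentMap, SurfaceCellMesh, VolumetricCellMesh

__all__ = [
    "DivisionRecord",
    "detect_divisions",
    "fit_division_plane",
    "shared_wall_vertices",
    "combine_daughters",
    "enumerate_candidate_planes",
    "enumerate_candidate_chords",
    "rank_planes",
    "division_plane_angles",
    "daughter_asymmetry",
    "analyze_division_3d",
    "analyze_division_2d",
]


@dataclass
class DivisionRecord:
    """One division: actual plane fit, daughter asymmetry and the simulated
    candidate planes with their sizes (cross-section area in µm² for 3D,
    chord length in µm for 2.5D)."""
    mother: int
    daughters: tuple[int, int]
    plane_point: np.ndarray
    plane_normal: np.ndarray            # unit; in 2.5D the in-plane normal of the wall line
    wall_direction: np.ndarray | None   # 2.5D: best-fit line direction of the wall
    asymmetry: float                    # |s1 - s2| / (s1 + s2)
    candidate_normals: np.ndarray | None = None   # (n, 3)
    candidate_sizes: np.ndarray | None = None     # (n,)
    actual_size: float | None = None
    rank_info: dict = field(default_factory=dict)


def detect_divisions(parents: ParentMap) -> list[int]:
    """Mothers that divided exactly once (exactly two children)."""
    counts: dict[int, int] = {}
    for p in parents.values():
        counts[p] = counts.get(p, 0) + 1
    return sorted(p for p, n in counts.items() if n == 2)


# --------------------------------------------------------------------------
# Actual-plane fitting
# --------------------------------------------------------------------------

def shared_wall_vertices(mesh, daughter_a: int, daughter_b: int) -> np.ndarray:
    """Vertex positions on the wall shared by two daughter cells."""
    if isinstance(mesh, VolumetricCellMesh):
        cell = mesh.cells[daughter_a]
        mask = cell.wall_label == daughter_b
        if not mask.any():
            raise ValueError(f"cells {daughter_a} and {daughter_b} share no wall")
        return cell.vertices[np.unique(cell.triangles[mask])]
    # surface mesh: vertices on edges shared by triangles of both labels
    uniq, start, counts, tri_idx = mesh._edge_tables()
    offsets = np.concatenate([[0], np.cumsum(counts)])
    pts = []
    for e in range(len(uniq)):
        if counts[e] < 2:
            continue
        labs = {int(mesh.face_label[t]) for t in tri_idx[offsets[e]:offsets[e + 1]]}
        if daughter_a in labs and daughter_b in labs:
            pts.extend(uniq[e])
    if not pts:
        raise ValueError(f"cells {daughter_a} and {daughter_b} share no boundary")
    return mesh.vertices[np.unique(np.array(pts))]


def fit_division_plane(wall_vertices: np.ndarray, tangent_normal: np.ndarray | None = None):
    """PCA plane (3D) or line (2.5D) through the division-wall vertices.

    Returns ``(point, normal, direction)``: the vertex centroid, the
    smallest-variance principal axis (the plane normal), and the
    largest-variance axis (the wall's line direction, meaningful in 2.5D).
    With ``tangent_normal`` given (2.5D), vertices are analysed within the
    tissue tangent plane and the returned normal is the in-plane normal of
    the wall line.  Collinear 3D vertex sets are flagged as degenerate.
    """
    pts = np.asarray(wall_vertices, dtype=float).reshape(-1, 3)
    if tangent_normal is None and len(pts) < 3:
        raise ValueError("need >= 3 wall vertices for a 3D plane fit")
    if tangent_normal is not None and len(pts) < 2:
        raise ValueError("need >= 2 wall vertices for a 2.5D line fit")
    center = pts.mean(axis=0)
    X = pts - center
    if tangent_normal is not None:
        n = np.asarray(tangent_normal, dtype=float)
        n = n / np.linalg.norm(n)
        X = X - np.outer(X @ n, n)
        cov = X.T @ X / len(X)
        w, v = np.linalg.eigh(cov)
        direction = v[:, np.argmax(w)]
        normal = np.cross(n, direction)
        normal /= np.linalg.norm(normal)
        return center, normal, direction
    cov = X.T @ X / len(X)
    w, v = np.linalg.eigh(cov)
    if w[1] < 1e-12 * max(w[2], 1.0):
        raise ValueError("degenerate wall: vertices are collinear")
    normal = v[:, 0]
    direction = v[:, 2]
    return center, normal, direction


# --------------------------------------------------------------------------
# Candidate planes (3D)
# --------------------------------------------------------------------------

def combine_daughters(mesh: VolumetricCellMesh, daughter_a: int, daughter_b: int) -> CellSurface:
    """Reconstitute the mother cell: the union of the two daughters with the
    shared wall removed.  Watertight because the daughters' wall patches
    match."""
    tris = []
    for lab, sibling in ((daughter_a, daughter_b), (daughter_b, daughter_a)):
        cell = mesh.cells[lab]
        keep = cell.wall_label != sibling
        for t in cell.triangles[keep]:
            tris.append([cell.vertices[t[0]], cell.vertices[t[1]], cell.vertices[t[2]]])
    pts = np.array([p for tri in tris for p in tri])
    key = np.round(pts * 1e8).astype(np.int64)
    uniq, inverse = np.unique(key, axis=0, return_inverse=True)
    verts = np.zeros((len(uniq), 3))
    verts[inverse] = pts
    tri_idx = inverse.reshape(-1, 3)
    return CellSurface(verts, tri_idx, np.zeros(len(tri_idx), dtype=np.int64))


def enumerate_candidate_planes(mother: CellSurface, n: int = 1000):
    """Simulate ``n`` equally distributed division planes through the
    mother's volume centroid (Fibonacci lattice on the hemisphere) and
    measure each plane's cell cross-section area.

    Returns ``(normals (n,3), areas (n,))``.  Disjoint section polygons of
    non-convex cells sum their areas.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not mother.is_watertight():
        raise ValueError("mother cell surface is not watertight")
    _, centroid = _geom.mesh_volume_centroid(mother.vertices, mother.triangles)
    normals = _geom.fibonacci_hemisphere(n)
    areas = np.array([
        _geom.plane_cross_section_area(mother.vertices, mother.triangles, centroid, nrm)
        for nrm in normals])
    return normals, areas


def enumerate_candidate_chords(mesh: SurfaceCellMesh, label: int, step_deg: float = 1.0):
    """2.5D candidates: chords of the cell polygon through its area centroid,
    swept at ``step_deg`` steps over 180° in the cell tangent plane.

    Returns ``(directions (n,3) world, lengths (n,))``.
    """
    from shapely.geometry import LineString, Polygon
    loop = mesh.cell_boundary_loop(label)
    nrm = mesh.cell_normal(label)
    e1, e2 = _geom.tangent_basis(nrm)
    origin = mesh.cell_centroid(label)
    p2 = (mesh.vertices[loop] - origin) @ np.column_stack([e1, e2])
    poly = Polygon(p2)
    if not poly.is_valid:
        poly = poly.buffer(0)
    c = np.array([poly.centroid.x, poly.centroid.y])   # area centroid
    span = 4.0 * max(np.abs(p2).max(), 1e-9)
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs, lengths = [], []
    for a in angles:
        d = np.array([np.cos(a), np.sin(a)])
        line = LineString([c - span * d, c + span * d])
        inter = line.intersection(poly)
        lengths.append(inter.length)
        dirs.append(d[0] * e1 + d[1] * e2)
    return np.array(dirs), np.array(lengths)


def rank_planes(sizes: np.ndarray, normals: np.ndarray | None = None,
                actual_size: float | None = None, k_neighbors: int = 6) -> dict:
    """Shortest candidate(s), local minima and the actual plane's percentile
    rank among the simulated candidates.

    A local minimum is a candidate smaller than all of its angular
    neighbours — the adjacent directions in a 2.5D sweep, the ``k`` nearest
    (axial) directions in 3D.
    """
    sizes = np.asarray(sizes, dtype=float)
    n = len(sizes)
    best = int(np.argmin(sizes))
    minima = []
    if normals is None:
        for i in range(n):
            if sizes[i] < sizes[(i - 1) % n] and sizes[i] < sizes[(i + 1) % n]:
                minima.append(i)
    else:
        normals = np.asarray(normals, dtype=float)
        dots = np.abs(normals @ normals.T)
        for i in range(n):
            nb = np.argsort(-dots[i])[1:k_neighbors + 1]
            if np.all(sizes[i] < sizes[nb]):
                minima.append(i)
    out = {"best_index": best, "best_size": float(sizes[best]), "local_minima": minima}
    if actual_size is not None:
        out["actual_percentile"] = float(100.0 * np.mean(sizes <= actual_size))
    return out


def division_plane_angles(plane_normal: np.ndarray, axis: np.ndarray) -> float:
    """Angle between a division PLANE and an axis, degrees in [0, 90].

    90° means the plane is perpendicular to the axis (normal parallel to
    it); 0° means the plane contains the axis.
    """
    n = np.asarray(plane_normal, dtype=float)
    a = np.asarray(axis, dtype=float)
    n = n / np.linalg.norm(n)
    a = a / np.linalg.norm(a)
    angle_normal_axis = np.degrees(np.arccos(np.clip(abs(n @ a), -1.0, 1.0)))
    return float(90.0 - angle_normal_axis)


def daughter_asymmetry(s1: float, s2: float) -> float:
    """|s1 - s2| / (s1 + s2): 0 for equal daughters, label-order invariant."""
    if s1 + s2 <= 0:
        raise ValueError("daughter sizes must be positive")
    return float(abs(s1 - s2) / (s1 + s2))


# --------------------------------------------------------------------------
# Whole-record drivers
# --------------------------------------------------------------------------

def analyze_division_3d(mesh_t1: VolumetricCellMesh, mother: int,
                        daughters: tuple[int, int], n_planes: int = 1000) -> DivisionRecord:
    da, db = daughters
    wall = shared_wall_vertices(mesh_t1, da, db)
    point, normal, direction = fit_division_plane(wall)
    sa = mesh_t1.cells[da].volume()
    sb = mesh_t1.cells[db].volume()
    combined = combine_daughters(mesh_t1, da, db)
    normals, areas = enumerate_candidate_planes(combined, n_planes)
    actual_area = _geom.plane_cross_section_area(
        combined.vertices, combined.triangles, point, normal)
    rec = DivisionRecord(mother=mother, daughters=(da, db), plane_point=point,
                         plane_normal=normal, wall_direction=None,
                         asymmetry=daughter_asymmetry(sa, sb),
                         candidate_normals=normals, candidate_sizes=areas,
                         actual_size=float(actual_area))
    rec.rank_info = rank_planes(areas, normals, actual_size=rec.actual_size)
    return rec


def analyze_division_2d(mesh_t1: SurfaceCellMesh, mother: int,
                        daughters: tuple[int, int], step_deg: float = 1.0) -> DivisionRecord:
    da, db = daughters
    wall = shared_wall_vertices(mesh_t1, da, db)
    # tangent normal from the daughters' union
    idx = np.concatenate([mesh_t1.cell_triangle_indices(da),
                          mesh_t1.cell_triangle_indices(db)])
    nrm = _geom.area_weighted_normal(mesh_t1.vertices, mesh_t1.triangles[idx])
    point, normal, direction = fit_division_plane(wall, tangent_normal=nrm)
    sa = mesh_t1.cell_area(da)
    sb = mesh_t1.cell_area(db)
    wall_sorted = wall[np.argsort((wall - point) @ direction)]
    actual_len = float(np.linalg.norm(wall_sorted[-1] - wall_sorted[0]))
    # candidate chords need the reconstituted mother polygon: relabel the
    # daughters into one temporary cell
    relab = mesh_t1.face_label.copy()
    tmp = int(max(mesh_t1.labels())) + 1
    relab[(mesh_t1.face_label == da) | (mesh_t1.face_label == db)] = tmp
    merged = SurfaceCellMesh(mesh_t1.vertices, mesh_t1.triangles, relab)
    dirs, lengths = enumerate_candidate_chords(merged, tmp, step_deg=step_deg)
    rec = DivisionRecord(mother=mother, daughters=(da, db), plane_point=point,
                         plane_normal=normal, wall_direction=direction,
                         asymmetry=daughter_asymmetry(sa, sb),
                         candidate_normals=dirs, candidate_sizes=lengths,
                         actual_size=actual_len)
    rec.rank_info = rank_planes(lengths, normals=None, actual_size=actual_len)
    return rec
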