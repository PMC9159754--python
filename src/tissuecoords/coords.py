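"""Organ-centric coordinate systems and per-cell direction frames.

Positional information is attached to cells as attribute maps: graph
distances to seed cells, arc-length coordinates along a Bezier axis, polar
angles around a Cartesian axis, distances to another mesh, and the relative
radial coordinate combining a central axis with the organ surface.  Direction
fields (heat-map gradients, axis tangents, surface normals) are combined into
right-handed orthonormal per-cell frames.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from . import _geom
from .core import AttributeMap, SurfaceCellMesh, VolumetricCellMesh

__all__ = [
    "BezierSpline",
    "CellFrame",
    "cell_distance",
    "bezier_line_coord",
    "bezier_from_cell_file",
    "polar_coord",
    "mesh_distance",
    "relative_radial_coord",
    "attribute_gradient_directions",
    "build_cell_frame",
]

WEIGHT_MODES = ("euclidean", "cells", "inv_wall")
_WALL_FLOOR = 1e-9


class CellFrame(AttributeMap):
    """Per-cell right-handed orthonormal triads.

    Values are ``(3, 3)`` arrays whose ROWS are ``d1`` (primary /
    longitudinal), ``d2`` (secondary — normal or radial) and ``d3``
    (orthogonal complement, ``d1 x d2``).
    """

    def __init__(self, data=None, name: str = "frame"):
        super().__init__(data, name=name)


# --------------------------------------------------------------------------
# Bezier splines
# --------------------------------------------------------------------------

_GL_X, _GL_W = np.polynomial.legendre.leggauss(8)


@dataclass
class BezierSpline:
    """Composite cubic Bezier curve with clamped ends.

    ``control_points`` has ``3 * n_segments + 1`` rows; consecutive segments
    share their joint control point (C0).  The global parameter ``t`` in
    [0, 1] is uniform across segments.  An arc-length lookup table (1000
    samples per segment, lengths by Gauss-Legendre quadrature between
    samples) supports the parameter <-> arc-length conversions.
    """
    control_points: np.ndarray
    samples_per_segment: int = 1000
    _table: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        cp = np.asarray(self.control_points, dtype=float).reshape(-1, 3)
        if len(cp) < 4 or (len(cp) - 1) % 3 != 0:
            raise ValueError("composite cubic Bezier needs 3k+1 control points (k >= 1)")
        if np.allclose(cp, cp[0]):
            raise ValueError("degenerate spline: all control points equal")
        self.control_points = cp

    @property
    def n_segments(self) -> int:
        return (len(self.control_points) - 1) // 3

    @classmethod
    def from_endpoints(cls, p0, p1) -> "BezierSpline":
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        return cls(np.array([p0, p0 + (p1 - p0) / 3, p0 + 2 * (p1 - p0) / 3, p1]))

    def _segment(self, t: np.ndarray):
        t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
        k = np.minimum((t * self.n_segments).astype(int), self.n_segments - 1)
        u = t * self.n_segments - k
        return k, u

    def evaluate(self, t) -> np.ndarray:
        k, u = self._segment(t)
        cp = self.control_points
        p = np.zeros(np.shape(k) + (3,))
        for j, b in enumerate(_bernstein3(u)):
            p += b[..., None] * cp[3 * k + j]
        return p

    def tangent(self, t, normalize: bool = True) -> np.ndarray:
        k, u = self._segment(t)
        cp = self.control_points
        d = np.zeros(np.shape(k) + (3,))
        for j, b in enumerate(_bernstein2(u)):
            d += b[..., None] * (cp[3 * k + j + 1] - cp[3 * k + j]) * 3 * self.n_segments
        if normalize:
            n = np.linalg.norm(d, axis=-1, keepdims=True)
            n[n == 0] = 1.0
            d = d / n
        return d

    def _arc_table(self):
        if self._table is None:
            n = self.samples_per_segment * self.n_segments
            t = np.linspace(0.0, 1.0, n + 1)
            # Gauss-Legendre quadrature of |B'| on each sub-interval
            mid = (t[:-1] + t[1:]) / 2
            half = (t[1:] - t[:-1]) / 2
            seg_len = np.zeros(n)
            for x, w in zip(_GL_X, _GL_W):
                speed = np.linalg.norm(self.tangent(mid + x * half, normalize=False), axis=-1)
                seg_len += w * speed * half
            cum = np.concatenate([[0.0], np.cumsum(seg_len)])
            object.__setattr__(self, "_table", (t, cum))
        return self._table

    def arc_length(self, t=1.0) -> np.ndarray:
        tt, cum = self._arc_table()
        return np.interp(np.clip(t, 0, 1), tt, cum)

    @property
    def total_length(self) -> float:
        return float(self.arc_length(1.0))

    def nearest_parameter(self, point: np.ndarray) -> float:
        """Parameter of the spline point closest to *point*: winning sample of
        the dense polyline, refined by golden-section search around it."""
        tt, _ = self._arc_table()
        pts = self.evaluate(tt)
        d2 = ((pts - np.asarray(point, dtype=float)) ** 2).sum(axis=1)
        i = int(np.argmin(d2))
        lo = tt[max(i - 1, 0)]
        hi = tt[min(i + 1, len(tt) - 1)]
        return _golden_section(lambda t: ((self.evaluate(t) - point) ** 2).sum(), lo, hi)


def _bernstein3(u):
    v = 1 - u
    return [v ** 3, 3 * v ** 2 * u, 3 * v * u ** 2, u ** 3]


def _bernstein2(u):
    v = 1 - u
    return [v ** 2, 2 * v * u, u ** 2]


def _golden_section(f, lo, hi, tol=1e-10, max_iter=200):
    phi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = f(d)
    return (a + b) / 2


def bezier_from_cell_file(cells: list[int], mesh, n_segments: int | None = None) -> BezierSpline:
    """Least-squares composite cubic Bezier through the ordered centroids of a
    cell file.  Endpoint interpolation is exact; interior control points are
    fitted with chord-length parameterization."""
    if len(cells) < 2:
        raise ValueError("a cell file needs at least 2 cells")
    centroids = np.array([_centroid_of(mesh, int(c)) for c in cells])
    if len(cells) == 2:
        return BezierSpline.from_endpoints(centroids[0], centroids[1])
    chord = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(chord)])
    t /= t[-1]
    if n_segments is None:
        n_segments = max(1, (len(cells) - 1) // 4)
    n_cp = 3 * n_segments + 1
    k = np.minimum((t * n_segments).astype(int), n_segments - 1)
    u = t * n_segments - k
    A = np.zeros((len(t), n_cp))
    for j, b in enumerate(_bernstein3(u)):
        A[np.arange(len(t)), 3 * k + j] += b
    # pin the endpoints exactly, solve for interior control points
    rhs = centroids - np.outer(A[:, 0], centroids[0]) - np.outer(A[:, -1], centroids[-1])
    interior, *_ = np.linalg.lstsq(A[:, 1:-1], rhs, rcond=None)
    cp = np.vstack([centroids[0], interior, centroids[-1]])
    return BezierSpline(cp)


# --------------------------------------------------------------------------
# Coordinate operations
# --------------------------------------------------------------------------

def _centroid_of(mesh, label: int) -> np.ndarray:
    if isinstance(mesh, VolumetricCellMesh):
        return mesh.cells[label].centroid()
    if hasattr(mesh, "cell_centroid"):
        return mesh.cell_centroid(label)
    return mesh.centroids()[label]


def _centroids(mesh) -> dict[int, np.ndarray]:
    return mesh.centroids()


def cell_distance(graph: nx.Graph, seeds, weight_mode: str = "cells") -> AttributeMap:
    """Shortest-path distance of every cell to the nearest seed cell.

    Dijkstra on the cell connectivity graph; edge weights are centroid
    distances (``euclidean``, µm), 1 per edge (``cells``) or the inverse
    shared-wall measure (``inv_wall``).  Seeds get 0; unreachable cells are
    left unassigned.
    """
    seeds = [int(s) for s in seeds]
    if not seeds:
        raise ValueError("empty seed set")
    missing = [s for s in seeds if s not in graph]
    if missing:
        raise ValueError(f"seed cells not in graph: {missing}")
    if weight_mode not in WEIGHT_MODES:
        raise ValueError(f"weight_mode must be one of {WEIGHT_MODES}")

    if weight_mode == "cells":
        wfun = lambda u, v, d: 1.0
        unit = "cells"
    elif weight_mode == "euclidean":
        wfun = lambda u, v, d: float(np.linalg.norm(
            graph.nodes[u]["centroid"] - graph.nodes[v]["centroid"]))
        unit = "µm"
    else:
        wfun = lambda u, v, d: 1.0 / max(d["wall_measure"], _WALL_FLOOR)
        unit = ""
    dist = nx.multi_source_dijkstra_path_length(graph, set(seeds), weight=wfun)
    return AttributeMap({int(k): float(v) for k, v in dist.items()},
                        name=f"cell_distance_{weight_mode}", unit=unit)


def bezier_line_coord(mesh, spline: BezierSpline):
    """Arc-length coordinate along a Bezier axis for every cell.

    Returns ``(coord, distance, tangent)`` attribute maps: arc length at the
    spline point nearest the cell centroid (clamped to [0, total length]),
    the Euclidean distance to that point, and the unit spline tangent there.
    """
    coord = AttributeMap(name="bezier_coord", unit="µm")
    dist = AttributeMap(name="bezier_distance", unit="µm")
    tang = AttributeMap(name="bezier_tangent")
    for lab, c in _centroids(mesh).items():
        t = spline.nearest_parameter(c)
        p = spline.evaluate(t)
        coord[lab] = float(spline.arc_length(t))
        dist[lab] = float(np.linalg.norm(c - p))
        tang[lab] = spline.tangent(t)
    return coord, dist, tang


def polar_coord(mesh, axis="z", reference=(1.0, 0.0, 0.0), origin=(0.0, 0.0, 0.0)) -> AttributeMap:
    """Angle of each centroid around a Cartesian axis, degrees in [0, 360),
    measured from the reference direction (projected into the plane
    perpendicular to the axis).  Centroids on the axis are left unassigned."""
    ax = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]),
          "z": np.array([0, 0, 1.0])}.get(axis, None)
    if ax is None:
        ax = np.asarray(axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
    ref = np.asarray(reference, dtype=float)
    ref = ref - ax * (ref @ ax)
    if np.linalg.norm(ref) < 1e-12:
        raise ValueError("reference direction is parallel to the axis")
    ref /= np.linalg.norm(ref)
    perp = np.cross(ax, ref)
    out = AttributeMap(name="polar_coord", unit="°")
    for lab, c in _centroids(mesh).items():
        u = c - np.asarray(origin, dtype=float)
        u = u - ax * (u @ ax)
        if np.linalg.norm(u) < 1e-12:
            continue
        ang = np.degrees(np.arctan2(u @ perp, u @ ref)) % 360.0
        out[lab] = float(ang)
    return out


def mesh_distance(mesh, other) -> AttributeMap:
    """Per-cell Euclidean distance from the centroid to the nearest vertex of
    another mesh (e.g. an organ surface)."""
    if isinstance(other, VolumetricCellMesh):
        pts = np.vstack([c.vertices for c in other.cells.values()])
    else:
        pts = other.vertices
    if len(pts) == 0:
        raise ValueError("other mesh has no vertices")
    tree = cKDTree(pts)
    out = AttributeMap(name="mesh_distance", unit="µm")
    for lab, c in _centroids(mesh).items():
        out[lab] = float(tree.query(c)[0])
    return out


def relative_radial_coord(mesh, axis_spline: BezierSpline, surface: SurfaceCellMesh):
    """Relative radial position of each cell between the organ axis (0) and
    the organ surface (1).

    A ray is cast from the nearest axis point through the cell centroid; the
    relative coordinate is the centroid's axis distance divided by the
    surface hit's axis distance.  Cells whose ray misses the surface are left
    unassigned.  Returns ``(relative, absolute)`` attribute maps.
    """
    rel = AttributeMap(name="rel_radial")
    absolute = AttributeMap(name="radial_distance", unit="µm")
    sv, st = surface.vertices, surface.triangles
    for lab, c in _centroids(mesh).items():
        t = axis_spline.nearest_parameter(c)
        a = axis_spline.evaluate(t)
        u = c - a
        r = np.linalg.norm(u)
        if r < 1e-12:
            continue
        u = u / r
        hits = _geom.ray_mesh_hits(a, u, sv, st)
        if len(hits) == 0:
            continue
        # first surface crossing at or beyond the centroid (the centroid lies
        # between axis and surface; "on the surface" maps to exactly 1)
        outer = hits[hits >= r * (1 - 1e-9)]
        h = float(outer[0]) if len(outer) else float(hits[-1])
        rel[lab] = float(min(r / h, 1.0))
        absolute[lab] = float(r)
    return rel, absolute


def attribute_gradient_directions(mesh: SurfaceCellMesh, attr: AttributeMap,
                                  graph: nx.Graph | None = None) -> CellFrame:
    """Per-cell frame from the in-surface gradient of a cell attribute.

    For every cell with the attribute defined on itself and at least two
    neighbours, a least-squares linear fit of the attribute over the 1-ring
    centroids gives the gradient; ``d1`` is its unit projection into the
    cell's tangent plane, ``d2`` the cell surface normal and ``d3 = d1 x d2``
    the in-surface orthogonal (e.g. the ML axis when the attribute is a
    proximal-distal distance).  Cells with a constant neighbourhood are left
    unassigned.
    """
    from .core import build_cell_graph
    if graph is None:
        graph = build_cell_graph(mesh)
    frames = CellFrame(name="gradient_frame")
    cents = _centroids(mesh)
    for lab in graph.nodes:
        if lab not in attr:
            continue
        ring = [n for n in graph.neighbors(lab) if n in attr]
        if len(ring) < 2:
            continue
        members = [lab] + ring
        X = np.array([cents[m] for m in members])
        y = np.array([attr[m] for m in members], dtype=float)
        if np.ptp(y) < 1e-12:
            continue
        Xc = X - X.mean(axis=0)
        A = np.column_stack([np.ones(len(members)), Xc])
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        g = sol[1:]
        n = mesh.cell_normal(int(lab))
        g = g - n * (g @ n)
        if np.linalg.norm(g) < 1e-12:
            continue
        d1 = g / np.linalg.norm(g)
        d2 = n
        d3 = np.cross(d1, d2)
        frames[int(lab)] = np.vstack([d1, d2, d3])
    return frames


def build_cell_frame(d1_map: AttributeMap, d2_map: AttributeMap,
                     parallel_tol: float = 0.99) -> CellFrame:
    """Combine two per-cell direction fields into right-handed orthonormal
    triads: ``d2`` is Gram-Schmidt re-orthogonalized against ``d1`` and
    ``d3 = d1 x d2``.  Cells where the inputs are (near-)parallel are left
    unassigned."""
    frames = CellFrame(name="cell_frame")
    for lab in d1_map:
        if lab not in d2_map:
            continue
        d1 = np.asarray(d1_map[lab], dtype=float)
        d2 = np.asarray(d2_map[lab], dtype=float)
        d1 = d1 / np.linalg.norm(d1)
        d2 = d2 / np.linalg.norm(d2)
        if abs(d1 @ d2) > parallel_tol:
            continue
        d2 = d2 - d1 * (d1 @ d2)
        d2 /= np.linalg.norm(d2)
        d3 = np.cross(d1, d2)
        frames[int(lab)] = np.vstack([d1, d2, d3])
    return frames
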