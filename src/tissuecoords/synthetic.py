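"""Synthetic segmented tissues with known ground truth.

The generators emulate the kinds of data the quantification pipeline is used
on — epidermal surface segmentations (polygonal cells tiling a curved
surface), layered radially-symmetric 3D organs, time-lapse pairs produced by
a known smooth deformation with planted divisions, and per-vertex signal
fields with planted polarity or fibril orientation — so that every algorithm
can be tested against an analytic ground truth instead of microscopy data.

All generators are deterministic per seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import Voronoi

from . import _geom
from .core import AttributeMap, CellSurface, ParentMap, SurfaceCellMesh, VolumetricCellMesh

__all__ = [
    "GroundTruth",
    "AffineDeformation",
    "RadialGrowthDeformation",
    "BendingDeformation",
    "AxialBendDeformation",
    "make_surface_tissue",
    "make_grid_tissue",
    "make_organ_3d",
    "apply_timelapse",
    "make_signal_field",
    "make_box_cell",
    "make_sphere_cell",
    "make_stacked_boxes",
]


@dataclass
class GroundTruth:
    """Planted truth accompanying a generated fixture.  Fields are populated
    by whichever generator produced it; unused ones stay ``None``."""
    layer: AttributeMap | None = None            # 1 = innermost
    circ_index: AttributeMap | None = None
    ring_index: AttributeMap | None = None
    rel_radial: AttributeMap | None = None       # in (0, 1]
    lineage: ParentMap | None = None
    deformation: "Deformation | None" = None
    vertex_count_t0: int | None = None           # t1 vertices [:n] correspond to t0
    polarity_direction: np.ndarray | None = None
    stripe_orientation_deg: float | None = None
    centerline: np.ndarray | None = None         # (k, 3) points along the organ axis
    central_file: list[int] | None = None        # ordered labels of the axial cell file
    cell_polygons: dict | None = None            # label -> (k, 2) planar outline
    surface_radius: float | None = None
    divided_mothers: list[int] | None = None


# --------------------------------------------------------------------------
# Deformations with analytic Jacobians
# --------------------------------------------------------------------------

class Deformation:
    def map(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def jacobian(self, point: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass
class AffineDeformation(Deformation):
    matrix: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if np.linalg.det(self.matrix) <= 0:
            raise ValueError("deformation must be orientation-preserving (det > 0)")

    def map(self, points):
        return np.atleast_2d(points) @ self.matrix.T + self.translation

    def jacobian(self, point):
        return self.matrix.copy()


@dataclass
class RadialGrowthDeformation(Deformation):
    """Growth gradient: points move radially away from *center* with a
    smooth (C-infinity) quadratic growth law x -> c + u (1 + g |u|²).

    The radial stretch is 1 + 3 g r² and the circumferential stretch
    1 + g r², both increasing away from the centre — a growing-organ-like
    field whose Jacobian is smooth everywhere (including the centre, where
    a |u|-proportional law would have a cusp)."""
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gain: float = 1e-5   # 1/µm²

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.gain < 0:
            raise ValueError("gain must be >= 0 for an invertible radial growth field")

    def map(self, points):
        u = np.atleast_2d(points) - self.center
        r2 = (u ** 2).sum(axis=1, keepdims=True)
        return self.center + u * (1.0 + self.gain * r2)

    def jacobian(self, point):
        u = np.asarray(point, dtype=float) - self.center
        r2 = float(u @ u)
        return (1.0 + self.gain * r2) * np.eye(3) + 2.0 * self.gain * np.outer(u, u)


@dataclass
class BendingDeformation(Deformation):
    """Volume-preserving shear bend of a flat (xy) tissue: z gains a
    quadratic offset in x."""
    curvature: float = 0.001   # 1/µm

    def map(self, points):
        p = np.atleast_2d(points).astype(float).copy()
        p[:, 2] = p[:, 2] + self.curvature * p[:, 0] ** 2
        return p

    def jacobian(self, point):
        j = np.eye(3)
        j[2, 0] = 2.0 * self.curvature * float(np.asarray(point)[0])
        return j


@dataclass
class AxialBendDeformation(Deformation):
    """Bend of a z-axial organ: x gains a quadratic offset in z."""
    curvature: float = 0.001   # 1/µm

    def map(self, points):
        p = np.atleast_2d(points).astype(float).copy()
        p[:, 0] = p[:, 0] + self.curvature * p[:, 2] ** 2
        return p

    def jacobian(self, point):
        j = np.eye(3)
        j[0, 2] = 2.0 * self.curvature * float(np.asarray(point)[2])
        return j


# --------------------------------------------------------------------------
# 2.5D surface tissues
# --------------------------------------------------------------------------

def _bounded_voronoi(points: np.ndarray, size: float):
    """Voronoi cells of *points* clipped exactly to [0,size]^2 via mirroring."""
    mirrors = [points.copy() for _ in range(4)]
    mirrors[0][:, 0] = -mirrors[0][:, 0]
    mirrors[1][:, 0] = 2 * size - mirrors[1][:, 0]
    mirrors[2][:, 1] = -mirrors[2][:, 1]
    mirrors[3][:, 1] = 2 * size - mirrors[3][:, 1]
    vor = Voronoi(np.vstack([points] + mirrors))
    polys = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        poly = vor.vertices[region]
        c = poly.mean(axis=0)
        ang = np.arctan2(poly[:, 1] - c[1], poly[:, 0] - c[0])
        polys.append(poly[np.argsort(ang)])
    return polys


def _polygon_centroid_2d(poly: np.ndarray) -> np.ndarray:
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        return poly.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6 * a)
    cy = ((y + yn) * cross).sum() / (6 * a)
    return np.array([cx, cy])


_SURFACES: dict[str, Callable] = {
    "plane": lambda x, y, size: np.zeros_like(x),
    "paraboloid": lambda x, y, size: ((x - size / 2) ** 2 + (y - size / 2) ** 2) / (2 * size),
    "sphere_cap": lambda x, y, size: np.sqrt(
        np.clip((1.5 * size) ** 2 - (x - size / 2) ** 2 - (y - size / 2) ** 2, 0, None)
    ) - 1.5 * size,
}


def make_surface_tissue(
    surface: str = "plane",
    n_cells: int = 50,
    seed: int = 0,
    size: float = 100.0,
    lloyd_iters: int = 4,
    inset: float = 0.5,
    edge_length: float = 2.0,
) -> tuple[SurfaceCellMesh, GroundTruth]:
    """Lloyd-relaxed Voronoi tessellation of a parametric surface patch.

    Cells are polygonal, labelled 1..n_cells; junctions are exactly the
    Voronoi vertices.  Each polygon is triangulated with an inset ring
    ``inset`` µm inside the outline (strip + centroid fan), giving every
    cell private near-border vertices — the natural place for
    membrane-adjacent signal, which in real projections lands just inside
    the owning cell.  Curved variants lift the planar tessellation onto a
    paraboloid or a sphere cap (height field over the same square domain).
    """
    if surface not in _SURFACES:
        raise ValueError(f"surface must be one of {sorted(_SURFACES)}")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0.05 * size, 0.95 * size, size=(n_cells, 2))
    if n_cells == 1:
        polys = [np.array([[0, 0], [size, 0], [size, size], [0, size]], dtype=float)]
    else:
        for _ in range(lloyd_iters):
            polys = _bounded_voronoi(pts, size)
            pts = np.array([_polygon_centroid_2d(p) for p in polys])
        polys = _bounded_voronoi(pts, size)

    lift = _SURFACES[surface]
    vert_index: dict[tuple, int] = {}
    vertices: list[np.ndarray] = []

    def add_vertex(p2: np.ndarray) -> int:
        key = (round(float(p2[0]), 9), round(float(p2[1]), 9))
        if key not in vert_index:
            z = float(lift(np.array(p2[0]), np.array(p2[1]), size))
            vert_index[key] = len(vertices)
            vertices.append(np.array([p2[0], p2[1], z]))
        return vert_index[key]

    tris, labels = [], []
    polygons = {}
    for lab, poly in enumerate(polys, start=1):
        polygons[lab] = poly.copy()
        c2 = _polygon_centroid_2d(poly)
        ci = add_vertex(c2)
        # subdivide each polygon side to at most edge_length (shared sides
        # subdivide identically in both cells, so the points are shared)
        dense = []
        kp = len(poly)
        for i in range(kp):
            a, b = poly[i], poly[(i + 1) % kp]
            nseg = max(1, int(np.ceil(np.linalg.norm(b - a) / edge_length)))
            for t in range(nseg):
                dense.append(a + (b - a) * t / nseg)
        dense = np.array(dense)
        outer = [add_vertex(p) for p in dense]
        inner = []
        for p in dense:
            to_c = c2 - p
            dist = np.linalg.norm(to_c)
            step = min(inset, 0.45 * dist)
            inner.append(add_vertex(p + to_c / max(dist, 1e-12) * step))
        k = len(outer)
        for i in range(k):
            a, b = outer[i], outer[(i + 1) % k]
            qa, qb = inner[i], inner[(i + 1) % k]
            if a == b:
                continue
            tris.append([a, b, qb])
            labels.append(lab)
            if qa != qb:
                tris.append([a, qb, qa])
                labels.append(lab)
                tris.append([ci, qa, qb])
                labels.append(lab)
    mesh = SurfaceCellMesh(np.array(vertices), np.array(tris), np.array(labels))
    return mesh, GroundTruth(cell_polygons=polygons)


def make_grid_tissue(nx: int = 2, ny: int = 2, cell_size: float = 1.0,
                     subdiv: int = 1) -> tuple[SurfaceCellMesh, GroundTruth]:
    """Axis-aligned grid of square cells on the z=0 plane (labels row-major,
    1-based).  Handy for hand-checkable fixtures; each cell is a
    ``subdiv x subdiv`` quad grid of triangle pairs."""
    step = cell_size / subdiv
    vert_index: dict[tuple, int] = {}
    vertices: list = []

    def vid(x, y):
        key = (round(x, 9), round(y, 9))
        if key not in vert_index:
            vert_index[key] = len(vertices)
            vertices.append([x, y, 0.0])
        return vert_index[key]

    tris, labels = [], []
    polygons = {}
    for cy in range(ny):
        for cx in range(nx):
            lab = cy * nx + cx + 1
            x0, y0 = cx * cell_size, cy * cell_size
            polygons[lab] = np.array([[x0, y0], [x0 + cell_size, y0],
                                      [x0 + cell_size, y0 + cell_size], [x0, y0 + cell_size]])
            for i in range(subdiv):
                for j in range(subdiv):
                    a = vid(x0 + i * step, y0 + j * step)
                    b = vid(x0 + (i + 1) * step, y0 + j * step)
                    c = vid(x0 + (i + 1) * step, y0 + (j + 1) * step)
                    d = vid(x0 + i * step, y0 + (j + 1) * step)
                    # alternate the quad diagonal so the triangulation has no
                    # preferred direction (matters for gradient statistics)
                    if (i + j) % 2 == 0:
                        tris += [[a, b, c], [a, c, d]]
                    else:
                        tris += [[b, c, d], [b, d, a]]
                    labels += [lab, lab]
    mesh = SurfaceCellMesh(np.array(vertices, dtype=float), np.array(tris), np.array(labels))
    return mesh, GroundTruth(cell_polygons=polygons)


# --------------------------------------------------------------------------
# 3D layered organs
# --------------------------------------------------------------------------

def _quad(p0, p1, p2, p3, outward):
    """Two triangles covering quad p0..p3, wound so normals align with
    *outward* (degenerate corners allowed: collapsed triangles are dropped)."""
    tris = []
    for tri in ([p0, p1, p2], [p0, p2, p3]):
        a, b, c = (np.asarray(p) for p in tri)
        n = np.cross(b - a, c - a)
        if np.linalg.norm(n) < 1e-14:
            continue
        if np.dot(n, outward) < 0:
            tri = [tri[0], tri[2], tri[1]]
        tris.append(tri)
    return tris


def make_organ_3d(
    n_layers: int = 4,
    cells_per_ring: int = 8,
    n_rings: int = 10,
    curvature: float = 0.0,
    seed: int = 0,
    radius: float = 20.0,
    ring_height: float = 10.0,
    arc_subdiv: int = 3,
    core: bool = False,
) -> tuple[VolumetricCellMesh, GroundTruth]:
    """Concentric layers of wedge cells along a (possibly bent) centerline.

    Layers are equal-thickness shells (layer 1 innermost); each layer is cut
    into ``cells_per_ring`` circumferential wedges and ``n_rings`` axial
    rings.  With ``core=True`` the innermost layer is instead one on-axis
    cell per ring (a central cell file, as in a root columella/vasculature),
    giving ``((n_layers-1)*cells_per_ring + 1) * n_rings`` cells.

    ``curvature`` bends the organ by offsetting x by ``curvature * z**2``;
    the ground truth records the bent centerline.  Ground-truth layer /
    circumferential / ring indices and the relative radial coordinate of
    every cell centroid (computed in the straight frame, where it is exact)
    are returned.
    """
    del seed  # geometry is deterministic; signature kept uniform
    radii = np.linspace(0.0, radius, n_layers + 1)
    z_levels = np.arange(n_rings + 1) * ring_height
    bend = AxialBendDeformation(curvature) if curvature else None

    cells: dict[int, CellSurface] = {}
    layer_map, circ_map, ring_map, rel_map = (AttributeMap(name=n) for n in
                                              ("layer", "circ_index", "ring_index", "rel_radial"))
    central_file: list[int] = []
    label = 0

    def cyl(r, theta, z):
        return np.array([r * np.cos(theta), r * np.sin(theta), z])

    def label_of(l, c, m):
        """Grid cell -> label (same enumeration as the generation loop)."""
        if core:
            per_ring = (n_layers - 1) * cells_per_ring + 1
            if l == 1:
                return m * per_ring + 1
            return m * per_ring + 1 + (l - 2) * cells_per_ring + c + 1
        per_ring = n_layers * cells_per_ring
        return m * per_ring + (l - 1) * cells_per_ring + c + 1

    dtheta = 2 * np.pi / cells_per_ring
    sub = dtheta / arc_subdiv

    for m in range(n_rings):
        z0, z1 = z_levels[m], z_levels[m + 1]
        for l in range(1, n_layers + 1):
            r_in, r_out = radii[l - 1], radii[l]
            if core and l == 1:
                # single on-axis cell: a full disc prism up to r_out
                label += 1
                tris, tags, pts = [], [], []
                nseg = cells_per_ring * arc_subdiv
                thetas = np.arange(nseg + 1) * 2 * np.pi / nseg
                for t0, t1 in zip(thetas[:-1], thetas[1:]):
                    mid = cyl(r_out, (t0 + t1) / 2, 0)
                    for tri in _quad(cyl(r_out, t0, z0), cyl(r_out, t1, z0),
                                     cyl(r_out, t1, z1), cyl(r_out, t0, z1), mid):
                        tris.append(tri)
                        tags.append(label_of(2, int(((t0 + t1) / 2) // dtheta) % cells_per_ring, m)
                                    if n_layers > 1 else 0)
                    for z, out in ((z0, [0, 0, -1]), (z1, [0, 0, 1])):
                        for tri in _quad(cyl(0, 0, z), cyl(r_out, t0, z),
                                         cyl(r_out, t1, z), cyl(0, 0, z), np.array(out)):
                            tris.append(tri)
                            if z == z0:
                                tags.append(label_of(1, 0, m - 1) if m > 0 else 0)
                            else:
                                tags.append(label_of(1, 0, m + 1) if m < n_rings - 1 else 0)
                verts, tri_idx = _dedupe(tris)
                cells[label] = CellSurface(verts, tri_idx, np.array(tags))
                layer_map[label], circ_map[label], ring_map[label] = 1, 0, m
                cen = cells[label].centroid()
                rel_map[label] = float(np.hypot(cen[0], cen[1]) / radius)
                central_file.append(label)
                continue
            for c in range(cells_per_ring):
                label += 1
                th0 = c * dtheta
                tris, tags = [], []
                for si in range(arc_subdiv):
                    t0, t1 = th0 + si * sub, th0 + (si + 1) * sub
                    tm = (t0 + t1) / 2
                    # outer wall
                    for tri in _quad(cyl(r_out, t0, z0), cyl(r_out, t1, z0),
                                     cyl(r_out, t1, z1), cyl(r_out, t0, z1), cyl(1, tm, 0)):
                        tris.append(tri)
                        tags.append(label_of(l + 1, c, m) if l < n_layers else 0)
                    # inner wall
                    if r_in > 0:
                        for tri in _quad(cyl(r_in, t0, z0), cyl(r_in, t1, z0),
                                         cyl(r_in, t1, z1), cyl(r_in, t0, z1), -cyl(1, tm, 0)):
                            tris.append(tri)
                            tags.append(label_of(l - 1, 0, m) if (core and l == 2)
                                        else label_of(l - 1, c, m))
                    # top / bottom annular sector pieces
                    for z, out, tag in ((z0, np.array([0, 0, -1.0]),
                                         label_of(l, c, m - 1) if m > 0 else 0),
                                        (z1, np.array([0, 0, 1.0]),
                                         label_of(l, c, m + 1) if m < n_rings - 1 else 0)):
                        for tri in _quad(cyl(r_in, t0, z), cyl(r_out, t0, z),
                                         cyl(r_out, t1, z), cyl(r_in, t1, z), out):
                            tris.append(tri)
                            tags.append(tag)
                # radial side walls at th0 and th0+dtheta
                for th, sgn in ((th0, -1.0), (th0 + dtheta, 1.0)):
                    out = sgn * np.array([-np.sin(th), np.cos(th), 0.0])
                    nb_c = (c + (1 if sgn > 0 else -1)) % cells_per_ring
                    for tri in _quad(cyl(r_in, th, z0), cyl(r_out, th, z0),
                                     cyl(r_out, th, z1), cyl(r_in, th, z1), out):
                        tris.append(tri)
                        tags.append(label_of(l, nb_c, m) if cells_per_ring > 1 else 0)
                verts, tri_idx = _dedupe(tris)
                cells[label] = CellSurface(verts, tri_idx, np.array(tags))
                layer_map[label], circ_map[label], ring_map[label] = l, c, m
                cen = cells[label].centroid()
                rel_map[label] = float(np.hypot(cen[0], cen[1]) / radius)

    if bend is not None:
        for cell in cells.values():
            cell.vertices = bend.map(cell.vertices)
    centerline = np.column_stack([
        (curvature * z_levels ** 2), np.zeros_like(z_levels), z_levels.astype(float)])
    mesh = VolumetricCellMesh(cells)
    return mesh, GroundTruth(layer=layer_map, circ_index=circ_map, ring_index=ring_map,
                             rel_radial=rel_map, centerline=centerline,
                             central_file=central_file or None,
                             surface_radius=radius, deformation=bend)


def _dedupe(tris: list) -> tuple[np.ndarray, np.ndarray]:
    pts = np.array([p for tri in tris for p in tri], dtype=float)
    key = np.round(pts * 1e8).astype(np.int64)
    uniq, inverse = np.unique(key, axis=0, return_inverse=True)
    out = np.zeros((len(uniq), 3))
    out[inverse] = pts
    return out, inverse.reshape(-1, 3)


# --------------------------------------------------------------------------
# Time-lapse pairs
# --------------------------------------------------------------------------

def apply_timelapse(
    mesh: SurfaceCellMesh,
    deformation: Deformation,
    division_rate: float = 0.0,
    seed: int = 0,
    orientation: str = "shortest",
) -> tuple[SurfaceCellMesh, ParentMap, GroundTruth]:
    """Deform a surface tissue through an analytic map and optionally divide
    a seeded fraction of cells by an exact plane cut through their centroid.

    Every t1 cell appears in the returned lineage (non-divided cells map to
    themselves).  The first ``len(mesh.vertices)`` vertices of the t1 mesh
    correspond one-to-one to the t0 vertices, so junction landmarks can be
    matched exactly on fixtures.  Daughter walls are planar by construction.
    """
    if not isinstance(mesh, SurfaceCellMesh):
        raise TypeError("apply_timelapse operates on surface meshes; deform volumetric "
                        "meshes by mapping their vertices directly")
    if orientation not in ("shortest", "random"):
        raise ValueError("orientation must be 'shortest' or 'random'")
    rng = np.random.default_rng(seed)
    new_vertices = deformation.map(mesh.vertices)
    jac_dets = [np.linalg.det(deformation.jacobian(v)) for v in mesh.vertices[:: max(1, len(mesh.vertices) // 16)]]
    if min(jac_dets) <= 0:
        raise ValueError("requested deformation is not orientation-preserving on the mesh domain")
    signal = None if mesh.vertex_signal is None else list(mesh.vertex_signal)

    labels = mesh.labels()
    divide = rng.random(len(labels)) < division_rate
    mothers = [int(l) for l, d in zip(labels, divide) if d]

    verts = [v for v in new_vertices]
    tris = [list(t) for t in mesh.triangles]
    face_label = list(mesh.face_label)
    parents = ParentMap({int(l): int(l) for l in labels})
    next_label = int(labels.max()) + 1 if len(labels) else 1

    # incidence map keeps hanging-node repair O(1) per cut edge; removed
    # triangles become tombstones (None) so list positions stay stable
    vert_tris: dict[int, set] = {}
    for ti, t in enumerate(tris):
        for vv in t:
            vert_tris.setdefault(int(vv), set()).add(ti)

    def add_tri(t3, lab):
        ti = len(tris)
        tris.append(list(t3))
        face_label.append(lab)
        for vv in t3:
            vert_tris.setdefault(int(vv), set()).add(ti)
        return ti

    def remove_tri(ti):
        for vv in tris[ti]:
            vert_tris[int(vv)].discard(ti)
        tris[ti] = None
        face_label[ti] = None

    for mother in mothers:
        idx = [i for i, l in enumerate(face_label) if l == mother]
        cell_tris = [tris[i] for i in idx]
        normal = _geom.area_weighted_normal(np.array(verts), np.array(cell_tris))
        areas = _geom.triangle_areas(np.array(verts), np.array(cell_tris))
        cents = _geom.triangle_centroids(np.array(verts), np.array(cell_tris))
        centroid = (cents * areas[:, None]).sum(axis=0) / areas.sum()
        if orientation == "random":
            v = rng.normal(size=3)
            h = v - normal * (v @ normal)
        else:
            # cut perpendicular to the cell's in-plane major axis (shortest wall
            # for elongated convex cells)
            d = cents - centroid
            d -= np.outer(d @ normal, normal)
            cov = (d * areas[:, None]).T @ d / areas.sum()
            w, vecs = np.linalg.eigh(cov)
            h = vecs[:, np.argmax(w)]
            h -= normal * (h @ normal)
        h = h / np.linalg.norm(h)

        la, lb = next_label, next_label + 1
        next_label += 2
        del parents[mother]
        parents[la] = mother
        parents[lb] = mother

        cut_cache: dict[tuple, int] = {}

        def cut_point(i, j):
            si = (verts[i] - centroid) @ h
            sj = (verts[j] - centroid) @ h
            t = si / (si - sj)
            if t <= 1e-9:       # cut passes through an existing vertex: reuse it
                return i
            if t >= 1 - 1e-9:
                return j
            key = (min(i, j), max(i, j))
            if key not in cut_cache:
                verts.append(verts[i] + t * (verts[j] - verts[i]))
                if signal is not None:
                    signal.append(signal[i] + t * (signal[j] - signal[i]))
                cut_cache[key] = len(verts) - 1
            return cut_cache[key]

        for ti in idx:
            tvx = list(tris[ti])
            s = np.array([(verts[v] - centroid) @ h for v in tvx])
            s[np.abs(s) < 1e-12] = 0.0
            if np.all(s <= 0):
                face_label[ti] = la
                continue
            if np.all(s >= 0):
                face_label[ti] = lb
                continue
            # split: rotate so the lone-signed vertex comes first
            signs = np.sign(s)
            lone_positive = (signs > 0).sum() == 1
            lone = np.nonzero(signs > 0 if lone_positive else signs < 0)[0][0]
            order = [(lone + k) % 3 for k in range(3)]
            a, b, c = (tvx[o] for o in order)
            sa = s[order[0]]
            p_ab = cut_point(a, b)
            p_ca = cut_point(c, a)
            lone_lab = lb if sa > 0 else la
            rest_lab = la if sa > 0 else lb
            remove_tri(ti)
            for t3, l3 in (([a, p_ab, p_ca], lone_lab),
                           ([p_ab, b, c], rest_lab),
                           ([p_ab, c, p_ca], rest_lab)):
                if len(set(t3)) == 3:
                    add_tri(t3, l3)
        # keep the triangulation conforming: a cut vertex on a wall shared
        # with a neighbouring cell must also split the neighbour's triangle,
        # otherwise the hanging node silently destroys the adjacency edge
        for (i, j), v in cut_cache.items():
            for ti in sorted(vert_tris.get(i, set()) & vert_tris.get(j, set())):
                t3 = tris[ti]
                if t3 is None or v in t3:
                    continue
                k = [x for x in t3 if x not in (i, j)][0]
                ii = t3.index(i)
                jj = t3.index(j)
                if (ii + 1) % 3 == jj:   # i -> j in winding order
                    first, second = [i, v, k], [v, j, k]
                else:                     # j -> i
                    first, second = [j, v, k], [v, i, k]
                lab_n = face_label[ti]
                remove_tri(ti)
                add_tri(first, lab_n)
                add_tri(second, lab_n)

    live = [i for i, t in enumerate(tris) if t is not None]
    mesh_t1 = SurfaceCellMesh(np.array(verts), np.array([tris[i] for i in live]),
                              np.array([face_label[i] for i in live]),
                              None if signal is None else np.array(signal))
    gt = GroundTruth(lineage=ParentMap(parents), deformation=deformation,
                     vertex_count_t0=len(mesh.vertices), divided_mothers=mothers)
    return mesh_t1, ParentMap(parents), gt


# --------------------------------------------------------------------------
# Signal fields
# --------------------------------------------------------------------------

def make_signal_field(mesh: SurfaceCellMesh, kind: str = "uniform", *,
                      direction=(1.0, 0.0, 0.0), sharpness: float = 4.0,
                      orientation_deg: float = 0.0, wavelength: float = 10.0,
                      value: float = 1.0, seed: int = 0,
                      noise_sigma: float = 0.4) -> tuple[np.ndarray, GroundTruth]:
    """Per-vertex signal with planted structure.

    kinds: ``polarized`` (signal concentrated on the side of each cell facing
    *direction*, von-Mises-like with the given sharpness), ``striped``
    (sinusoidal stripes; fibrils run ALONG ``orientation_deg``, i.e. the
    signal varies perpendicular to it), ``uniform``, ``noise`` (log-normal
    multiplicative noise about 1, emulating fluorescence statistics).
    """
    v = mesh.vertices
    gt = GroundTruth()
    if kind == "uniform":
        signal = np.full(len(v), float(value))
    elif kind == "noise":
        rng = np.random.default_rng(seed)
        signal = rng.lognormal(mean=0.0, sigma=noise_sigma, size=len(v))
    elif kind == "polarized":
        # membrane-adjacent reporter: bright on each cell's private
        # near-border vertices on the side facing the planted direction,
        # baseline elsewhere (shared wall vertices are ambiguous between
        # neighbours and stay at baseline)
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        baseline = 0.05
        signal = np.full(len(v), baseline)
        vlabs = mesh.vertex_labels()
        for lab in mesh.labels():
            c = mesh.cell_centroid(int(lab))
            n = mesh.cell_normal(int(lab))
            dt = d - n * (d @ n)
            dt /= max(np.linalg.norm(dt), 1e-12)
            vs = np.unique(mesh.triangles[mesh.cell_triangle_indices(int(lab))])
            private = [int(x) for x in vs if len(vlabs[x]) == 1]
            u = v[private] - c
            u -= np.outer(u @ n, n)
            norms = np.linalg.norm(u, axis=1)
            ok = norms > 1e-12
            cosang = np.zeros(len(private))
            cosang[ok] = (u[ok] @ dt) / norms[ok]
            signal[private] = baseline + np.exp(sharpness * (cosang - 1.0))
        gt.polarity_direction = d
    elif kind == "striped":
        edge = mesh.vertices[mesh.triangles[:, 0]] - mesh.vertices[mesh.triangles[:, 1]]
        med = float(np.median(np.linalg.norm(edge, axis=1)))
        if wavelength < 2 * med:
            raise ValueError(f"wavelength {wavelength} µm under-samples the mesh "
                             f"(median edge length {med:.3g} µm): aliasing")
        th = np.deg2rad(orientation_deg)
        grad_dir = np.array([-np.sin(th), np.cos(th), 0.0])   # signal varies ⟂ fibrils
        phase = (v @ grad_dir) * 2 * np.pi / wavelength
        signal = 1.0 + np.cos(phase)
        gt.stripe_orientation_deg = float(orientation_deg % 180)
    else:
        raise ValueError(f"unknown signal kind '{kind}'")
    return signal, gt


# --------------------------------------------------------------------------
# Small 3D fixtures
# --------------------------------------------------------------------------

def make_box_cell(bounds=((0, 0, 0), (1, 1, 1)), face_tags: dict | None = None) -> CellSurface:
    """Axis-aligned watertight box cell.  ``face_tags`` maps face names
    ('+x','-x','+y','-y','+z','-z') to neighbour labels (default all 0)."""
    (x0, y0, z0), (x1, y1, z1) = bounds
    P = lambda x, y, z: np.array([x, y, z], dtype=float)
    faces = {
        "-x": ([P(x0, y0, z0), P(x0, y0, z1), P(x0, y1, z1), P(x0, y1, z0)], [-1, 0, 0]),
        "+x": ([P(x1, y0, z0), P(x1, y1, z0), P(x1, y1, z1), P(x1, y0, z1)], [1, 0, 0]),
        "-y": ([P(x0, y0, z0), P(x1, y0, z0), P(x1, y0, z1), P(x0, y0, z1)], [0, -1, 0]),
        "+y": ([P(x0, y1, z0), P(x0, y1, z1), P(x1, y1, z1), P(x1, y1, z0)], [0, 1, 0]),
        "-z": ([P(x0, y0, z0), P(x0, y1, z0), P(x1, y1, z0), P(x1, y0, z0)], [0, 0, -1]),
        "+z": ([P(x0, y0, z1), P(x1, y0, z1), P(x1, y1, z1), P(x0, y1, z1)], [0, 0, 1]),
    }
    face_tags = face_tags or {}
    tris, tags = [], []
    for name, (quad, out) in faces.items():
        for tri in _quad(*quad, np.array(out, dtype=float)):
            tris.append(tri)
            tags.append(int(face_tags.get(name, 0)))
    verts, tri_idx = _dedupe(tris)
    return CellSurface(verts, tri_idx, np.array(tags))


def make_stacked_boxes(split_z: float = 1.0, top: float = 2.0) -> VolumetricCellMesh:
    """Two unit-footprint boxes stacked in z, sharing a tagged wall — the
    minimal two-daughter fixture for 3D division analysis."""
    a = make_box_cell(((0, 0, 0), (1, 1, split_z)), {"+z": 2})
    b = make_box_cell(((0, 0, split_z), (1, 1, top)), {"-z": 1})
    return VolumetricCellMesh({1: a, 2: b})


def make_sphere_cell(radius: float = 1.0, center=(0.0, 0.0, 0.0), subdiv: int = 3) -> CellSurface:
    """Icosphere cell (watertight, outward-oriented), all walls tagged outside."""
    t = (1 + np.sqrt(5)) / 2
    verts = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1]], dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [[0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
             [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
             [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
             [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]]
    verts = list(verts)
    for _ in range(subdiv):
        cache: dict[tuple, int] = {}

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = (verts[i] + verts[j]) / 2
                m /= np.linalg.norm(m)
                verts.append(m)
                cache[key] = len(verts) - 1
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        faces = new_faces
    v = np.array(verts) * radius + np.asarray(center, dtype=float)
    return CellSurface(v, np.array(faces), np.zeros(len(faces), dtype=np.int64))
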