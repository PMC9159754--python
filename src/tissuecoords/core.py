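"""Domain types, mesh and graph construction, and file I/O.

Two mesh flavours are supported:

* :class:`SurfaceCellMesh` — a curved, triangulated 2.5D surface carrying a
  cellular segmentation as a per-triangle cell label, with optional per-vertex
  signal intensity.  Junctions (vertices where three or more cells meet, or
  two cells and the tissue border) are derived on demand.
* :class:`VolumetricCellMesh` — a set of closed per-cell surfaces whose wall
  triangles are tagged with the neighbouring cell's label (0 = organ outside).

All coordinates are micrometres, right-handed axes.  Cell labels are positive
integers; 0 means background / unlabeled / outside.
"""
from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import networkx as nx
import pandas as pd

from . import _geom

__all__ = [
    "AttributeMap",
    "ParentMap",
    "SurfaceCellMesh",
    "CellSurface",
    "VolumetricCellMesh",
    "read_mesh",
    "write_mesh",
    "read_label_tiff",
    "build_cell_graph",
    "export_attributes",
    "import_attributes",
    "validate_mesh",
    "export_parent_map",
    "import_parent_map",
]


class MeshFormatError(ValueError):
    """Raised for malformed mesh files; the message names the offending element."""


class AttributeMap(dict):
    """Named per-cell-label store of scalars, 3-vectors or symmetric tensors.

    Plain ``dict`` keyed by label; a missing label simply has no entry.
    """

    def __init__(self, data: Mapping | None = None, name: str = "attr", unit: str = ""):
        super().__init__(data or {})
        self.name = name
        self.unit = unit

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self), name=self.name)


class ParentMap(dict):
    """Lineage relation: child label (time t+1) -> parent label (time t)."""

    def children_of(self, parent: int) -> list[int]:
        return sorted(c for c, p in self.items() if p == parent)

    def parents(self) -> list[int]:
        return sorted(set(self.values()))


# --------------------------------------------------------------------------
# Surface (2.5D) meshes
# --------------------------------------------------------------------------

@dataclass
class SurfaceCellMesh:
    vertices: np.ndarray                  # (N, 3) float64, µm
    triangles: np.ndarray                 # (M, 3) int, outward-oriented
    face_label: np.ndarray                # (M,) positive int, 0 = unlabeled
    vertex_signal: np.ndarray | None = None   # (N,) non-negative, a.u.
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        self.face_label = np.asarray(self.face_label, dtype=np.int64).reshape(-1)
        if self.vertex_signal is not None:
            self.vertex_signal = np.asarray(self.vertex_signal, dtype=np.float64).reshape(-1)

    # -- basic derived quantities ------------------------------------------
    def labels(self) -> np.ndarray:
        return np.unique(self.face_label[self.face_label > 0])

    def cell_triangle_indices(self, label: int) -> np.ndarray:
        return np.nonzero(self.face_label == label)[0]

    def cell_area(self, label: int) -> float:
        idx = self.cell_triangle_indices(label)
        return float(_geom.triangle_areas(self.vertices, self.triangles[idx]).sum())

    def cell_centroid(self, label: int) -> np.ndarray:
        idx = self.cell_triangle_indices(label)
        tri = self.triangles[idx]
        areas = _geom.triangle_areas(self.vertices, tri)
        cent = _geom.triangle_centroids(self.vertices, tri)
        w = areas.sum()
        if w == 0:
            return cent.mean(axis=0)
        return (cent * areas[:, None]).sum(axis=0) / w

    def centroids(self) -> dict[int, np.ndarray]:
        if "centroids" not in self._cache:
            self._cache["centroids"] = {int(l): self.cell_centroid(int(l)) for l in self.labels()}
        return self._cache["centroids"]

    def cell_normal(self, label: int) -> np.ndarray:
        idx = self.cell_triangle_indices(label)
        return _geom.area_weighted_normal(self.vertices, self.triangles[idx])

    # -- edge topology ------------------------------------------------------
    def _edge_tables(self):
        """Per-undirected-edge triangle incidence.  Cached."""
        if "edges" in self._cache:
            return self._cache["edges"]
        tri = self.triangles
        edges = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        tri_idx = np.tile(np.arange(len(tri)), 3)
        key = np.sort(edges, axis=1)
        order = np.lexsort((key[:, 1], key[:, 0]))
        key = key[order]
        tri_idx = tri_idx[order]
        uniq, start, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        self._cache["edges"] = (uniq, start, counts, tri_idx)
        return self._cache["edges"]

    def border_vertices(self) -> np.ndarray:
        """Vertices on the open border of the mesh (edges used by one triangle)."""
        uniq, start, counts, _ = self._edge_tables()
        border_edges = uniq[counts == 1]
        return np.unique(border_edges)

    def vertex_labels(self) -> list[set]:
        """For each vertex, the set of cell labels of incident triangles."""
        if "vertex_labels" in self._cache:
            return self._cache["vertex_labels"]
        out = [set() for _ in range(len(self.vertices))]
        for t, lab in zip(self.triangles, self.face_label):
            for v in t:
                out[v].add(int(lab))
        self._cache["vertex_labels"] = out
        return out

    def junctions(self) -> np.ndarray:
        """Vertices incident to >=3 cell labels, or 2 labels on the mesh border."""
        vl = self.vertex_labels()
        border = set(self.border_vertices().tolist())
        out = []
        for v, labs in enumerate(vl):
            labs = {l for l in labs if l > 0}
            if len(labs) >= 3 or (len(labs) == 2 and v in border):
                out.append(v)
        return np.array(sorted(out), dtype=np.int64)

    def cell_junctions(self, label: int) -> np.ndarray:
        vl = self.vertex_labels()
        return np.array([v for v in self.junctions() if label in vl[v]], dtype=np.int64)

    def cell_boundary_loop(self, label: int) -> np.ndarray:
        """Ordered closed loop of vertex indices around a cell (outer boundary).

        Orientation follows the triangle winding (counter-clockwise seen from
        the outward normal side).
        """
        idx = self.cell_triangle_indices(label)
        if len(idx) == 0:
            raise KeyError(f"no triangles with label {label}")
        tri = self.triangles[idx]
        directed = set()
        for a, b, c in tri:
            directed.update([(int(a), int(b)), (int(b), int(c)), (int(c), int(a))])
        boundary = [(a, b) for (a, b) in directed if (b, a) not in directed]
        succ = {}
        for a, b in boundary:
            succ.setdefault(a, []).append(b)
        loops = []
        remaining = set(boundary)
        while remaining:
            a0, b0 = min(remaining)
            loop = [a0]
            a, b = a0, b0
            remaining.discard((a, b))
            while b != a0:
                loop.append(b)
                nxts = [x for x in succ.get(b, []) if (b, x) in remaining]
                if not nxts:
                    raise MeshFormatError(f"cell {label}: open boundary (stuck at vertex {b})")
                nxt = nxts[0]
                remaining.discard((b, nxt))
                a, b = b, nxt
            loops.append(loop)
        loops.sort(key=len, reverse=True)
        return np.array(loops[0], dtype=np.int64)


# --------------------------------------------------------------------------
# Volumetric (3D) meshes
# --------------------------------------------------------------------------

@dataclass
class CellSurface:
    """Closed triangulated surface of one volumetric cell."""
    vertices: np.ndarray        # (n, 3)
    triangles: np.ndarray       # (m, 3), outward-oriented
    wall_label: np.ndarray      # (m,) neighbour label per triangle, 0 = outside

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        self.wall_label = np.asarray(self.wall_label, dtype=np.int64).reshape(-1)

    def volume(self) -> float:
        v, _ = _geom.mesh_volume_centroid(self.vertices, self.triangles)
        return v

    def centroid(self) -> np.ndarray:
        _, c = _geom.mesh_volume_centroid(self.vertices, self.triangles)
        return c

    def wall_areas(self) -> dict[int, float]:
        """Summed triangle area per neighbour tag."""
        areas = _geom.triangle_areas(self.vertices, self.triangles)
        out: dict[int, float] = {}
        for tag in np.unique(self.wall_label):
            out[int(tag)] = float(areas[self.wall_label == tag].sum())
        return out

    def is_watertight(self) -> bool:
        tri = self.triangles
        edges = np.sort(np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2)) and len(tri) > 0


@dataclass
class VolumetricCellMesh:
    cells: dict[int, CellSurface]

    def labels(self) -> np.ndarray:
        return np.array(sorted(self.cells), dtype=np.int64)

    def centroids(self) -> dict[int, np.ndarray]:
        return {l: c.centroid() for l, c in self.cells.items()}


# --------------------------------------------------------------------------
# PLY / OBJ I/O (documented profile: per-face int "label", per-vertex
# float "signal"; ASCII and binary-little-endian; writer emits binary)
# --------------------------------------------------------------------------

_PLY_TYPES = {
    "char": "b", "uchar": "B", "int8": "b", "uint8": "B",
    "short": "h", "ushort": "H", "int16": "h", "uint16": "H",
    "int": "i", "uint": "I", "int32": "i", "uint32": "I",
    "float": "f", "float32": "f", "double": "d", "float64": "d",
}


def write_ply(mesh: SurfaceCellMesh, path, binary: bool = True) -> None:
    path = Path(path)
    has_signal = mesh.vertex_signal is not None
    header = ["ply",
              "format binary_little_endian 1.0" if binary else "format ascii 1.0",
              f"element vertex {len(mesh.vertices)}",
              "property double x", "property double y", "property double z"]
    if has_signal:
        header.append("property double signal")
    header += [f"element face {len(mesh.triangles)}",
               "property list uchar int vertex_indices",
               "property int label",
               "end_header"]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode())
        if binary:
            if has_signal:
                vdata = np.column_stack([mesh.vertices, mesh.vertex_signal])
            else:
                vdata = mesh.vertices
            fh.write(np.ascontiguousarray(vdata, dtype="<f8").tobytes())
            for t, lab in zip(mesh.triangles, mesh.face_label):
                fh.write(struct.pack("<B3ii", 3, int(t[0]), int(t[1]), int(t[2]), int(lab)))
        else:
            for i, v in enumerate(mesh.vertices):
                row = f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}"
                if has_signal:
                    row += f" {mesh.vertex_signal[i]:.17g}"
                fh.write((row + "\n").encode())
            for t, lab in zip(mesh.triangles, mesh.face_label):
                fh.write(f"3 {t[0]} {t[1]} {t[2]} {int(lab)}\n".encode())


def read_ply(path) -> SurfaceCellMesh:
    path = Path(path)
    with open(path, "rb") as fh:
        line = fh.readline().strip()
        if line != b"ply":
            raise MeshFormatError(f"{path}: not a PLY file (magic {line!r})")
        fmt = None
        elements = []  # (name, count, [(prop_name, type, is_list, list_count_type)])
        while True:
            line = fh.readline()
            if not line:
                raise MeshFormatError(f"{path}: unexpected EOF in header")
            tok = line.decode().strip().split()
            if not tok or tok[0] == "comment":
                continue
            if tok[0] == "format":
                fmt = tok[1]
            elif tok[0] == "element":
                elements.append((tok[1], int(tok[2]), []))
            elif tok[0] == "property":
                if tok[1] == "list":
                    elements[-1][2].append((tok[4], tok[3], True, tok[2]))
                else:
                    elements[-1][2].append((tok[2], tok[1], False, None))
            elif tok[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise MeshFormatError(f"{path}: unsupported PLY format '{fmt}'")
        data = {}
        if fmt == "ascii":
            tokens = fh.read().decode().split()
            pos = 0
            for name, count, props in elements:
                rows = []
                for _ in range(count):
                    row = {}
                    for pname, ptype, is_list, _ctype in props:
                        if is_list:
                            n = int(tokens[pos]); pos += 1
                            row[pname] = [float(tokens[pos + j]) for j in range(n)]
                            pos += n
                        else:
                            row[pname] = float(tokens[pos]); pos += 1
                    rows.append(row)
                data[name] = rows
        else:
            for name, count, props in elements:
                rows = []
                for _ in range(count):
                    row = {}
                    for pname, ptype, is_list, ctype in props:
                        if is_list:
                            (n,) = struct.unpack("<" + _PLY_TYPES[ctype],
                                                 fh.read(struct.calcsize(_PLY_TYPES[ctype])))
                            code = _PLY_TYPES[ptype]
                            sz = struct.calcsize(code)
                            row[pname] = list(struct.unpack(f"<{int(n)}{code}", fh.read(sz * int(n))))
                        else:
                            code = _PLY_TYPES[ptype]
                            (row[pname],) = struct.unpack("<" + code, fh.read(struct.calcsize(code)))
                    rows.append(row)
                data[name] = rows
    if "vertex" not in data or "face" not in data:
        raise MeshFormatError(f"{path}: PLY missing vertex or face element")
    vrows = data["vertex"]
    vertices = np.array([[r["x"], r["y"], r["z"]] for r in vrows])
    signal = None
    if vrows and "signal" in vrows[0]:
        signal = np.array([r["signal"] for r in vrows])
    frows = data["face"]
    tris, labels = [], []
    for r in frows:
        vi = r.get("vertex_indices") or r.get("vertex_index")
        if vi is None or len(vi) != 3:
            raise MeshFormatError(f"{path}: non-triangular or index-less face {r}")
        tris.append([int(x) for x in vi])
        labels.append(int(r.get("label", 0)))
    return SurfaceCellMesh(vertices, np.array(tris), np.array(labels), signal)


def write_obj(mesh: SurfaceCellMesh, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# tissuecoords OBJ (per-face cell label via material name)\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        order = np.argsort(mesh.face_label, kind="stable")
        current = None
        for fi in order:
            lab = int(mesh.face_label[fi])
            if lab != current:
                fh.write(f"usemtl cell_{lab}\n")
                current = lab
            t = mesh.triangles[fi]
            fh.write(f"f {t[0]+1} {t[1]+1} {t[2]+1}\n")


def read_obj(path) -> SurfaceCellMesh:
    path = Path(path)
    vertices, tris, labels = [], [], []
    current = 0
    for ln, raw in enumerate(path.read_text().splitlines(), 1):
        tok = raw.split()
        if not tok or tok[0].startswith("#"):
            continue
        if tok[0] == "v":
            vertices.append([float(x) for x in tok[1:4]])
        elif tok[0] == "usemtl":
            name = tok[1]
            if not name.startswith("cell_"):
                raise MeshFormatError(f"{path}:{ln}: material '{name}' is not cell_<label>")
            current = int(name[5:])
        elif tok[0] == "f":
            idx = [int(t.split("/")[0]) - 1 for t in tok[1:]]
            if len(idx) != 3:
                raise MeshFormatError(f"{path}:{ln}: only triangular faces supported")
            tris.append(idx)
            labels.append(current)
    return SurfaceCellMesh(np.array(vertices), np.array(tris), np.array(labels))


# --------------------------------------------------------------------------
# Label-TIFF import (voxel-face surface extraction)
# --------------------------------------------------------------------------

def label_volume_to_mesh(labels: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> VolumetricCellMesh:
    """Extract per-cell closed surfaces from a 3D label image.

    Surfaces are exact voxel-boundary ('blocky') surfaces: each face between
    voxels of different labels becomes two triangles, tagged with the
    neighbouring label (0 = outside).  No smoothing — topology and wall areas
    are exact by construction.  Voxel ``(i,j,k)`` occupies the axis-aligned box
    ``[i*sx, (i+1)*sx] x ...``.
    """
    lab = np.asarray(labels)
    if lab.ndim != 3:
        raise ValueError("label volume must be 3D")
    s = np.asarray(voxel_size, dtype=float)
    padded = np.pad(lab, 1, constant_values=0)
    faces: dict[int, list] = {}   # label -> list of (corner4, tag)

    # unit quads, corners ordered CCW seen from +axis side
    for axis in range(3):
        a = padded[tuple(slice(0, -1) if ax == axis else slice(1, -1) for ax in range(3))]
        b = padded[tuple(slice(1, None) if ax == axis else slice(1, -1) for ax in range(3))]
        diff = a != b
        ii, jj, kk = np.nonzero(diff)
        # boundary plane between a-voxel (index-1 along axis) and b-voxel
        for i, j, k in zip(ii, jj, kk):
            idx3 = [i, j, k]
            la = int(a[i, j, k])
            lb = int(b[i, j, k])
            # plane position along `axis`: after voxel index (idx3[axis]-1)+1 = idx3[axis]
            base = np.array(idx3, dtype=float)
            base[axis] = idx3[axis]
            # quad corners in the plane; (axis, u, v) must be an even
            # permutation of the axes so the winding normal points along +axis
            u, v = [ax for ax in range(3) if ax != axis]
            if axis == 1:
                u, v = v, u
            c = []
            for du, dv in ((0, 0), (1, 0), (1, 1), (0, 1)):
                p = base.copy()
                p[u] += du
                p[v] += dv
                c.append(p * s)
            c = np.array(c)
            # winding: (c1-c0)x(c3-c0) points along +axis -> outward for the a-cell
            if la > 0:
                faces.setdefault(la, []).append((c, lb))
            if lb > 0:
                faces.setdefault(lb, []).append((c[::-1], la))

    cells = {}
    for label, quads in faces.items():
        pts = []
        tris = []
        tags = []
        for c, tag in quads:
            i0 = len(pts)
            pts.extend(c)
            tris.append([i0, i0 + 1, i0 + 2])
            tris.append([i0, i0 + 2, i0 + 3])
            tags.extend([tag, tag])
        pts = np.array(pts)
        key = np.round(pts / np.maximum(s.min(), 1e-9) * 1e6).astype(np.int64)
        uniq, inverse = np.unique(key, axis=0, return_inverse=True)
        new_pts = np.zeros((len(uniq), 3))
        new_pts[inverse] = pts
        tris = inverse[np.array(tris)]
        cells[label] = CellSurface(new_pts, tris, np.array(tags))
    return VolumetricCellMesh(cells)


def read_label_tiff(path, voxel_size=(1.0, 1.0, 1.0)) -> VolumetricCellMesh:
    import tifffile
    arr = tifffile.imread(str(path))
    if arr.ndim != 3:
        raise MeshFormatError(f"{path}: expected a 3D label stack, got shape {arr.shape}")
    return label_volume_to_mesh(arr, voxel_size)


def read_mesh(path, fmt: str | None = None, voxel_size=(1.0, 1.0, 1.0)):
    """Read a mesh; format from extension unless given (ply/obj/tif)."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lower().lstrip(".")
    fmt = fmt.lower()
    if fmt == "ply":
        return read_ply(path)
    if fmt == "obj":
        return read_obj(path)
    if fmt in ("tif", "tiff"):
        return read_label_tiff(path, voxel_size)
    raise ValueError(f"unsupported mesh format: {fmt}")


def write_mesh(mesh: SurfaceCellMesh, path, fmt: str | None = None, binary: bool = True):
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lower().lstrip(".")
    if fmt == "ply":
        write_ply(mesh, path, binary=binary)
    elif fmt == "obj":
        write_obj(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format: {fmt}")


# --------------------------------------------------------------------------
# Cell connectivity graph
# --------------------------------------------------------------------------

def build_cell_graph(mesh) -> nx.Graph:
    """Cell adjacency graph with ``wall_measure`` edge attributes.

    Adjacency requires a shared boundary of positive measure — a shared edge
    (2.5D, wall_measure = summed shared boundary length, µm) or a shared wall
    patch (3D, wall_measure = patch area, µm²).  A single shared vertex does
    not create an edge (no diagonal adjacency).
    """
    g = nx.Graph()
    if isinstance(mesh, SurfaceCellMesh):
        labels = mesh.labels()
        if len(labels) == 0:
            raise ValueError("unlabeled mesh: no positive cell labels")
        for l in labels:
            g.add_node(int(l), centroid=mesh.cell_centroid(int(l)))
        uniq, start, counts, tri_idx = mesh._edge_tables()
        lengths = np.linalg.norm(mesh.vertices[uniq[:, 0]] - mesh.vertices[uniq[:, 1]], axis=1)
        offsets = np.concatenate([[0], np.cumsum(counts)])
        # recover sorted grouping of tri_idx by edge
        for e in range(len(uniq)):
            if counts[e] < 2:
                continue
            tris = tri_idx[offsets[e]:offsets[e + 1]]
            labs = {int(mesh.face_label[t]) for t in tris}
            labs.discard(0)
            if len(labs) == 2:
                a, b = sorted(labs)
                if g.has_edge(a, b):
                    g[a][b]["wall_measure"] += float(lengths[e])
                else:
                    g.add_edge(a, b, wall_measure=float(lengths[e]))
    elif isinstance(mesh, VolumetricCellMesh):
        if not mesh.cells:
            raise ValueError("unlabeled mesh: no cells")
        for l, cell in mesh.cells.items():
            g.add_node(int(l), centroid=cell.centroid())
        acc: dict[tuple, list] = {}
        for l, cell in mesh.cells.items():
            for tag, area in cell.wall_areas().items():
                if tag > 0 and tag in mesh.cells:
                    acc.setdefault(tuple(sorted((int(l), int(tag)))), []).append(area)
        for (a, b), areas in acc.items():
            g.add_edge(a, b, wall_measure=float(np.mean(areas)))
    else:
        raise TypeError(f"unsupported mesh type {type(mesh)!r}")
    return g


# --------------------------------------------------------------------------
# Attribute CSV I/O
# --------------------------------------------------------------------------

_VEC_SUFFIX = ["x", "y", "z"]
_TENS_SUFFIX = ["xx", "xy", "xz", "yy", "yz", "zz"]


def _flatten_value(name: str, value):
    v = np.asarray(value, dtype=float) if not np.isscalar(value) else value
    if np.isscalar(v) or getattr(v, "ndim", 0) == 0:
        return {name: float(v)}
    if v.shape == (3,):
        return {f"{name}_{s}": float(x) for s, x in zip(_VEC_SUFFIX, v)}
    if v.shape == (2,):
        return {f"{name}_x": float(v[0]), f"{name}_y": float(v[1])}
    if v.shape == (3, 3):
        comps = [v[0, 0], v[0, 1], v[0, 2], v[1, 1], v[1, 2], v[2, 2]]
        return {f"{name}_{s}": float(x) for s, x in zip(_TENS_SUFFIX, comps)}
    if v.shape == (2, 2):
        return {f"{name}_xx": float(v[0, 0]), f"{name}_xy": float(v[0, 1]),
                f"{name}_yy": float(v[1, 1])}
    raise ValueError(f"attribute '{name}': unsupported value shape {v.shape}")


def export_attributes(maps: Iterable[AttributeMap], path) -> None:
    """Write attribute maps to CSV: one row per label, suffixed columns for
    vector/tensor components; missing labels leave empty fields."""
    maps = list(maps)
    names = [m.name for m in maps]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate attribute names: {sorted(names)}")
    all_labels = sorted({int(l) for m in maps for l in m})
    rows = []
    for lab in all_labels:
        row: dict = {"Label": lab}
        for m in maps:
            if lab in m:
                row.update(_flatten_value(m.name, m[lab]))
        rows.append(row)
    cols = ["Label"]
    for m in maps:
        probe = next(iter(m.values())) if m else 0.0
        cols.extend(_flatten_value(m.name, probe).keys())
    pd.DataFrame(rows).reindex(columns=cols).to_csv(path, index=False)


def import_attributes(path) -> list[AttributeMap]:
    df = pd.read_csv(path)
    if "Label" not in df.columns:
        raise MeshFormatError(f"{path}: missing 'Label' column")
    labels = df["Label"].astype(int).to_numpy()
    groups: dict[str, list[str]] = {}
    for col in df.columns[1:]:
        base = col
        for suffixes in (_TENS_SUFFIX, _VEC_SUFFIX):
            for s in suffixes:
                if col.endswith("_" + s):
                    base = col[: -(len(s) + 1)]
                    break
        groups.setdefault(base, []).append(col)
    out = []
    for base, cols in groups.items():
        m = AttributeMap(name=base)
        if len(cols) == 1:
            for lab, v in zip(labels, df[cols[0]]):
                if pd.notna(v):
                    m[int(lab)] = float(v)
        elif len(cols) in (2, 3):
            ordered = [f"{base}_{s}" for s in _VEC_SUFFIX[: len(cols)]]
            for i, lab in enumerate(labels):
                vals = [df[c].iloc[i] for c in ordered]
                if all(pd.notna(v) for v in vals):
                    m[int(lab)] = np.array(vals, dtype=float)
        elif len(cols) == 6:
            ordered = [f"{base}_{s}" for s in _TENS_SUFFIX]
            for i, lab in enumerate(labels):
                vals = [df[c].iloc[i] for c in ordered]
                if all(pd.notna(v) for v in vals):
                    t = np.array([[vals[0], vals[1], vals[2]],
                                  [vals[1], vals[3], vals[4]],
                                  [vals[2], vals[4], vals[5]]])
                    m[int(lab)] = t
        else:
            raise MeshFormatError(f"{path}: cannot reassemble attribute '{base}' from {cols}")
        out.append(m)
    return out


def export_parent_map(parents: ParentMap, path) -> None:
    pd.DataFrame(sorted(parents.items()), columns=["child", "parent"]).to_csv(path, index=False)


def import_parent_map(path) -> ParentMap:
    df = pd.read_csv(path)
    return ParentMap({int(c): int(p) for c, p in zip(df["child"], df["parent"])})


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

def validate_mesh(mesh, wall_tol: float = 1e-6) -> list[str]:
    """Check mesh invariants; returns a list of human-readable violations
    (empty iff the mesh is valid)."""
    report: list[str] = []
    if isinstance(mesh, SurfaceCellMesh):
        if np.any(mesh.face_label < 0):
            report.append("negative face labels present")
        if mesh.triangles.size and mesh.triangles.max() >= len(mesh.vertices):
            report.append("triangle index out of range")
            return report
        for lab in mesh.labels():
            idx = mesh.cell_triangle_indices(int(lab))
            tri = mesh.triangles[idx]
            # edge-connectivity of the cell's triangle set
            g = nx.Graph()
            g.add_nodes_from(range(len(tri)))
            edge_map: dict[tuple, list[int]] = {}
            for t_i, t in enumerate(tri):
                for e in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                    edge_map.setdefault(tuple(sorted((int(e[0]), int(e[1])))), []).append(t_i)
            for tris in edge_map.values():
                for i in range(len(tris) - 1):
                    g.add_edge(tris[i], tris[i + 1])
            if len(tri) and not nx.is_connected(g):
                report.append(f"cell {int(lab)}: triangle set not edge-connected")
            try:
                mesh.cell_boundary_loop(int(lab))
            except MeshFormatError as exc:
                report.append(str(exc))
    elif isinstance(mesh, VolumetricCellMesh):
        for lab, cell in mesh.cells.items():
            if not cell.is_watertight():
                report.append(f"cell {int(lab)}: non-watertight surface")
            elif cell.volume() <= 0:
                report.append(f"cell {int(lab)}: non-positive volume {cell.volume():.3g}")
        seen_pairs = set()
        for lab, cell in mesh.cells.items():
            for tag, area in cell.wall_areas().items():
                if tag <= 0:
                    continue
                if tag not in mesh.cells:
                    report.append(f"cell {int(lab)}: wall tagged with missing cell {tag}")
                    continue
                pair = tuple(sorted((int(lab), int(tag))))
                if pair in seen_pairs:
                    continue
                seen_pairs.add(pair)
                back = mesh.cells[tag].wall_areas().get(int(lab), 0.0)
                scale = max(area, back, 1.0)
                if abs(area - back) > max(wall_tol * scale, 1e-9):
                    report.append(
                        f"wall mismatch between cells {int(lab)} and {tag}: "
                        f"{area:.6g} vs {back:.6g} µm²")
    else:
        report.append(f"unsupported mesh type {type(mesh)!r}")
    return report
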