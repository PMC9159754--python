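"""Time-lapse growth quantification.

Between two segmented time points with known lineage, each mother cell's
deformation is summarised by a linear map ``F`` fitted from matched junction
landmarks.  The right stretch tensor ``U = sqrt(F^T F)`` yields the principal
directions of growth (PDGs): ``kmax``/``kmin`` are the maximal/minimal
stretch ratios over the interval and their eigenvectors the corresponding
material directions.  Growth can be projected onto organ axes (e.g. the
proximal-distal direction), and per-cell change maps (areal extension,
proliferation, attribute changes) complete the catalogue.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _geom
from .core import AttributeMap, ParentMap, SurfaceCellMesh, VolumetricCellMesh

__all__ = [
    "GrowthTensor",
    "fit_growth_tensor",
    "compute_pdgs",
    "match_junction_landmarks",
    "areal_extension",
    "proliferation",
    "project_growth",
    "change_map",
]


@dataclass
class GrowthTensor:
    """Per-cell linear growth map in the t0 material frame.

    ``F`` is 2x2 for surface cells (expressed in the cell tangent basis
    ``frame`` whose rows are the basis vectors) or 3x3 for volumetric cells
    (``frame`` is the identity).  ``stretches`` (kmax >= ... >= kmin > 0) and
    ``directions`` (rows, unit, in the material frame) come from the polar
    decomposition ``F = R U``.
    """
    F: np.ndarray
    frame: np.ndarray            # (dim, 3): rows map frame coords -> world
    stretches: np.ndarray        # descending
    directions: np.ndarray       # rows: eigenvectors of U, frame coords

    @property
    def kmax(self) -> float:
        return float(self.stretches[0])

    @property
    def kmin(self) -> float:
        return float(self.stretches[-1])

    @property
    def kmid(self) -> float:
        return float(self.stretches[1]) if len(self.stretches) == 3 else float("nan")

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.F))

    def direction_world(self, i: int = 0) -> np.ndarray:
        """Principal growth direction *i* in world coordinates."""
        return self.directions[i] @ self.frame


def fit_growth_tensor(p0: np.ndarray, p1: np.ndarray,
                      frame: np.ndarray | None = None) -> GrowthTensor:
    """Least-squares linear map (with translation) sending landmark set
    ``p0`` to ``p1``.

    With ``frame`` given (rows = tangent basis vectors of the t0 cell), both
    point sets are projected into that plane and a 2x2 map is fitted — the
    2.5D convention.  Without it a full 3x3 map is fitted.  Raises on
    rank-deficient landmark configurations.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if frame is not None:
        frame = np.asarray(frame, dtype=float).reshape(-1, 3)
        q0 = (p0 - p0.mean(axis=0)) @ frame.T
        q1 = (p1 - p1.mean(axis=0)) @ frame.T
    else:
        frame = np.eye(3)
        q0 = p0 - p0.mean(axis=0)
        q1 = p1 - p1.mean(axis=0)
    dim = q0.shape[1]
    if len(q0) < dim + 1:
        raise ValueError(f"need at least {dim + 1} landmarks, got {len(q0)}")
    if np.linalg.matrix_rank(q0, tol=1e-9 * max(1.0, np.abs(q0).max())) < dim:
        raise ValueError("rank-deficient landmark configuration")
    F, *_ = np.linalg.lstsq(q0, q1, rcond=None)
    F = F.T
    # polar decomposition F = R U via SVD
    W, s, Vt = np.linalg.svd(F)
    return GrowthTensor(F=F, frame=frame, stretches=s, directions=Vt)


def match_junction_landmarks(mesh_t0: SurfaceCellMesh, mesh_t1: SurfaceCellMesh,
                             parents: ParentMap, field=None,
                             max_dist: float | None = None) -> dict[int, tuple]:
    """Junction landmark pairs per t0 cell.

    For each mother, t1 junctions of the daughters' union are mapped back to
    t0 (through the inverse deformation *field* when given, identity
    otherwise) and matched to the mother's nearest t0 junction; a t0 junction
    keeps only its closest match.  Returns ``{mother: (P0, P1)}`` arrays.
    Fixtures with exact vertex correspondence can bypass this and pass
    landmark pairs to :func:`compute_pdgs` directly.
    """
    from scipy.spatial import cKDTree
    j0 = mesh_t0.junctions()
    vl0 = mesh_t0.vertex_labels()
    j1 = mesh_t1.junctions()
    vl1 = mesh_t1.vertex_labels()
    out = {}
    for mother in sorted(set(parents.values())):
        children = parents.children_of(mother)
        mother_j = [v for v in j0 if mother in vl0[v]]
        child_j = [v for v in j1 if any(c in vl1[v] for c in children)]
        if len(mother_j) < 3 or len(child_j) < 3:
            continue
        P0 = mesh_t0.vertices[mother_j]
        P1 = mesh_t1.vertices[child_j]
        back = field.map(P1) if field is not None else P1
        tree = cKDTree(P0)
        d, idx = tree.query(back)
        best: dict[int, tuple[float, int]] = {}
        for k, (dd, ii) in enumerate(zip(d, idx)):
            if max_dist is not None and dd > max_dist:
                continue
            if ii not in best or dd < best[ii][0]:
                best[ii] = (dd, k)
        pairs = sorted((ii, k) for ii, (_, k) in best.items())
        if len(pairs) < 3:
            continue
        out[mother] = (P0[[i for i, _ in pairs]], P1[[k for _, k in pairs]])
    return out


def compute_pdgs(mesh_t0, mesh_t1=None, parents: ParentMap | None = None,
                 landmarks: dict[int, tuple] | None = None) -> AttributeMap:
    """Principal directions of growth for every t0 cell with enough matched
    junction landmarks (>=3 in 2.5D, >=4 in 3D).

    ``landmarks`` maps mother label -> (t0 points, t1 points); when omitted
    it is derived by :func:`match_junction_landmarks`.  Surface-cell tensors
    are 2x2 in the cell's tangent frame (landmarks projected into the
    t0 area-weighted normal plane); volumetric tensors are 3x3.  Cells with
    rank-deficient landmark sets are skipped (unassigned).
    """
    if landmarks is None:
        if mesh_t1 is None or parents is None:
            raise ValueError("either landmarks or (mesh_t1, parents) required")
        landmarks = match_junction_landmarks(mesh_t0, mesh_t1, parents)
    surface = isinstance(mesh_t0, SurfaceCellMesh)
    out = AttributeMap(name="pdg")
    for mother, (p0, p1) in landmarks.items():
        p0 = np.asarray(p0, dtype=float)
        if len(p0) < (3 if surface else 4):
            continue
        try:
            if surface:
                n = mesh_t0.cell_normal(int(mother))
                e1, e2 = _geom.tangent_basis(n)
                out[int(mother)] = fit_growth_tensor(p0, p1, frame=np.vstack([e1, e2]))
            else:
                out[int(mother)] = fit_growth_tensor(p0, p1)
        except ValueError:
            continue
    return out


def _cell_size(mesh, label: int) -> float:
    if isinstance(mesh, VolumetricCellMesh):
        return mesh.cells[label].volume()
    return mesh.cell_area(label)


def areal_extension(mesh_t0, mesh_t1, parents: ParentMap) -> AttributeMap:
    """Per-mother size ratio: sum of daughters' areas (volumes in 3D) at t1
    over the mother's area (volume) at t0.  Mothers without any present
    daughter are unassigned."""
    out = AttributeMap(name="areal_extension")
    labels1 = set(int(l) for l in (mesh_t1.labels() if hasattr(mesh_t1, "labels") else []))
    for mother in sorted(set(parents.values())):
        kids = [c for c in parents.children_of(mother) if not labels1 or c in labels1]
        if not kids:
            continue
        s0 = _cell_size(mesh_t0, int(mother))
        if s0 <= 0:
            continue
        out[int(mother)] = float(sum(_cell_size(mesh_t1, int(c)) for c in kids) / s0)
    return out


def proliferation(parent_maps: ParentMap | list[ParentMap]) -> AttributeMap:
    """Number of terminal descendant cells per ancestor cell.

    A chain of lineage maps (one per interval) is composed; a cell that never
    divides has proliferation 1, a once-divided mother 2.  A child whose
    parent is missing from the previous interval's children raises.
    """
    if isinstance(parent_maps, ParentMap) or isinstance(parent_maps, dict):
        chain = [parent_maps]
    else:
        chain = list(parent_maps)
    if not chain:
        raise ValueError("no parent maps given")
    for i in range(1, len(chain)):
        prev_children = set(chain[i - 1].keys())
        missing = sorted(set(chain[i].values()) - prev_children)
        if missing:
            raise ValueError(f"children reference parents missing from the previous "
                             f"interval: {missing}")
    # compose: terminal child -> ancestor
    counts = AttributeMap(name="proliferation", unit="cells")
    ancestors = {c: p for c, p in chain[0].items()}
    for pm in chain[1:]:
        ancestors = {c: ancestors[p] for c, p in pm.items()}
    for anc in ancestors.values():
        counts[int(anc)] = counts.get(int(anc), 0) + 1
    return counts


def project_growth(tensor: GrowthTensor, direction) -> float:
    """Stretch of a material fiber initially along *direction*: ``|F d|``.

    The direction is given in world coordinates (projected into the tensor's
    material frame for surface cells) and normalized if needed; the
    perpendicular component is ``project_growth`` of the in-frame orthogonal.
    """
    d = np.asarray(direction, dtype=float)
    if d.shape == (3,):
        d = tensor.frame @ d
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise ValueError("zero projection of direction onto the tensor frame")
    if abs(n - 1.0) > 1e-6:
        import warnings
        warnings.warn("direction not unit length in the tensor frame; normalizing")
    d = d / n
    return float(np.linalg.norm(tensor.F @ d))


def change_map(attr_t0: AttributeMap, attr_t1: AttributeMap, parents: ParentMap,
               mode: str = "ratio", aggregate: str = "sum") -> AttributeMap:
    """Per-mother change of a cell attribute across an interval.

    Daughter values are aggregated by ``sum`` (sizes) or ``mean``
    (intensities); ``mode`` is ``ratio``, ``percent`` or ``difference``.
    """
    if mode not in ("ratio", "percent", "difference"):
        raise ValueError("mode must be ratio, percent or difference")
    if aggregate not in ("sum", "mean"):
        raise ValueError("aggregate must be sum or mean")
    if attr_t0.unit and attr_t1.unit and attr_t0.unit != attr_t1.unit:
        raise ValueError(f"unit mismatch: {attr_t0.unit!r} vs {attr_t1.unit!r}")
    out = AttributeMap(name=f"change_{attr_t0.name}",
                       unit=attr_t0.unit if mode == "difference" else
                       ("%" if mode == "percent" else ""))
    for mother in sorted(set(parents.values())):
        if mother not in attr_t0:
            continue
        vals = [attr_t1[c] for c in parents.children_of(mother) if c in attr_t1]
        if not vals:
            continue
        v1 = float(np.sum(vals) if aggregate == "sum" else np.mean(vals))
        v0 = float(attr_t0[mother])
        if mode == "difference":
            out[int(mother)] = v1 - v0
        elif v0 != 0:
            r = v1 / v0
            out[int(mother)] = r if mode == "ratio" else (r - 1.0) * 100.0
    return out
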