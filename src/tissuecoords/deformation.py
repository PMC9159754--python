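"""Cubic-RBF deformation functions and what they enable.

A deformation function maps every point of one time point's space onto the
next: scattered landmark correspondences (cell centroids and/or junctions)
are interpolated with cubic radial-basis functions φ(r) = r³ plus a linear
polynomial, the classical polyharmonic spline in 3D.  Its analytic gradient
is the local deformation gradient F, which yields continuous (subcellular)
growth maps.  The same machinery drives semi-automatic lineage tracking —
map unassigned cells into the earlier frame, adopt the nearest cell, verify
by neighbourhood correspondence, clear failures and iterate — and
Catmull-Rom morphing of mesh sequences.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from . import _geom
from .core import ParentMap, SurfaceCellMesh, build_cell_graph

__all__ = [
    "DeformationField",
    "fit_deformation",
    "subcellular_growth",
    "auto_parent_label",
    "spread_seed_cells",
    "morph_sequence",
]


def spread_seed_cells(mesh, candidates=None, k: int = 3) -> list[int]:
    """Pick ``k`` mutually distant cells as tracking landmarks.

    Mirrors how a user places initial landmarks: spread across the tissue
    rather than clustered.  Greedy max-min selection starting from the
    lowest-corner cell; deterministic given the mesh.
    """
    from .core import VolumetricCellMesh as _Vol
    if candidates is None:
        candidates = ([int(l) for l in mesh.labels()] if not isinstance(mesh, _Vol)
                      else [int(l) for l in mesh.labels()])
    cents = {c: (mesh.cells[c].centroid() if isinstance(mesh, _Vol)
                 else mesh.cell_centroid(c)) for c in candidates}
    chosen = [min(candidates, key=lambda c: float(cents[c][0] + cents[c][1]))]
    while len(chosen) < min(k, len(candidates)):
        nxt = max((c for c in candidates if c not in chosen),
                  key=lambda c: min(float(np.linalg.norm(cents[c] - cents[s]))
                                    for s in chosen))
        chosen.append(nxt)
    return chosen


@dataclass
class DeformationField:
    """Fitted cubic-RBF + linear interpolant of landmark correspondences.

    Stored in source coordinates pre-scaled to zero mean and unit RMS radius
    for conditioning; ``weights`` are the per-center kernel coefficients and
    ``poly`` the 4x3 constant+linear block.  The side conditions
    Σw = 0 and Σ w ⊗ c = 0 hold after every fit, which makes the far field
    affine and gives exact reproduction of affine data (zero RBF weights).
    """
    centers: np.ndarray          # (n, 3) scaled source landmarks
    weights: np.ndarray          # (n, 3)
    poly: np.ndarray             # (4, 3): [intercept; linear 3x3]
    mu: np.ndarray               # scaling offset
    scale: float                 # scaling factor
    ridge: float = 0.0

    def map(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        xs = (p - self.mu) / self.scale
        r = cdist(xs, self.centers)
        out = (r ** 3) @ self.weights + self.poly[0] + xs @ self.poly[1:]
        return out if np.ndim(points) == 2 else out[0]

    __call__ = map

    def gradient(self, point: np.ndarray) -> np.ndarray:
        """Analytic deformation gradient F (3x3) at *point*:
        Σᵢ wᵢ ⊗ 3 rᵢ (x − cᵢ) plus the linear block, unscaled."""
        xs = (np.asarray(point, dtype=float) - self.mu) / self.scale
        d = xs - self.centers
        r = np.linalg.norm(d, axis=1)
        J = self.poly[1:].T.copy()
        J += self.weights.T @ (3.0 * r[:, None] * d)
        return J / self.scale


def fit_deformation(source: np.ndarray, target: np.ndarray,
                    ridge: float = 0.0, allow_degenerate: bool = False) -> DeformationField:
    """Interpolate ``source -> target`` landmark pairs with φ(r)=r³ + linear
    polynomial.

    With ``ridge`` 0 the field passes through every landmark exactly; a
    positive ridge is added to the kernel diagonal for noisy landmarks.
    Coplanar or otherwise polynomially degenerate landmark sets raise by
    default (add landmarks or a ridge); with ``allow_degenerate`` the
    augmented system is solved in the minimum-norm sense instead, which
    still interpolates the landmarks — the natural choice when tracking
    flat 2.5D tissues whose centroids are (near-)coplanar.
    """
    src = np.asarray(source, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target, dtype=float).reshape(-1, 3)
    if src.shape != tgt.shape:
        raise ValueError("source and target landmark arrays must align")
    n = len(src)
    if n < 4:
        raise ValueError("need at least 4 landmarks for a 3D deformation function")
    mu = src.mean(axis=0)
    scale = float(np.sqrt(((src - mu) ** 2).sum(axis=1).mean()))
    if scale <= 0:
        raise ValueError("degenerate landmarks: all source points coincide")
    xs = (src - mu) / scale
    P = np.column_stack([np.ones(n), xs])
    degenerate = np.linalg.matrix_rank(P, tol=1e-9) < 4
    if degenerate and not allow_degenerate:
        raise ValueError("degenerate (coplanar/collinear) landmark set: add landmarks "
                         "or increase the ridge")
    K = cdist(xs, xs) ** 3
    if ridge:
        K = K + ridge * np.eye(n)
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = tgt
    if degenerate:
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    else:
        sol = np.linalg.solve(A, rhs)
    return DeformationField(centers=xs, weights=sol[:n], poly=sol[n:],
                            mu=mu, scale=scale, ridge=ridge)


def _affine_fit(source: np.ndarray, target: np.ndarray):
    """Fallback affine (or translation) map for sparse/degenerate seeds."""
    src = np.asarray(source, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target, dtype=float).reshape(-1, 3)
    if len(src) >= 3:
        # least-squares affine; under-determined sets (e.g. 3 points on a
        # surface) get the minimum-norm linear extension, which still
        # interpolates the pairs and captures in-plane scaling
        mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
        A, *_ = np.linalg.lstsq(src - mu_s, tgt - mu_t, rcond=None)
        return lambda p: (np.atleast_2d(p) - mu_s) @ A + mu_t
    t = (tgt - src).mean(axis=0)
    return lambda p: np.atleast_2d(p) + t


def subcellular_growth(field: DeformationField, mesh_t0: SurfaceCellMesh) -> dict:
    """Continuous growth map: per-vertex stretches of the deformation field.

    At every t0 vertex the analytic gradient F is restricted to the local
    tangent plane (SVD of F·[e1 e2]); returns arrays ``kmax``, ``kmin``,
    their product (the heat value combining maximal and minimal growth),
    and the world-space direction of maximal stretch.
    """
    v = mesh_t0.vertices
    tris = mesh_t0.triangles
    # per-vertex normals: mean of incident triangle normals
    tn = _geom.triangle_normals(v, tris)
    normals = np.zeros_like(v)
    for k in range(3):
        np.add.at(normals, tris[:, k], tn)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    normals /= norms
    kmax = np.zeros(len(v))
    kmin = np.zeros(len(v))
    emax = np.zeros_like(v)
    for i in range(len(v)):
        e1, e2 = _geom.tangent_basis(normals[i])
        F = field.gradient(v[i])
        M = F @ np.column_stack([e1, e2])          # 3x2
        W, s, Vt = np.linalg.svd(M, full_matrices=False)
        kmax[i], kmin[i] = s[0], s[1]
        emax[i] = Vt[0, 0] * e1 + Vt[0, 1] * e2
    return {"kmax": kmax, "kmin": kmin, "product": kmax * kmin, "emax_world": emax}


def auto_parent_label(
    mesh_t0, mesh_t1, seeds,
    max_iter: int = 50,
    compat_fraction: float = 1.0,
    gate_factor: float = 1.0,
    ridge: float = 0.1,
    graph_t0=None, graph_t1=None,
) -> tuple[ParentMap, list[int]]:
    """Semi-automatic lineage from a few seed correspondences.

    ``seeds`` maps t1 child labels to their t0 parents.  Each round fits a
    t1 -> t0 deformation function from the verified pairs' centroids (affine
    only while fewer than 4 non-degenerate pairs exist), maps every
    unassigned t1 centroid into the t0 frame and adopts the nearest t0 cell
    (ties by distance then lowest label).  Every assignment must then pass
    the neighbourhood check: all verified t1 neighbours of a child must map
    to its parent or to a t0 neighbour of its parent, and at least one
    neighbour must be verified; failing assignments are cleared and the
    process repeats until stable, so correct labels grow outward from the
    seeds.  A cell is only adopted while the field maps its centroid to
    within ``gate_factor`` effective cell radii of the adopted parent's
    centroid (i.e. roughly inside the parent) — the field is accurate near
    verified landmarks and degrades away from them, so the gate confines
    adoption to the trustworthy frontier, and normalising by cell radius
    keeps daughters of large mothers from being stolen by small neighbours.
    Only verified assignments are returned; the second element lists t1
    cells left unresolved for manual curation.
    """
    seeds = {int(c): int(p) for c, p in dict(seeds).items()}
    if not seeds:
        raise ValueError("at least one seed pair is required")
    g0 = graph_t0 if graph_t0 is not None else build_cell_graph(mesh_t0)
    g1 = graph_t1 if graph_t1 is not None else build_cell_graph(mesh_t1)
    c0 = {int(l): g0.nodes[l]["centroid"] for l in g0.nodes}
    c1 = {int(l): g1.nodes[l]["centroid"] for l in g1.nodes}
    bad = [c for c in seeds if c not in c1] + [p for p in seeds.values() if p not in c0]
    if bad:
        raise ValueError(f"seed labels missing from meshes: {sorted(set(bad))}")
    t0_labels = sorted(c0)
    t0_pts = np.array([c0[l] for l in t0_labels])
    tree0 = cKDTree(t0_pts)
    nbr0 = {l: set(g0.neighbors(l)) for l in g0.nodes}
    # adoption resolves the containing t0 cell: nearest point among a dense
    # per-cell sample (triangle centroids, vertices and the cell centroid),
    # so an off-centre daughter mapped inside a large mother is not stolen by
    # a small adjacent cell whose centroid happens to be closer
    from . import _geom
    from .core import VolumetricCellMesh as _Vol
    sample_pts, sample_lab = [], []
    if isinstance(mesh_t0, _Vol):
        radii = {}
        for l in t0_labels:
            cell = mesh_t0.cells[l]
            tc = _geom.triangle_centroids(cell.vertices, cell.triangles)
            sample_pts.append(np.vstack([tc, c0[l][None, :]]))
            sample_lab.append(np.full(len(tc) + 1, l))
            radii[l] = (3 * cell.volume() / (4 * np.pi)) ** (1 / 3)
    else:
        radii = {}
        for l in t0_labels:
            idx = mesh_t0.cell_triangle_indices(l)
            tri = mesh_t0.triangles[idx]
            tc = _geom.triangle_centroids(mesh_t0.vertices, tri)
            vs = mesh_t0.vertices[np.unique(tri)]
            sample_pts.append(np.vstack([tc, vs, c0[l][None, :]]))
            sample_lab.append(np.full(len(tc) + len(vs) + 1, l))
            radii[l] = np.sqrt(mesh_t0.cell_area(l) / np.pi)
    sample_pts = np.vstack(sample_pts)
    sample_lab = np.concatenate(sample_lab)
    sample_tree = cKDTree(sample_pts)
    samples_by_label = {l: sample_pts[sample_lab == l] for l in t0_labels}
    r0 = {l: max(r, 1e-9) for l, r in radii.items()}

    if isinstance(mesh_t1, _Vol):
        size1 = {int(l): mesh_t1.cells[l].volume() for l in c1}
    else:
        size1 = {int(l): mesh_t1.cell_area(l) for l in c1}
    if isinstance(mesh_t0, _Vol):
        size0 = {int(l): mesh_t0.cells[l].volume() for l in t0_labels}
    else:
        size0 = {int(l): mesh_t0.cell_area(l) for l in t0_labels}

    # per-cell junction positions (surface meshes): once a pair is verified,
    # its matched junctions become extra landmarks that pin the local
    # deformation much more tightly than centroids alone
    def _cell_junction_points(mesh):
        if isinstance(mesh, _Vol):
            return {}
        out: dict[int, list] = {}
        vl = mesh.vertex_labels()
        for v in mesh.junctions():
            for lab in vl[v]:
                if lab > 0:
                    out.setdefault(int(lab), []).append(mesh.vertices[v])
        return {l: np.array(p) for l, p in out.items()}

    junc0 = _cell_junction_points(mesh_t0)
    junc1 = _cell_junction_points(mesh_t1)
    jsrc = np.zeros((0, 3))
    jdst = np.zeros((0, 3))

    assigned = dict(seeds)
    for _ in range(max_iter):
        src = np.array([c1[c] for c in assigned])
        dst = np.array([c0[p] for p in assigned.values()])
        if len(jsrc):
            src = np.vstack([src, jsrc])
            dst = np.vstack([dst, jdst])
        try:
            fld = fit_deformation(src, dst, ridge=ridge, allow_degenerate=True)
            mapper = fld.map
        except ValueError:
            mapper = _affine_fit(src, dst)
        if ridge > 0 and len(assigned) > 8:
            # with a smoothing ridge the field no longer interpolates its
            # landmarks exactly, so a pair disagreeing with the consensus of
            # its neighbours stands out: its mapped centroid falls outside
            # the claimed parent's region.  Such pairs are cleared.
            mapped_assigned = np.atleast_2d(mapper(src[:len(assigned)]))
            keep = {}
            for (child, parent), mp in zip(assigned.items(), mapped_assigned):
                d_region = np.min(np.linalg.norm(samples_by_label[parent] - mp, axis=1))
                if child in seeds or d_region <= 0.35 * r0[parent]:
                    keep[child] = parent
            assigned = keep
        todo = [l for l in sorted(c1) if l not in assigned]
        proposal = dict(assigned)
        if todo:
            mapped = np.atleast_2d(mapper(np.array([c1[l] for l in todo])))
            d, idx = sample_tree.query(mapped)
            for l, dd, i in zip(todo, d, idx):
                cand = int(sample_lab[int(i)])
                if dd <= gate_factor * r0[cand]:
                    proposal[l] = cand
        # verification: every assigned neighbour must be compatible, and the
        # assignment must touch the already-verified region — correct labels
        # grow out from the landmarks instead of locking in coherent but
        # globally shifted patches
        verified = dict(seeds)
        for child, parent in proposal.items():
            if child in seeds:
                continue
            nb = [x for x in g1.neighbors(child) if x in assigned]
            if not nb:
                continue
            ok = sum(1 for x in nb
                     if assigned[x] == parent or assigned[x] in nbr0[parent])
            if ok >= compat_fraction * len(nb):
                verified[child] = parent
        # sibling-coherence: all children claiming one parent must form a
        # connected patch in t1 (daughters share the division wall); a
        # disconnected claimant is an off-by-one adoption and is cleared
        by_parent: dict[int, list[int]] = {}
        for child, parent in verified.items():
            by_parent.setdefault(parent, []).append(child)
        for parent, claim in by_parent.items():
            if len(claim) < 2:
                continue
            sub = g1.subgraph(claim)
            import networkx as _nx
            comps = list(_nx.connected_components(sub))
            if len(comps) > 1:
                keep_comp = max(comps, key=lambda cc: (any(x in seeds for x in cc), len(cc)))
                for cc in comps:
                    if cc is keep_comp:
                        continue
                    for x in cc:
                        if x not in seeds:
                            del verified[x]
        # size conservation: the t1 material claimed on a parent, mapped back
        # through the field, must roughly reproduce the parent's size.  An
        # extra (off-by-one) claimant roughly doubles the claim and is
        # cleared, worst region-fit first.
        if ridge > 0 and len(assigned) > 8:
            by_parent = {}
            for child, parent in verified.items():
                by_parent.setdefault(parent, []).append(child)
            for parent, claim in by_parent.items():
                if len(claim) < 2:
                    continue
                while len(claim) > 1:
                    mid = np.mean([c1[x] for x in claim], axis=0)
                    try:
                        J = fld.gradient(mid)
                        if isinstance(mesh_t1, _Vol):
                            det2 = abs(float(np.linalg.det(J)))
                        else:
                            e1, e2 = _geom.tangent_basis(mesh_t1.cell_normal(claim[0]))
                            det2 = float(np.linalg.norm(np.cross(J @ e1, J @ e2)))
                    except Exception:
                        break
                    r = det2 * sum(size1[x] for x in claim) / max(size0[parent], 1e-12)
                    if r <= 1.35:
                        break
                    removable = [x for x in claim if x not in seeds]
                    if not removable:
                        break
                    worst = max(removable, key=lambda x: float(np.min(np.linalg.norm(
                        samples_by_label[parent] - np.atleast_2d(mapper(c1[x]))[0], axis=1))))
                    claim.remove(worst)
                    del verified[worst]
        # refresh junction landmarks from verified frontier pairs: junctions
        # of a singleton child matched (1-1, nearest within half a cell
        # radius) to its parent's junctions through the current field
        n_children = {}
        for p in verified.values():
            n_children[p] = n_children.get(p, 0) + 1
        jsrc_list, jdst_list = [], []
        for child, parent in verified.items():
            if n_children[parent] != 1 or child not in junc1 or parent not in junc0:
                continue
            if not any(x not in verified for x in g1.neighbors(child)):
                continue   # only frontier cells need the extra pinning
            pts1 = junc1[child]
            pts0 = junc0[parent]
            back = np.atleast_2d(mapper(pts1))
            dmat = np.linalg.norm(back[:, None, :] - pts0[None, :, :], axis=2)
            used0: set[int] = set()
            for k in np.argsort(dmat.min(axis=1)):
                j = int(np.argmin(np.where(np.isin(np.arange(len(pts0)), list(used0)),
                                           np.inf, dmat[k])))
                if dmat[k, j] <= 0.5 * r0[parent]:
                    used0.add(j)
                    jsrc_list.append(pts1[k])
                    jdst_list.append(pts0[j])
        if jsrc_list:
            jsrc = np.array(jsrc_list)
            jdst = np.array(jdst_list)
        else:
            jsrc = np.zeros((0, 3))
            jdst = np.zeros((0, 3))
        if verified == assigned:
            break
        assigned = verified
    unresolved = sorted(set(c1) - set(assigned))
    return ParentMap(assigned), unresolved


# --------------------------------------------------------------------------
# Catmull-Rom morphing
# --------------------------------------------------------------------------

def _catmull_rom(P0, P1, P2, P3, u, alpha=0.5):
    """Centripetal Catmull-Rom point at local parameter u in [0,1] between
    P1 and P2, vectorised over point rows."""
    def tj(ti, a, b):
        d = np.linalg.norm(b - a, axis=-1)
        return ti + np.maximum(d, 1e-12) ** alpha
    t0 = np.zeros(P0.shape[0])
    t1 = tj(t0, P0, P1)
    t2 = tj(t1, P1, P2)
    t3 = tj(t2, P2, P3)
    t = t1 + u * (t2 - t1)

    def lerp(pa, pb, ta, tb):
        w = ((t - ta) / np.where(tb - ta == 0, 1, tb - ta))[:, None]
        return (1 - w) * pa + w * pb

    A1 = lerp(P0, P1, t0, t1)
    A2 = lerp(P1, P2, t1, t2)
    A3 = lerp(P2, P3, t2, t3)
    B1 = lerp(A1, A2, t0, t2)
    B2 = lerp(A2, A3, t1, t3)
    return lerp(B1, B2, t1, t2)


def morph_sequence(meshes: list[SurfaceCellMesh], n_frames: int) -> list[SurfaceCellMesh]:
    """Interpolated mesh sequence through >=2 corresponding time points.

    All meshes must share vertex count and triangulation (per-vertex
    correspondence established beforehand, e.g. via deformation fields).
    Two time points interpolate linearly; three or more use centripetal
    (α=0.5) Catmull-Rom through each vertex's trajectory, with one-sided
    ghost points at the ends.  Frames at knots reproduce the inputs exactly;
    per-vertex signal is interpolated linearly within each interval.
    """
    if len(meshes) < 2:
        raise ValueError("morphing needs at least 2 time points")
    if n_frames < 2:
        raise ValueError("need at least 2 output frames")
    nv = len(meshes[0].vertices)
    for m in meshes[1:]:
        if len(m.vertices) != nv or len(m.triangles) != len(meshes[0].triangles):
            raise ValueError("meshes must share vertex correspondence and topology")
    K = len(meshes)
    times = np.linspace(0.0, K - 1.0, n_frames)
    out = []
    V = [m.vertices for m in meshes]
    S = [m.vertex_signal for m in meshes]
    has_signal = all(s is not None for s in S)
    for s_glob in times:
        k = min(int(np.floor(s_glob)), K - 2)
        u = s_glob - k
        if u <= 1e-12:
            pos = V[k].copy()
        elif u >= 1 - 1e-12:
            pos = V[k + 1].copy()
        elif K == 2:
            pos = (1 - u) * V[0] + u * V[1]
        else:
            P1, P2 = V[k], V[k + 1]
            P0 = V[k - 1] if k - 1 >= 0 else 2 * V[0] - V[1]
            P3 = V[k + 2] if k + 2 < K else 2 * V[-1] - V[-2]
            pos = _catmull_rom(P0, P1, P2, P3, u)
        sig = None
        if has_signal:
            sig = (1 - u) * S[k] + u * S[k + 1] if u > 0 else S[k].copy()
        out.append(SurfaceCellMesh(pos, meshes[0].triangles.copy(),
                                   meshes[0].face_label.copy(), sig))
    return out
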