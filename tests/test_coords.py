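"""Organ coordinate systems and per-cell frames."""
import heapq

import numpy as np
import pytest

from tissuecoords import AttributeMap, build_cell_graph
from tissuecoords import synthetic as syn
from tissuecoords.coords import (
    BezierSpline,
    attribute_gradient_directions,
    bezier_from_cell_file,
    bezier_line_coord,
    build_cell_frame,
    cell_distance,
    mesh_distance,
    polar_coord,
    relative_radial_coord,
)


# --------------------------------------------------------------------------
# cell_distance
# --------------------------------------------------------------------------

def _dijkstra_oracle(graph, seeds, weight_fn):
    """Textbook binary-heap Dijkstra, independent of networkx."""
    dist = {s: 0.0 for s in seeds}
    heap = [(0.0, s) for s in seeds]
    heapq.heapify(heap)
    done = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v in graph.neighbors(u):
            nd = d + weight_fn(u, v, graph[u][v])
            if v not in dist or nd < dist[v]:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


def test_cell_distance_path_modes():
    mesh, _ = syn.make_grid_tissue(3, 1)
    g = build_cell_graph(mesh)
    assert dict(cell_distance(g, [1], "cells")) == {1: 0.0, 2: 1.0, 3: 2.0}
    eu = cell_distance(g, [1], "euclidean")
    assert eu[2] == pytest.approx(1.0) and eu[3] == pytest.approx(2.0)


@pytest.mark.parametrize("mode", ["euclidean", "cells", "inv_wall"])
def test_cell_distance_matches_dijkstra_oracle(voronoi_graph, mode):
    g = voronoi_graph
    seeds = [min(g.nodes)]
    got = cell_distance(g, seeds, mode)
    if mode == "cells":
        wf = lambda u, v, d: 1.0
    elif mode == "euclidean":
        wf = lambda u, v, d: float(np.linalg.norm(g.nodes[u]["centroid"] - g.nodes[v]["centroid"]))
    else:
        wf = lambda u, v, d: 1.0 / max(d["wall_measure"], 1e-9)
    expect = _dijkstra_oracle(g, seeds, wf)
    assert set(got) == set(expect)
    for k in got:
        assert got[k] == pytest.approx(expect[k], abs=1e-9)


def test_cell_distance_triangle_inequality(voronoi_graph):
    g = voronoi_graph
    d = cell_distance(g, [1], "euclidean")
    for u, v in g.edges:
        w = float(np.linalg.norm(g.nodes[u]["centroid"] - g.nodes[v]["centroid"]))
        assert d[u] <= d[v] + w + 1e-9
    assert d[1] == 0.0


def test_cell_distance_empty_seeds(voronoi_graph):
    with pytest.raises(ValueError):
        cell_distance(voronoi_graph, [])


# --------------------------------------------------------------------------
# Bezier
# --------------------------------------------------------------------------

class _PointCloudMesh:
    def __init__(self, cents):
        self._c = {i + 1: np.asarray(c, dtype=float) for i, c in enumerate(cents)}

    def centroids(self):
        return self._c


def test_bezier_straight_line_coord():
    sp = BezierSpline.from_endpoints([0, 0, 0], [100, 0, 0])
    mesh = _PointCloudMesh([[50, 7, 0], [130, 5, 0]])
    coord, dist, tang = bezier_line_coord(mesh, sp)
    assert coord[1] == pytest.approx(50.0, abs=1e-3)
    assert dist[1] == pytest.approx(7.0, abs=1e-6)
    assert np.allclose(tang[1], [1, 0, 0], atol=1e-9)
    # beyond the end clamps to total arc length
    assert coord[2] == pytest.approx(sp.total_length, abs=1e-3)


def test_bezier_curved_matches_dense_sampling_oracle():
    cp = np.array([[0, 0, 0], [30, 60, 0], [70, -40, 20], [100, 10, 5]], dtype=float)
    sp = BezierSpline(cp)
    rng = np.random.default_rng(1)
    pts = rng.uniform(-10, 110, size=(10, 3))
    # oracle: brute force over 1e5 uniform parameter samples
    ts = np.linspace(0, 1, 100_001)
    curve = sp.evaluate(ts)
    arc = sp.arc_length(ts)
    mesh = _PointCloudMesh(pts)
    coord, dist, _ = bezier_line_coord(mesh, sp)
    for i, p in enumerate(pts, start=1):
        d2 = ((curve - p) ** 2).sum(axis=1)
        j = np.argmin(d2)
        assert dist[i] == pytest.approx(np.sqrt(d2[j]), abs=0.1)
        assert coord[i] == pytest.approx(arc[j], abs=0.1)


def test_bezier_rigid_invariance():
    cp = np.array([[0, 0, 0], [30, 60, 0], [70, -40, 20], [100, 10, 5]], dtype=float)
    p = np.array([[40.0, 10.0, 3.0]])
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
    t = np.array([5.0, -3.0, 11.0])
    c1, d1, _ = bezier_line_coord(_PointCloudMesh(p), BezierSpline(cp))
    c2, d2, _ = bezier_line_coord(_PointCloudMesh(p @ R.T + t), BezierSpline(cp @ R.T + t))
    assert c1[1] == pytest.approx(c2[1], abs=1e-5)
    assert d1[1] == pytest.approx(d2[1], abs=1e-6)


def test_bezier_degenerate_rejected():
    with pytest.raises(ValueError):
        BezierSpline(np.zeros((4, 3)))


def test_bezier_from_cell_file_cases():
    # collinear centroids -> straight spline
    line = _PointCloudMesh([[i * 10.0, 0, 0] for i in range(6)])
    sp = bezier_from_cell_file(list(line.centroids()), line)
    ts = np.linspace(0, 1, 100)
    assert np.abs(sp.evaluate(ts)[:, 1:]).max() < 1e-8
    # two cells -> straight segment between centroids
    two = _PointCloudMesh([[0, 0, 0], [10, 5, 0]])
    sp2 = bezier_from_cell_file([1, 2], two)
    assert np.allclose(sp2.evaluate(0.0), [0, 0, 0])
    assert np.allclose(sp2.evaluate(1.0), [10, 5, 0])
    # circular arc: fitted spline within 2% of radius of all centroids
    th = np.linspace(0, np.pi / 2, 9)
    arc = _PointCloudMesh(np.column_stack([50 * np.cos(th), 50 * np.sin(th), np.zeros(9)]))
    sp3 = bezier_from_cell_file(list(arc.centroids()), arc)
    for c in arc.centroids().values():
        d = min(np.linalg.norm(sp3.evaluate(t) - c) for t in np.linspace(0, 1, 2000))
        assert d < 0.02 * 50
    with pytest.raises(ValueError):
        bezier_from_cell_file([1], line)


# --------------------------------------------------------------------------
# polar / mesh distance / radial
# --------------------------------------------------------------------------

def test_polar_coord_known_angles():
    mesh = _PointCloudMesh([[1, 0, 5], [0, 1, 5], [-1, 0, 2]])
    pc = polar_coord(mesh, axis="z", reference=(1, 0, 0))
    assert pc[1] == pytest.approx(0.0, abs=1e-9)
    assert pc[2] == pytest.approx(90.0, abs=1e-9)
    assert pc[3] == pytest.approx(180.0, abs=1e-9)


def test_polar_coord_matches_atan2_oracle():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(20, 3))
    pc = polar_coord(_PointCloudMesh(pts), axis="z", reference=(1, 0, 0))
    for i, p in enumerate(pts, start=1):
        expect = np.degrees(np.arctan2(p[1], p[0])) % 360
        assert pc[i] == pytest.approx(expect, abs=1e-9)


def test_polar_on_axis_unassigned():
    pc = polar_coord(_PointCloudMesh([[0, 0, 3], [1, 0, 0]]), axis="z")
    assert 1 not in pc and 2 in pc


def test_mesh_distance_brute_force(voronoi_plane):
    mesh, _ = voronoi_plane
    other, _ = syn.make_grid_tissue(3, 3, cell_size=30.0)
    other.vertices[:, 2] += 4.0
    got = mesh_distance(mesh, other)
    for lab in mesh.labels():
        c = mesh.cell_centroid(int(lab))
        expect = np.linalg.norm(other.vertices - c, axis=1).min()
        assert got[int(lab)] == pytest.approx(expect, abs=1e-9)


def test_relative_radial_layers_monotone(organ_4layer, organ_surface):
    organ, gt = organ_4layer
    axis = BezierSpline.from_endpoints([0, 0, 0], [0, 0, 40])
    rel, absolute = relative_radial_coord(organ, axis, organ_surface)
    assert all(0.0 <= v <= 1.0 for v in rel.values())
    means = {}
    for lab, v in rel.items():
        means.setdefault(gt.layer[lab], []).append(v)
    layer_means = [np.mean(means[L]) for L in sorted(means)]
    assert all(a < b for a, b in zip(layer_means, layer_means[1:]))


def test_relative_radial_trivial_points(organ_surface):
    axis = BezierSpline.from_endpoints([0, 0, 0], [0, 0, 40])
    # fake "cells" at half and full radius of the organ surface (r=20)
    mesh = _PointCloudMesh([[10, 0, 20], [20, 0, 20]])
    rel, absolute = relative_radial_coord(mesh, axis, organ_surface)
    assert rel[1] == pytest.approx(0.5, abs=0.02)
    assert rel[2] == pytest.approx(1.0, abs=0.02)
    assert absolute[1] == pytest.approx(10.0, abs=1e-6)


# --------------------------------------------------------------------------
# direction frames
# --------------------------------------------------------------------------

def test_gradient_directions_linear_field():
    mesh, _ = syn.make_grid_tissue(5, 5)
    attr = AttributeMap({int(l): mesh.cell_centroid(int(l))[0] for l in mesh.labels()},
                        name="x")
    frames = attribute_gradient_directions(mesh, attr)
    interior = [7, 8, 9, 12, 13, 14, 17, 18, 19]
    for lab in interior:
        d1, d2, d3 = frames[lab]
        assert np.allclose(d1, [1, 0, 0], atol=1e-6)
        assert np.allclose(np.abs(d3), [0, 1, 0], atol=1e-6)


def test_gradient_matches_normal_equations_oracle():
    mesh, _ = syn.make_grid_tissue(5, 5)
    g = build_cell_graph(mesh)
    rng = np.random.default_rng(5)
    coef = np.array([0.3, -0.7, 0.0])
    attr = AttributeMap({int(l): float(mesh.cell_centroid(int(l)) @ coef
                                       + 0.01 * rng.normal()) for l in mesh.labels()},
                        name="noisy")
    frames = attribute_gradient_directions(mesh, attr, g)
    lab = 13
    members = [lab] + sorted(g.neighbors(lab))
    X = np.array([mesh.cell_centroid(m) for m in members])
    y = np.array([attr[m] for m in members])
    A = np.column_stack([np.ones(len(members)), X - X.mean(axis=0)])
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    gvec = sol[1:]
    gvec[2] = 0.0   # tangent plane of the flat tissue
    gvec /= np.linalg.norm(gvec)
    assert np.allclose(frames[lab][0], gvec, atol=1e-8)


def test_gradient_constant_field_unassigned():
    mesh, _ = syn.make_grid_tissue(3, 3)
    attr = AttributeMap({int(l): 5.0 for l in mesh.labels()}, name="const")
    frames = attribute_gradient_directions(mesh, attr)
    assert len(frames) == 0


def test_build_cell_frame_gram_schmidt():
    f = build_cell_frame(AttributeMap({1: [0, 0, 1]}, name="a"),
                         AttributeMap({1: [1, 0, 0]}, name="b"))
    assert np.allclose(f[1], [[0, 0, 1], [1, 0, 0], [0, 1, 0]])
    g = build_cell_frame(AttributeMap({1: [0, 0, 1]}, name="a"),
                         AttributeMap({1: np.array([1, 0, 1]) / np.sqrt(2)}, name="b"))
    assert np.allclose(g[1][1], [1, 0, 0], atol=1e-9)


def test_frames_orthonormal_right_handed():
    rng = np.random.default_rng(11)
    d1 = AttributeMap({i: v / np.linalg.norm(v) for i, v in
                       enumerate(rng.normal(size=(50, 3)))}, name="d1")
    d2 = AttributeMap({i: v / np.linalg.norm(v) for i, v in
                       enumerate(rng.normal(size=(50, 3)))}, name="d2")
    frames = build_cell_frame(d1, d2)
    assert len(frames) > 30
    for f in frames.values():
        assert np.allclose(f @ f.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(f) == pytest.approx(1.0, abs=1e-9)


def test_parallel_inputs_flagged():
    f = build_cell_frame(AttributeMap({1: [0, 0, 1]}, name="a"),
                         AttributeMap({1: [0, 0, 1]}, name="b"))
    assert 1 not in f
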