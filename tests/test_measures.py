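"""The per-cell measure catalogue."""
import itertools

import networkx as nx
import numpy as np
import pytest

from tissuecoords import AttributeMap, build_cell_graph
from tissuecoords import synthetic as syn
from tissuecoords.core import SurfaceCellMesh
from tissuecoords.measures import (
    ShapeAxes3D,
    cell_interior_samples,
    cell_length_along_direction,
    geometry_measures_2d,
    geometry_measures_3d,
    heat_bin,
    heat_smooth,
    lobeyness_measures,
    local_maxima,
    network_measures,
    shape_pca_3d,
    signal_measures,
    tissue_curvature,
)


def _polygon_mesh(poly2d, label=1):
    """Fan-triangulated planar polygon as a one-cell surface mesh."""
    poly2d = np.asarray(poly2d, dtype=float)
    c = poly2d.mean(axis=0)
    verts = [np.array([*c, 0.0])] + [np.array([x, y, 0.0]) for x, y in poly2d]
    k = len(poly2d)
    tris = [[0, 1 + i, 1 + (i + 1) % k] for i in range(k)]
    return SurfaceCellMesh(np.array(verts), np.array(tris), np.full(k, label))


# --------------------------------------------------------------------------
# 2D geometry
# --------------------------------------------------------------------------

def test_unit_square_geometry():
    mesh, _ = syn.make_grid_tissue(1, 1)
    g = geometry_measures_2d(mesh, 1)
    assert g["area"] == pytest.approx(1.0)
    assert g["perimeter"] == pytest.approx(4.0)


def test_rectangle_axes():
    mesh = _polygon_mesh([[0, 0], [2, 0], [2, 1], [0, 1]])
    g = geometry_measures_2d(mesh, 1)
    assert g["aspect_ratio"] == pytest.approx(2.0, abs=1e-9)
    assert abs(g["major_axis_direction"] @ np.array([1, 0, 0])) == pytest.approx(1.0, abs=1e-9)


def test_random_polygon_shoelace_oracle():
    rng = np.random.default_rng(4)
    th = np.sort(rng.uniform(0, 2 * np.pi, 9))
    r = rng.uniform(1, 3, 9)
    poly = np.column_stack([r * np.cos(th), r * np.sin(th)])
    mesh = _polygon_mesh(poly)
    g = geometry_measures_2d(mesh, 1)
    x, y = poly[:, 0], poly[:, 1]
    shoelace = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    edge_sum = np.linalg.norm(poly - np.roll(poly, -1, axis=0), axis=1).sum()
    assert g["area"] == pytest.approx(shoelace, abs=1e-9)
    assert g["perimeter"] == pytest.approx(edge_sum, abs=1e-9)


# --------------------------------------------------------------------------
# lobeyness family
# --------------------------------------------------------------------------

def test_convex_cell_reference_values():
    th = np.arange(6) * np.pi / 3
    hexagon = np.column_stack([np.cos(th), np.sin(th)])
    lb = lobeyness_measures(hexagon)
    assert lb["lobeyness"] == pytest.approx(1.0, abs=1e-9)
    assert lb["solidarity"] == pytest.approx(1.0, abs=1e-9)
    assert lb["visibility_stomata"] == pytest.approx(1.0, abs=1e-12)
    assert lb["visibility_pavement"] == pytest.approx(0.0, abs=1e-12)


def test_square_circularity():
    square = [[0, 0], [1, 0], [1, 1], [0, 1]]
    lb = lobeyness_measures(square)
    assert lb["circularity"] == pytest.approx(4.0 / np.pi, abs=1e-12)
    assert lb["rectangularity"] == pytest.approx(1.0, abs=1e-9)


def test_circularity_decreases_with_refinement():
    values = []
    for n in (6, 12, 24, 96):
        th = np.arange(n) * 2 * np.pi / n
        values.append(lobeyness_measures(np.column_stack([np.cos(th), np.sin(th)]))
                      ["circularity"])
    assert all(a > b for a, b in zip(values, values[1:]))
    assert values[-1] == pytest.approx(1.0, abs=1e-3)
    assert all(v >= 1.0 for v in values)


def test_plus_shape_complexity():
    plus = [[1, 0], [2, 0], [2, 1], [3, 1], [3, 2], [2, 2], [2, 3], [1, 3],
            [1, 2], [0, 2], [0, 1], [1, 1]]
    lb = lobeyness_measures(plus)
    # convex-hull oracle by gift wrapping
    def gift_wrap(pts):
        pts = [tuple(p) for p in pts]
        start = min(pts)
        hull = [start]
        cur = start
        while True:
            cand = pts[0] if pts[0] != cur else pts[1]
            for p in pts:
                if p == cur:
                    continue
                cross = ((cand[0] - cur[0]) * (p[1] - cur[1])
                         - (cand[1] - cur[1]) * (p[0] - cur[0]))
                if cross < 0:
                    cand = p
            if cand == start:
                return np.array(hull)
            hull.append(cand)
            cur = cand
    hull = gift_wrap(plus)
    hull_perim = np.linalg.norm(hull - np.roll(hull, -1, axis=0), axis=1).sum()
    x, y = np.array(plus, dtype=float).T
    perim = np.linalg.norm(np.array(plus) - np.roll(plus, -1, axis=0), axis=1).sum()
    hx, hy = hull.T
    hull_area = 0.5 * abs(np.sum(hx * np.roll(hy, -1) - np.roll(hx, -1) * hy))
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    assert lb["lobeyness"] == pytest.approx(perim / hull_perim, abs=1e-9)
    assert lb["solidarity"] == pytest.approx(hull_area / area, abs=1e-9)
    assert lb["lobeyness"] > 1.0 and lb["solidarity"] > 1.0
    assert lb["visibility_stomata"] < 1.0


def test_lobeyness_rigid_and_scale_invariant():
    rng = np.random.default_rng(7)
    th = np.sort(rng.uniform(0, 2 * np.pi, 10))
    poly = np.column_stack([np.cos(th), np.sin(th)]) * rng.uniform(1, 2, 10)[:, None]
    base = lobeyness_measures(poly)
    ang = 0.83
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    moved = lobeyness_measures(poly @ R.T * 3.7 + [11.0, -4.0])
    for key in ("circularity", "lobeyness", "rectangularity", "solidarity"):
        assert moved[key] == pytest.approx(base[key], rel=1e-9)


def test_self_intersecting_polygon_rejected():
    bow = [[0, 0], [1, 1], [1, 0], [0, 1]]
    with pytest.raises(ValueError):
        lobeyness_measures(bow)


# --------------------------------------------------------------------------
# 3D geometry
# --------------------------------------------------------------------------

def test_cube_measures(unit_box):
    g = geometry_measures_3d(unit_box)
    assert g["volume"] == pytest.approx(1.0)
    assert g["wall_area"] == pytest.approx(6.0)
    assert g["outside_wall_ratio"] == pytest.approx(1.0)


def test_stacked_cubes_outside_ratio():
    sb = syn.make_stacked_boxes()
    for lab in (1, 2):
        assert geometry_measures_3d(sb.cells[lab])["outside_wall_ratio"] == \
            pytest.approx(5.0 / 6.0)


def test_sphere_volume_closed_form():
    sp = syn.make_sphere_cell(radius=2.0, subdiv=3)
    assert geometry_measures_3d(sp)["volume"] == pytest.approx(4 / 3 * np.pi * 8, rel=0.02)


def test_volume_additive_over_adjacent_cells():
    sb = syn.make_stacked_boxes(split_z=0.7, top=2.0)
    from tissuecoords.division import combine_daughters
    union = combine_daughters(sb, 1, 2)
    assert union.volume() == pytest.approx(
        sb.cells[1].volume() + sb.cells[2].volume(), rel=1e-6)


def test_cell_length_cases(sphere_cell):
    box = syn.make_box_cell(((0, 0, 0), (2, 1, 1)))
    assert cell_length_along_direction(box, [1, 0, 0]) == pytest.approx(2.0)
    assert cell_length_along_direction(box, [0, 1, 0]) == pytest.approx(1.0)
    for d in ([1, 0, 0], [0.3, 0.5, 0.81]):
        assert cell_length_along_direction(sphere_cell, d) == pytest.approx(2.0, rel=0.01)


def test_cell_length_matches_brute_force_scan():
    rng = np.random.default_rng(11)
    box = syn.make_box_cell(((0, 0, 0), (3, 2, 1)))
    c = box.centroid()
    for _ in range(10):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        got = cell_length_along_direction(box, d)
        # oracle: Moller-Trumbore per triangle, pure python
        def ray(o, dd):
            best = np.inf
            for t in box.triangles:
                v0, v1, v2 = box.vertices[t]
                e1, e2 = v1 - v0, v2 - v0
                p = np.cross(dd, e2)
                det = e1 @ p
                if abs(det) < 1e-12:
                    continue
                tv = o - v0
                u = (tv @ p) / det
                q = np.cross(tv, e1)
                v = (dd @ q) / det
                tt = (e2 @ q) / det
                if u >= -1e-9 and v >= -1e-9 and u + v <= 1 + 1e-9 and tt > 1e-9:
                    best = min(best, tt)
            return best
        assert got == pytest.approx(ray(c, d) + ray(c, -d), abs=1e-9)


def test_shape_pca_formulas():
    ax = ShapeAxes3D(np.array([4.0, 2.0, 1.0]), np.eye(3))
    assert ax.elongation == pytest.approx(2.0)
    assert ax.flatness == pytest.approx(2.0)
    assert ax.anisotropy == pytest.approx((4 - 1 - 0.5) / 7)


def test_shape_pca_sphere_isotropic(sphere_cell):
    samples = cell_interior_samples(sphere_cell, 0.2)
    ax = shape_pca_3d(samples)
    assert ax.anisotropy == pytest.approx(0.0, abs=0.02)
    assert ax.elongation == pytest.approx(1.0, abs=0.05)


def test_shape_pca_ellipsoid_ratios():
    e = syn.make_sphere_cell(1.0, subdiv=3)
    from tissuecoords.core import CellSurface
    cell = CellSurface(e.vertices * [2.0, 1.0, 1.0], e.triangles, e.wall_label)
    ax = shape_pca_3d(cell_interior_samples(cell, 0.15))
    assert ax.elongation == pytest.approx(2.0, rel=0.03)


def test_shape_pca_degenerate_rejected():
    flat = np.column_stack([np.arange(10), np.arange(10) * 2, np.zeros(10)])
    with pytest.raises(ValueError):
        shape_pca_3d(flat)


# --------------------------------------------------------------------------
# network measures
# --------------------------------------------------------------------------

def _mini_graph(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    for u, v in g.edges:
        g[u][v]["wall_measure"] = 1.0
    return g


def test_betweenness_path_and_star():
    nm = network_measures(_mini_graph([(1, 2), (2, 3)]))
    assert dict(nm["betweenness"]) == {1: 0.0, 2: 1.0, 3: 0.0}
    star = network_measures(_mini_graph([(1, 2), (1, 3), (1, 4), (1, 5)]))
    assert star["betweenness"][1] == pytest.approx(6.0)   # C(4,2) pairs
    assert star["neighbors"][1] == 4


def _betweenness_oracle(g):
    """Exhaustive shortest-path counting for tiny graphs."""
    nodes = sorted(g.nodes)
    bc = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = list(nx.all_shortest_paths(g, s, t))
        for n in nodes:
            if n in (s, t):
                continue
            through = sum(1 for p in paths if n in p)
            bc[n] += through / len(paths)
    return bc


def test_betweenness_matches_exhaustive_oracle_small_graphs():
    rng = np.random.default_rng(13)
    for trial in range(6):
        n = int(rng.integers(4, 9))
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(10_000)))
        if not nx.is_connected(g):
            continue
        g = nx.relabel_nodes(g, {i: i + 1 for i in range(n)})
        for u, v in g.edges:
            g[u][v]["wall_measure"] = 1.0
        got = network_measures(g)["betweenness"]
        expect = _betweenness_oracle(g)
        for k in expect:
            assert got[k] == pytest.approx(expect[k], abs=1e-9)


def test_current_flow_defined_and_nonnegative(voronoi_graph):
    nm = network_measures(voronoi_graph, weighting="inv_wall")
    assert set(nm["current_flow"]) == set(voronoi_graph.nodes)
    assert all(v >= -1e-12 for v in nm["current_flow"].values())


# --------------------------------------------------------------------------
# signal / curvature
# --------------------------------------------------------------------------

def test_signal_uniform_and_zero():
    mesh, _ = syn.make_grid_tissue(1, 1, cell_size=4.0, subdiv=8)
    mesh.vertex_signal = np.full(len(mesh.vertices), 5.0)
    s = signal_measures(mesh, 1, border_width=1.0)
    for key in ("signal_total", "signal_border", "signal_interior"):
        assert s[key] == pytest.approx(5.0, abs=1e-12)
    mesh.vertex_signal[:] = 0.0
    s = signal_measures(mesh, 1, border_width=1.0)
    assert s["signal_total"] == 0.0


def test_signal_border_ring_only():
    mesh, _ = syn.make_grid_tissue(1, 1, cell_size=4.0, subdiv=8)
    loop = set(mesh.cell_boundary_loop(1).tolist())
    sig = np.zeros(len(mesh.vertices))
    for v in loop:
        sig[v] = 1.0
    mesh.vertex_signal = sig
    s = signal_measures(mesh, 1, border_width=0.25)
    assert s["signal_interior"] == pytest.approx(0.0)
    assert s["signal_border"] > s["signal_total"] > s["signal_interior"]


def test_curvature_plane_and_sphere():
    mesh, _ = syn.make_surface_tissue("plane", 30, seed=3, size=60.0)
    cv = tissue_curvature(mesh, radius=15.0)
    assert max(abs(v) for v in cv.values()) < 1e-6
    # sphere cap of radius 90 (size=60 -> R = 1.5*size); bumps positive
    cap, _ = syn.make_surface_tissue("sphere_cap", 30, seed=3, size=60.0)
    cvs = tissue_curvature(cap, radius=15.0)
    vals = list(cvs.values())
    assert np.mean(vals) == pytest.approx(1.0 / 90.0, rel=0.1)
    assert all(v > 0 for v in vals)


def test_curvature_radius_guard():
    mesh, _ = syn.make_surface_tissue("plane", 30, seed=3, size=60.0)
    with pytest.raises(ValueError):
        tissue_curvature(mesh, radius=0.01)


# --------------------------------------------------------------------------
# heat operators
# --------------------------------------------------------------------------

def test_heat_smooth_constant_and_spike():
    g = _mini_graph([(1, 2), (2, 3)])
    const = AttributeMap({1: 4.0, 2: 4.0, 3: 4.0}, name="c")
    assert dict(heat_smooth(const, g, 3)) == dict(const)
    spike = AttributeMap({1: 0.0, 2: 9.0, 3: 0.0}, name="s")
    sm = heat_smooth(spike, g, 1)
    assert sm[1] == pytest.approx(4.5)   # (0+9)/2
    assert sm[2] == pytest.approx(3.0)   # (0+9+0)/3
    assert sm[3] == pytest.approx(4.5)


def test_local_maxima_plateau_resolution():
    g = _mini_graph([(1, 2), (2, 3)])
    const = AttributeMap({1: 4.0, 2: 4.0, 3: 4.0}, name="c")
    assert local_maxima(const, g) == [1]   # one per plateau, lowest label
    spike = AttributeMap({1: 0.0, 2: 9.0, 3: 0.0}, name="s")
    assert local_maxima(spike, g) == [2]


def test_heat_bin_widths():
    vals = AttributeMap({i: float(i) for i in range(10)}, name="v")
    idx, stats = heat_bin(vals, bin_width=2.0)
    assert [stats[k][0] for k in sorted(stats)] == [2, 2, 2, 2, 2]
    assert idx[3] == 1
    idx2, stats2 = heat_bin(vals, n_bins=3)
    assert sum(s[0] for s in stats2.values()) == 10
    with pytest.raises(ValueError):
        heat_bin(vals)
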