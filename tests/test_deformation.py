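"""Deformation functions, lineage tracking and morphing."""
import numpy as np
import pytest

from tissuecoords import SurfaceCellMesh
from tissuecoords import synthetic as syn
from tissuecoords.deformation import (
    auto_parent_label,
    fit_deformation,
    morph_sequence,
    spread_seed_cells,
    subcellular_growth,
)


def _landmarks(n=30, seed=0):
    rng = np.random.default_rng(seed)
    return rng.uniform(0, 100, size=(n, 3))


def test_translation_has_zero_rbf_weights():
    src = _landmarks()
    f = fit_deformation(src, src + [5.0, -2.0, 1.0])
    assert np.abs(f.weights).max() < 1e-8
    p = np.array([[3.0, 4.0, 5.0]])
    assert np.allclose(f.map(p), p + [5, -2, 1], atol=1e-8)


def test_affine_reproduction():
    src = _landmarks(seed=1)
    A = np.array([[1.2, 0.1, 0.0], [0.0, 0.9, 0.05], [0.02, 0.0, 1.1]])
    f = fit_deformation(src, src @ A.T + [1, 2, 3])
    assert np.abs(f.weights).max() < 1e-8
    test = _landmarks(5, seed=2)
    assert np.allclose(f.map(test), test @ A.T + [1, 2, 3], atol=1e-7)
    assert np.allclose(f.gradient(test[0]), A, atol=1e-8)


def test_interpolation_and_side_conditions():
    src = _landmarks(seed=3)
    tgt = src + 2.0 * np.sin(src / 15.0)
    f = fit_deformation(src, tgt)
    assert np.abs(f.map(src) - tgt).max() < 1e-8
    assert np.abs(f.weights.sum(axis=0)).max() < 1e-8
    assert np.abs(f.weights.T @ f.centers).max() < 1e-8


def test_gradient_matches_finite_differences():
    src = _landmarks(seed=4)
    tgt = src + 2.0 * np.sin(src / 15.0)
    f = fit_deformation(src, tgt)
    p = np.array([40.0, 30.0, 20.0])
    J = f.gradient(p)
    h = 1e-4
    Jfd = np.zeros((3, 3))
    for j in range(3):
        e = np.zeros(3)
        e[j] = h
        Jfd[:, j] = (f.map(p + e) - f.map(p - e)) / (2 * h)
    assert np.abs(J - Jfd).max() / np.abs(J).max() < 1e-5


def test_degenerate_landmarks_rejected_by_default():
    src = _landmarks(seed=5)
    src[:, 2] = 0.0
    with pytest.raises(ValueError, match="degenerate"):
        fit_deformation(src, src)
    f = fit_deformation(src, src * [2, 1, 1], allow_degenerate=True)
    assert np.abs(f.map(src) - src * [2, 1, 1]).max() < 1e-7


def test_subcellular_growth_affine():
    mesh, _ = syn.make_grid_tissue(4, 4, subdiv=2)
    lm = _landmarks(seed=6)
    f = fit_deformation(lm, lm @ np.diag([2.0, 1.0, 1.0]))
    g = subcellular_growth(f, mesh)
    assert np.allclose(g["kmax"], 2.0, atol=1e-6)
    assert np.allclose(g["kmin"], 1.0, atol=1e-6)
    assert np.allclose(g["product"], 2.0, atol=1e-6)
    # identity -> product 1 everywhere
    gi = subcellular_growth(fit_deformation(lm, lm), mesh)
    assert np.allclose(gi["product"], 1.0, atol=1e-9)


def test_subcellular_growth_matches_analytic_jacobian():
    """Spatially varying warp: per-vertex stretches within 1% of the
    generator's analytic Jacobian."""
    mesh, _ = syn.make_grid_tissue(5, 5, cell_size=20.0, subdiv=2)
    warp = syn.RadialGrowthDeformation(center=[50, 50, 0], gain=3e-5)
    # landmark grid over the domain feeds the fitted field
    xs = np.linspace(-5, 105, 12)
    grid = np.array([[x, y, z] for x in xs for y in xs for z in (-3.0, 3.0)])
    f = fit_deformation(grid, warp.map(grid))
    g = subcellular_growth(f, mesh)
    for i, v in enumerate(mesh.vertices[::17]):
        J = warp.jacobian(v)
        M = J @ np.array([[1.0, 0], [0, 1.0], [0, 0]])
        s = np.linalg.svd(M, compute_uv=False)
        assert g["kmax"][17 * i] == pytest.approx(s[0], rel=0.01)
        assert g["kmin"][17 * i] == pytest.approx(s[1], rel=0.01)


# --------------------------------------------------------------------------
# lineage tracking
# --------------------------------------------------------------------------

def _timelapse_case(mesh_seed, div_seed, division_rate):
    m0, _ = syn.make_surface_tissue("plane", 200, seed=mesh_seed, size=200.0)
    warp = syn.RadialGrowthDeformation(center=[100, 100, 0], gain=1e-5)
    m1, parents, gt = syn.apply_timelapse(m0, warp, division_rate=division_rate,
                                          seed=div_seed)
    nondiv = [c for c, p in parents.items() if c == p]
    seeds = {s: s for s in spread_seed_cells(m1, nondiv)}
    return m0, m1, parents, seeds


def test_tracking_no_divisions_full_recovery():
    m0, m1, parents, seeds = _timelapse_case(21, 0, division_rate=0.0)
    pm, unresolved = auto_parent_label(m0, m1, seeds)
    assert unresolved == []
    assert dict(pm) == dict(parents)


def test_tracking_with_divisions_full_recovery():
    m0, m1, parents, seeds = _timelapse_case(22, 30, division_rate=0.2)
    pm, unresolved = auto_parent_label(m0, m1, seeds)
    assert unresolved == []
    wrong = [c for c in pm if pm[c] != parents[c]]
    assert wrong == []
    assert len(pm) == len(m1.labels())


def test_tracking_never_assigns_foreign_cells():
    """An extra cell patch absent at t0 stays unresolved, never mislabelled."""
    m0, m1, parents, seeds = _timelapse_case(23, 1, division_rate=0.1)
    # graft a disconnected far-away cell onto t1
    extra, _ = syn.make_grid_tissue(1, 1, cell_size=8.0)
    extra_label = int(m1.labels().max()) + 50
    base = len(m1.vertices)
    verts = np.vstack([m1.vertices, extra.vertices + [600.0, 600.0, 0.0]])
    tris = np.vstack([m1.triangles, extra.triangles + base])
    labels = np.concatenate([m1.face_label, np.full(len(extra.triangles), extra_label)])
    m1b = SurfaceCellMesh(verts, tris, labels)
    pm, unresolved = auto_parent_label(m0, m1b, seeds)
    assert extra_label not in pm
    assert extra_label in unresolved


def test_tracking_self_consistency(voronoi_plane):
    """Every returned assignment passes the tracker's own neighbourhood
    test: assigned neighbours map to the parent or a neighbour of it."""
    from tissuecoords import build_cell_graph
    m0, m1, parents, seeds = _timelapse_case(24, 2, division_rate=0.2)
    pm, _ = auto_parent_label(m0, m1, seeds)
    g0 = build_cell_graph(m0)
    g1 = build_cell_graph(m1)
    for child, parent in pm.items():
        nb = [x for x in g1.neighbors(child) if x in pm]
        assert nb, f"child {child} verified without assigned neighbours"
        for x in nb:
            assert pm[x] == parent or pm[x] in g0.neighbors(parent)


def test_tracking_requires_seeds(voronoi_plane):
    mesh, _ = voronoi_plane
    with pytest.raises(ValueError):
        auto_parent_label(mesh, mesh, {})


# --------------------------------------------------------------------------
# morphing
# --------------------------------------------------------------------------

def _scaled(mesh, s):
    sig = None if mesh.vertex_signal is None else mesh.vertex_signal * s
    return SurfaceCellMesh(mesh.vertices * s, mesh.triangles, mesh.face_label, sig)


def test_morph_two_frames_linear(grid_2x2):
    mesh, _ = grid_2x2
    m0 = SurfaceCellMesh(mesh.vertices, mesh.triangles, mesh.face_label,
                         np.zeros(len(mesh.vertices)))
    m1 = SurfaceCellMesh(mesh.vertices * 2, mesh.triangles, mesh.face_label,
                         np.full(len(mesh.vertices), 10.0))
    frames = morph_sequence([m0, m1], 3)
    assert np.allclose(frames[1].vertices, 1.5 * mesh.vertices)
    assert np.allclose(frames[1].vertex_signal, 5.0)
    # 30% of the way: heat 0 -> 10 interpolates to 3
    f = morph_sequence([m0, m1], 11)[3]
    assert np.allclose(f.vertex_signal, 3.0)


def test_morph_knots_reproduce_inputs(grid_2x2):
    mesh, _ = grid_2x2
    seq = [_scaled(mesh, s) for s in (1.0, 2.0, 3.5, 4.0)]
    frames = morph_sequence(seq, 7)
    for i, m in enumerate(seq):
        assert np.abs(frames[2 * i].vertices - m.vertices).max() < 1e-9


def test_morph_time_reversal_symmetric(grid_2x2):
    mesh, _ = grid_2x2
    m0 = _scaled(mesh, 1.0)
    m1 = _scaled(mesh, 2.0)
    fwd = morph_sequence([m0, m1], 9)
    bwd = morph_sequence([m1, m0], 9)
    for a, b in zip(fwd, reversed(bwd)):
        assert np.allclose(a.vertices, b.vertices, atol=1e-12)


def test_morph_input_validation(grid_2x2):
    mesh, _ = grid_2x2
    with pytest.raises(ValueError):
        morph_sequence([mesh], 5)
    with pytest.raises(ValueError):
        morph_sequence([mesh, mesh], 1)
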