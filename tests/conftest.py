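import numpy as np
import pytest

from tissuecoords import build_cell_graph
from tissuecoords import synthetic as syn


@pytest.fixture(scope="session")
def grid_2x2():
    mesh, gt = syn.make_grid_tissue(2, 2)
    return mesh, gt


@pytest.fixture(scope="session")
def voronoi_plane():
    """Mid-size Lloyd-relaxed Voronoi tissue on a plane."""
    mesh, gt = syn.make_surface_tissue("plane", 50, seed=7, size=100.0)
    return mesh, gt


@pytest.fixture(scope="session")
def voronoi_graph(voronoi_plane):
    mesh, _ = voronoi_plane
    return build_cell_graph(mesh)


@pytest.fixture(scope="session")
def organ_4layer():
    mesh, gt = syn.make_organ_3d(n_layers=4, cells_per_ring=8, n_rings=4, arc_subdiv=3)
    return mesh, gt


@pytest.fixture(scope="session")
def organ_surface(organ_4layer):
    """Outer surface of the 4-layer organ as a labelled surface mesh."""
    from tissuecoords.core import SurfaceCellMesh
    mesh, _ = organ_4layer
    verts, tris, labs = [], [], []
    for lab, cell in mesh.cells.items():
        mask = cell.wall_label == 0
        base = len(verts)
        verts.extend(cell.vertices)
        for t in cell.triangles[mask]:
            tris.append([base + t[0], base + t[1], base + t[2]])
            labs.append(lab)
    return SurfaceCellMesh(np.array(verts), np.array(tris), np.array(labs))


@pytest.fixture(scope="session")
def unit_box():
    return syn.make_box_cell()


@pytest.fixture(scope="session")
def sphere_cell():
    return syn.make_sphere_cell(radius=1.0, subdiv=3)
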