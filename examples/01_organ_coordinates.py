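"""Organ-centric coordinates on a synthetic layered root.

Builds a 4-layer cylindrical organ, attaches a central Bezier axis, computes
each cell's relative radial coordinate (0 = on the axis, 1 = on the organ
surface) and classifies the cell layers from it.
"""
import numpy as np

from tissuecoords import SurfaceCellMesh
from tissuecoords import synthetic as syn
from tissuecoords.classify import detect_layers
from tissuecoords.coords import BezierSpline, relative_radial_coord

organ, truth = syn.make_organ_3d(n_layers=4, cells_per_ring=8, n_rings=4)

# the organ surface (outside-tagged walls) as a labelled surface mesh
verts, tris, labs = [], [], []
for lab, cell in organ.cells.items():
    outside = cell.wall_label == 0
    base = len(verts)
    verts.extend(cell.vertices)
    for t in cell.triangles[outside]:
        tris.append([base + t[0], base + t[1], base + t[2]])
        labs.append(lab)
surface = SurfaceCellMesh(np.array(verts), np.array(tris), np.array(labs))

axis = BezierSpline.from_endpoints([0, 0, 0], [0, 0, 40])
rel, absolute = relative_radial_coord(organ, axis, surface)
layers = detect_layers(rel, mode="radial", k=4)

print(f"{len(organ.cells)} cells; relative radial coordinate spans "
      f"{min(rel.values()):.3f} .. {max(rel.values()):.3f}")
for L in sorted(set(layers.values())):
    members = [l for l in layers if layers[l] == L]
    mean_rel = np.mean([rel[l] for l in members])
    print(f"  detected layer {L} (outermost=1): {len(members)} cells, "
          f"mean relative radius {mean_rel:.3f}")
correct = sum(1 for l in layers if layers[l] == 4 + 1 - truth.layer[l])
print(f"layer assignment matches the generator ground truth for "
      f"{correct}/{len(layers)} cells")
# Each detected layer is a concentric shell; the mean relative radius drops
# from the epidermis (~0.86) toward the innermost tissue (~0.16).
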