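# Methods

This note documents the models, conventions and numerical choices behind
`tissuecoords`, in the order the modules build on each other, and states what
the synthetic fixtures do and do not demonstrate.

## Mesh model and conventions

All geometry is in micrometres, right-handed axes.  Cell labels are positive
integers; 0 means background/unlabeled/outside.

A **surface cell mesh** is a triangulated 2.5D surface with one cell label
per triangle and optional non-negative per-vertex signal.  Junctions are
derived, not stored: a vertex incident to ≥3 distinct cell labels, or to 2
labels while lying on the open mesh border.  Cell outlines are recovered by
chaining directed boundary edges (edges whose reverse is absent within the
cell's triangle set), which also fixes their orientation to the triangle
winding.

A **volumetric cell mesh** is a set of closed, outward-oriented per-cell
surfaces whose wall triangles carry the neighbouring cell's label (0 =
outside).  Validation checks watertightness (every edge used exactly twice),
positive volume, and symmetric wall areas between neighbour pairs.

*2.5D convention*: every planar measure flattens the cell into its tangent
plane, defined by the area-weighted mean triangle normal.

*File formats*: a documented PLY profile (per-vertex double x/y/z and
optional `signal`, per-face vertex list plus int `label`; ASCII and
binary-little-endian read, binary written), OBJ with labels encoded as
`usemtl cell_<label>`, and 3D label TIFF stacks.  TIFF import extracts exact
voxel-boundary surfaces (each inter-label voxel face becomes two triangles
tagged with the neighbour's label).  This is the iso-surface of each label's
binary mask at the half-voxel level with no smoothing: topology, neighbour
tags and wall areas are exact by construction, at the cost of blocky
geometry.  Attribute maps (per-label scalars, 3-vectors, symmetric tensors)
round-trip through CSV with component-suffixed columns; missing labels stay
missing.

Adjacency in the cell graph requires shared boundary of positive measure
(an edge in 2.5D, a wall patch in 3D); a single shared vertex is not
adjacency, which prevents diagonal-contact artifacts.  Edge weight is the
summed shared boundary length (µm) or wall area (µm²).

## Organ coordinates

*Cell distance*: multi-source Dijkstra to the nearest seed; edge weights are
centroid-to-centroid Euclidean distance, 1 per edge, or `1/wall_measure`
(floored at 1e-9).  Centroid distance was chosen for the Euclidean mode and
documented; wall-crossing distance is a plausible alternative the module
does not implement.

*Bezier axes*: composite cubic Bezier with clamped ends and a global
parameter uniform across segments.  Arc length comes from an 8-point
Gauss–Legendre quadrature of the speed on each of 1000 sub-intervals per
segment (cumulative table); the nearest point to a query is the winning
dense sample refined by golden-section search on its bracketing interval.
Axis fitting through a cell file pins the endpoints and least-squares fits
the interior control points under chord-length parameterization, one segment
per four cells.

*Relative radial coordinate*: a ray from the nearest axis point through the
cell centroid is intersected with the organ surface (vectorised
Möller–Trumbore); the coordinate is the centroid's axis distance over the
first surface crossing at or beyond the centroid, clamped to [0, 1].

*Direction frames*: the heat-map gradient of a cell attribute is the linear
least-squares fit over the 1-ring (cell + graph neighbours' centroids),
projected into the cell tangent plane; frames are completed by Gram–Schmidt
and `d3 = d1 × d2`, always right-handed orthonormal.  Cells with constant
neighbourhoods or near-parallel inputs (|d1·d2| > 0.99) stay unassigned.

## Growth tensors

For each mother, the linear map `F` (with translation) is fitted by least
squares from ≥3 (2.5D) or ≥4 (3D) matched junction landmarks; 2.5D landmark
pairs are first projected into the mother's t0 tangent plane, making `F`
2×2 in that frame.  The SVD gives the polar decomposition: singular values
are the stretch ratios `kmax ≥ (kmid ≥) kmin`, right singular vectors the
material principal directions of growth.  The estimator reproduces affine
data exactly (landmark residual at numerical precision), which the tests
assert.  Growth along an axis `d` is reported as `|F d|`, the length ratio
of a material fiber initially along `d` — exact for axis-aligned pure
stretches and maximised by the kmax direction.  Growth is per time interval;
no per-hour normalisation is applied by default.

Proliferation composes child→parent maps across intervals and counts
terminal descendants (1 for a non-dividing cell).  Areal extension is the
daughters' summed area (volume) over the mother's.

## Deformation functions

Landmark correspondences are interpolated with the 3D polyharmonic spline
φ(r) = r³ plus a linear polynomial, solved as the standard augmented
symmetric system with landmarks pre-scaled to zero mean and unit RMS radius
for conditioning.  The side conditions Σw = 0, Σw⊗c = 0 hold after every
fit, the far field is affine, and affine data yields zero RBF weights.  A
ridge on the kernel diagonal turns interpolation into smoothing.  Exactly
coplanar landmark sets (the normal case when tracking flat 2.5D tissues by
centroids) make the polynomial block rank-deficient; by default this errors,
and `allow_degenerate=True` solves the system in the minimum-norm sense
instead, which still interpolates the landmarks.  The gradient is analytic:
`F = Σᵢ wᵢ ⊗ 3 rᵢ (x−cᵢ) + A`.

*Subcellular growth* evaluates `F` at every vertex, restricts it to the
local tangent plane (SVD of `F·[e1 e2]`) and reports per-vertex kmax, kmin
and their product as the heat value.  Accuracy is limited by the landmark
density relative to the deformation's variation scale and degrades toward
the boundary of the landmark hull, where the field extrapolates.

*Lineage tracking* iterates: fit the t1→t0 field from verified pairs'
centroids (augmented, once available, by matched junctions of verified
frontier cells — junctions pin the local deformation far better than
centroids); map each unassigned t1 centroid and adopt the t0 cell whose
surface sample set is nearest, gated to within one effective cell radius
(so an off-centre daughter inside a large mother is not stolen by a small
neighbour whose centroid is closer); verify every adoption against the
previously verified region — at least one verified neighbour, all verified
neighbours mapping to the parent or a neighbour of it — and clear failures,
so correct labels grow outward from the seeds.  Three safeguards address
failure modes that plain nearest-centroid adoption with snapshot
verification cannot see, all observed on synthetic data: a smoothing ridge
(default 0.1) plus clearing of pairs whose mapped centroid falls outside the
claimed parent's region (an exact interpolant reproduces a wrong landmark
with zero residual and never self-corrects); a sibling-coherence check (all
claimants of one parent must form a connected patch in t1, as true daughters
share the division wall); and a local size-conservation check (the claimed
t1 material, scaled by the field's local Jacobian determinant, must roughly
reproduce the parent's size; gross excess clears the worst-fitting
claimant).  Only verified assignments are returned; everything else is
listed for manual curation, so false positives are traded for unresolved
cells.  Seed placement matters: the helper `spread_seed_cells` picks
mutually distant seeds (greedy max-min), mirroring how a user places
landmarks; clustered or collinear seeds can mis-anchor the first fit.

*Morphing* interpolates vertex trajectories with centripetal (α = 0.5)
Catmull–Rom splines (linear for two time points; one-sided ghost points at
the ends); knot frames reproduce the inputs exactly and per-vertex signal
interpolates linearly within each interval.

## Division analysis

The actual wall is the PCA plane (3D: normal = smallest-variance axis) or
tangent-plane line (2.5D: direction = largest-variance axis) of the shared
wall vertices.  The mother is reconstituted as the daughters' union with the
shared wall removed (watertight because wall patches match).  Candidates are
`n` directions on a Fibonacci hemisphere lattice (default 1000), all planes
through the volume centroid; each cross-section area is computed from the
oriented intersection segments of the closed surface with the plane (Stokes'
theorem), which sums disjoint polygons of non-convex cells correctly.  In
2.5D, candidates are chords of the cell polygon through its area centroid at
1° steps.  Local minima use the k = 6 nearest axial directions (immediate
neighbours in 2.5D).  The plane–axis angle is `90° − ∠(normal, axis)`,
folded into [0°, 90°]; daughter asymmetry is `|s1−s2|/(s1+s2)`.

## Measures

The 2D shape PCA integrates the area-weighted second moment exactly over
triangle interiors (edge-midpoint quadrature, exact for quadratics), so the
result is triangulation-independent; axis length is `2·√eigenvalue`.  The 3D
shape PCA reports `2·√(3·eigenvalue)` — the solid-box convention, which
reproduces box extents exactly; a solid ellipsoid's extent would need
`2·√(5λ)`.  Ratios (elongation max/mid, flatness mid/min) and the anisotropy
`(max − mid/2 − min/2)/(max + mid + min)` do not depend on this scaling,
absolute lengths do — hence this prominent note.

Contour measures operate on the flattened cell polygon via shapely:
circularity `P²/(4πA)`, lobeyness `P/P_hull`, solidarity `A_hull/A`,
rectangularity `A/A_minrect` (minimum rotated rectangle).  Visibility is
formalised as segment-visibility probability: the fraction of boundary point
pairs (10⁴ Monte-Carlo pairs, fixed seed 0) whose connecting segment stays
inside the polygon; convex polygons short-circuit to exactly 1, and a
relative 1e-9 buffer absorbs grazing-chord floating-point artifacts.

Volumes use the divergence theorem; cell lengths cast rays from the centroid
along ±d and sum the first hits.  Betweenness and current-flow betweenness
come from networkx, unnormalized by default; with inverse-wall weighting,
shortest paths use distance `1/wall_measure` and current flow uses the wall
measure as conductance (wide walls conduct more).  Signal border regions are
vertices within a geodesic border width (default 1 µm) of the cell outline,
averaged with barycentric-lumped area weights.  Tissue curvature fits a full
quadric over all vertices within a radius of the cell centroid in the cell
frame and reports `−(a+c)`, so bumps (convex toward the outward normal) are
positive.  Heat-map smoothing replaces a value by the mean over the closed
1-ring; plateaus of local maxima resolve to the lowest label; bins are
half-open `[lo, hi)` with the last bin closed when a bin count is requested.

## Polarity and fibril orientation

Border polarity samples the border band (cell triangles fully within the
border width of the outline) by area-fair edge-midpoint quadrature, bins the
samples by angle about the cell centroid (default 72 bins), and takes the
resultant of the *mean-centred per-bin means*: uneven sampling density or
incomplete angular coverage then cannot masquerade as polarity — uniform
signal gives exactly zero magnitude.  Direction is the resultant's tangent-
plane direction; magnitude is the normalised resultant length, flagged
undefined below 0.05.  Fibril orientation builds the area-weighted nematic
tensor of normalised per-triangle signal gradients (linear shape functions;
gradients below 1e-12 excluded); the fibril axis is the eigenvector of the
smaller eigenvalue (fibrils run perpendicular to the dominant intensity
gradient) and anisotropy is `(λ₁−λ₂)/(λ₁+λ₂)`.  This nematic formulation is
validated against synthetic fields only.  3D polarity is the area- and
signal-weighted first moment of wall-element positions about the centroid.

## Classification

Thresholds use half-open intervals (a value at a threshold joins the upper
class).  K-means and the SVM standardize features with training-set
statistics — mandatory, because the feature catalogue mixes units (µm, µm²,
dimensionless); the statistics ride along in the model.  The SVM is RBF,
C = 1, γ = 1/n_features, one-vs-one.  Polygon gates replace interactive 2D
cluster selection; gates evaluate in order, first match wins, ungated cells
get class 0.  Radial layer detection 1D-k-means the relative radial
coordinate and numbers layers from the outside in (layer 1 outermost);
surface mode is `floor(distance/thickness) + 1`.  The synthetic organ's
ground-truth layer index counts from the inside out, so comparisons use the
order-reversing bijection.

## Synthetic fixtures: what they emulate, what they do not

Flat/curved epidermes are Lloyd-relaxed (4 iterations) bounded Voronoi
tessellations, lifted onto a paraboloid or sphere cap for curved variants.
Polygon sides are subdivided to ≤2 µm and each cell gets a private inset
ring 0.5 µm inside its outline: real projected membrane signal lands just
inside the owning cell, and the inset ring is where the polarized signal
generator plants it (shared wall vertices are genuinely ambiguous between
neighbours and stay at baseline).  Grid tissues alternate quad diagonals so
the triangulation has no preferred direction — with uniform diagonals, the
gradient statistics of isotropic noise are structurally anisotropic.

Layered organs are concentric equal-thickness shells of wedge cells along a
straight or quadratically bent centerline, watertight with exactly matching
walls; an optional on-axis core cell file supports axis-fitting tests.
Time-lapse pairs map vertices through analytic deformations (affine, smooth
radial growth gradient `x → c + u(1 + g|u|²)`, shear bends) with exact
Jacobians; planted divisions are exact plane cuts through the cell centroid
(perpendicular to the in-plane major axis by default, i.e. near-shortest
walls), with cut vertices propagated into neighbouring triangles so the
triangulation stays conforming — hanging nodes would silently delete
adjacency edges.  The radial growth law is quadratic rather than
|u|-proportional because the latter's Jacobian has a cusp at the centre that
no smooth interpolant can match.  Signal fields: polarized (von-Mises-like
about the planted direction on the private ring), striped (sinusoid
perpendicular to the planted fibril axis, with an aliasing guard at twice
the median edge length), uniform, and multiplicative log-normal noise
(fluorescence-like, σ = 0.4).

All generators are deterministic per seed.  Passing tests on these fixtures
shows the algorithms are correct under their stated models — clean
segmentations, exact correspondences, smooth deformations, noise-free walls.
They do not demonstrate robustness to segmentation errors, non-smooth or
discontinuous growth, signal bleed-through between cells, or imaging
artifacts; on real data the tracking verifier is expected to leave more
cells unresolved rather than mislabel them.

## Problem sizes

The test-suite and reference-value runs use desk-scale fixtures chosen to
exercise every code path with tight tolerances: tissues of 20–200 cells,
organs of ≤128 cells, 500–1000 candidate division planes, 10⁴ Monte-Carlo
visibility pairs, and tracking scenarios of 200 cells with 20% divisions
from 3 seed pairs (validated across 40 generator seeds during development).
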