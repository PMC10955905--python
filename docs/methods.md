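# Methods

This note documents the models, numerical choices and limitations behind
`fenplan`.  Units are millimetres and degrees throughout.

## Coordinate conventions

Centerlines are ordered proximal (cranial) → distal, tangents point distal.
The circumferential angle `phi` of a point about the lumen axis is measured
from a **datum vector** (default patient-anterior, +y) projected into the
cross-sectional plane, clockwise as seen by a proximal observer looking
distally — the surgeon's en-face convention.  `AL = (phi/360)·π·D` uses the
*deployed* diameter, i.e. the surface that is actually cauterized.  `PGD`
increases distally from the proximal fabric edge; row 0 of every mask is
the proximal edge and column 0 the datum generator.  All pixel arithmetic
is half-open and 0-based.

## Graft templates and mask generation

A template is parametric: fabric length, proximal/distal diameters, and
zigzag strut rings (peak-to-peak amplitude, wire width, apices per ring,
ring stations).  Rings are symmetric triangular zigzags with apices fixed
in the angular coordinate; commercial strut patterns vary and the bundled
repository entries are illustrative, not vendor drawings.

Flattening cuts the deployed surface along the datum generator.  Uniform
grafts unroll to a `π·D × length` rectangle; tapered grafts develop the
frustum analytically, each PGD row spanning the local circumference
(diameter linear proximal→distal) with cells beyond it marked forbidden.
Strut pixels are those whose centers lie within `wire/2 + margin` of the
zigzag polyline (exact point-to-segment distances; tapered legs are
subdivided 8× because `AL = θ·C(z)` makes them mildly curved).  Defaults:

* resolution 0.25 mm/px — sub-millimetre deviation reporting needs sub-mm
  pixels; the column count is `round(π·D/res)` and the exact circumference
  is stored separately for AL conversions;
* cautery safety margin 1.0 mm around the wire — the cautery tip cannot
  approach metal closely; configurable.

Fenestration masks rasterize each vessel as a filled disc of its diameter
at its measured (AL, PGD), on a canvas spanning one full AL period (discs
near the seam wrap) and tight in PGD; disc centers are kept real-valued so
the rigid constellation's relative distances are exact.  Overlapping discs
are rejected as anatomically impossible.

## Anatomy measurement

From a binary lumen labelmap, per-axial-slice centroids and
equivalent-area diameters are computed (largest connected component with a
warning if the lumen is disconnected).  The equivalent diameter is
multiplied by `sqrt(|t_z|)` to correct the ellipse-area inflation of
oblique cuts.  Centroids are smoothed by a cubic smoothing spline
(`scipy.interpolate.splprep`; default residual budget `n·(0.2 mm)²`,
appropriate for centroid-level noise) and reparameterized by arclength on a
dense table (relative error ≪ 0.1%).  Station frames combine the projected
datum (primary) with rotation-minimizing double-reflection transport as a
fallback where the tangent is nearly parallel to the datum.

An ostium is measured by projecting its 3D point onto the centerline
(nearest dense station + parabolic refinement), giving `PGD = s_foot −
s_top` and `phi` from the projected datum.  The graft top can be given as
an arclength station or, more robustly, as a 3D landing point projected
onto whichever centerline is in use — arclength origins differ between
extraction runs, landing points do not.  An ostium beyond the fabric length
raises an out-of-coverage error naming the vessel.

Axial voxel slices are used for centroids rather than tangent-normal
resections; for the tube obliquities in scope (≲ 50°) the centroid of an
oblique elliptical cut still lies on the axis, and the diameter correction
above absorbs the area bias.

## Alignment search

The overlap count over all offsets is an FFT cross-correlation of the two
binary masks with circular padding on AL; counts are integers and are
recovered exactly by rounding, so the valid set equals nested-loop brute
force exactly (asserted in tests).  The search step is 1 px in both axes —
the finest grid the masks support.  Fenestrations may not cross the
proximal or distal fabric edge (such offsets are invalid): a hole at the
edge would compromise the seal.

Among valid offsets the planner minimizes `Σ_v δ_v`,
`δ_v = sqrt((dAL + shift_v)² + dPGD²)` with the AL difference taken on the
shorter arc; ties break deterministically (smallest |dPGD|, then |dAL|,
then lexicographic offset).  The relaxation fallback explores per-vessel
posterior AL shifts of 0…3 mm (pixel-quantized) for non-prioritized vessels
only, computed efficiently by rolling per-vessel overlap maps; among
feasible combinations the summed deviation (shifts included) is minimized
with smaller total relaxation preferred on ties, so the rigid solution is
always preferred when it exists.  "Posterior" maps to decreasing `phi` for
the right renal and increasing `phi` for the left renal under the anterior
datum; the sign map is configurable per vessel.  Relaxation is restricted
to the AL direction.  For tapered grafts the AL wrap uses the flattened
canvas period (proximal circumference); rows whose local circumference is
smaller carry forbidden padding, so designs cannot cross the seam there.

## Graft mesh, flattening, texture mapping

The deployed diameter is the mean lumen diameter over the proximal landing
zone — the first 10% of graft length — capped at the nominal fabric
diameter (an oversized fabric conforms to the wall; fabric cannot exceed
its manufactured size).  Tapered grafts interpolate linearly to a distal
deployed diameter sized analogously from the distal 10%.  The cap-at-nominal
rule is an engineering choice where oversizing interacts with the
landing-zone mean; it errs on the side of the manufactured geometry.

The tube mesh places rings of `n_circ` vertices (default 96) at `n_axial`
stations (default 1 mm spacing) using the projected-datum frames, so the
longitudinal seam lies exactly on the `phi = 0` generator and mesh AL
coincides with mask AL; the seam column is duplicated, making the mesh a
topological disk (Euler characteristic 1).  Faces are oriented outward by a
majority vote against the radial direction.  A warning reports stations
where the centerline curvature radius drops below the graft radius (the
loft locally self-intersects).

Flattening solves the discrete Laplace equation with cotangent weights
`w_ij = (cot α_ij + cot β_ij)/2` (single cotangent on boundary edges),
assembled as the positive semi-definite `L = D − W` with zero row sums.
Boundary vertices are pinned to the rectangle — proximal ring on top,
distal on bottom, seam copies left/right — spaced chord-length-
proportionally (reduces distortion on tapered grafts), and the interior
solves `L_II v_I = −L_IB v_B` per coordinate by sparse LU (well within
budget up to ~10⁵ vertices).  Negative cotangent weights from obtuse
triangles are kept as-is: the loft grids are near-structured and the
resulting maps are observed fold-free (flipped faces are detected via
signed areas and reported).  A uniform-weight (Tutte) variant exists for
comparison; it is also bijective on these disks but measurably more
angle-distorting on curved tubes (quasi-conformal error, asserted in
tests).

Texture mapping inverts the triangle edge matrix `T` to get barycentric
coordinates `λ = T⁻¹(p − r₃)`, `λ₁+λ₂+λ₃ = 1`, and applies the same weights
to the triangle's 3D vertices.  Point-in-triangle lookup uses a uniform
grid over uv-space bounding boxes with an exhaustive fallback, and snaps
across numerical gaps below 10⁻⁶ mm.  The deviation `δ` between two surface
points is the Euclidean norm in the developed plane with the AL difference
wrapped to the shorter arc; the plain (unwrapped) form would differ only
for near-antipodal placements.

## Synthetic anatomy

Cases emulate the planning inputs with full ground truth: a tube of radius
12 mm (24 mm visceral aorta) swept along a straight line, a planar arc
(R = 150 mm) or a tortuous 3D curve (6 mm lateral sinusoids, wavelengths
100/70 mm; minimum curvature radius ≈ 21 mm, above the graft radius), cut
flat at the axial ends like a cropped segmentation, and voxelized at 0.7 mm
isotropic by stamping balls along the densely sampled curve (voxelization
error ≤ 1 voxel).  The modeled segment is 200 mm with the graft top at
station 40, keeping the landing zone clear of the partial-slice artifacts
near the cut ends.

Default vessels (synthetic conventions, chosen once): CA (φ 355°, PGD
21 mm, ⌀7, prioritized), SMA (10°, 30 mm, ⌀7, prioritized), RRA (265°,
54 mm, ⌀6), LRA (95°, 57 mm, ⌀6), with per-case jitter of ±8° and ±1.2 mm;
ostium measurement noise is isotropic Gaussian (0–0.5 mm).  Stored ground
truth is the analytic (φ, station) of the *noisy* point, so recovery error
isolates pipeline error from injected noise.  The default device
(`thoracic-straight-26`: 116 mm, 4 rings at 10/42/74/106 mm, amplitude
9 mm, wire 0.4 mm, 8 apices) gives fabric windows that the default vessel
constellation falls into — mirroring the clinical premise that the surgeon
selects a graft admitting a valid fit.  Adversarial constructions
(`blocked_renal`, `no_fit`, `edge_fenestration`) carve or fill masks so the
named outcome is guaranteed, and verify it internally by brute force.

What passing the recovery study shows — and does not show: the pipeline's
discretization, measurement and mapping errors are sub-millimetre on
idealized circular-lumen anatomy.  Real CT data adds segmentation error,
non-circular lumens, thrombus/calcification and aortic deformation by the
device, none of which are modeled; clinical deviations would be larger.

## Problem sizes and runtimes

Defaults used by the test suite and acceptance script: masks at
0.25 mm/px (graft ≈ 464×303 px), meshes ≈ 11k vertices, labelmaps ≈ 2·10⁶
voxels.  One full planning run takes ~1.5 s on a single core; the recovery
study defaults to 40 cases in the acceptance script (the test suite runs
100) — sizes chosen to keep a laptop-scale run comfortable while leaving
the statistics stable.

## Known limitations

* Vendor-exact strut geometries and regulatory sizing charts are out of
  scope; templates are illustrative.
* The tapered-graft search approximates rotation by uniform mm shifts on
  the developed annulus; rows far from the proximal edge rotate through a
  slightly different angle per mm than the proximal row.
* No mechanics: graft deployment is purely geometric (wall-conforming
  cylinder/frustum); device–host interaction is not modeled.
* Segmentation itself is upstream: the package consumes a finished lumen
  labelmap or centerline.
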