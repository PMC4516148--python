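# Methods

`fibroid3d` implements a surface-rendering (SR) workflow for surgical
planning of uterine fibroids from sagittal T2-weighted pelvic MR volumes:
semi-automatic multi-structure segmentation from operator-traced key-slice
contours, 3D mesh extraction and smoothing, per-lesion characterization,
and the evaluation arithmetic of a two-observer reader study.  This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic tests do and do not establish.

## Grid and coordinate contract

Volumes and label maps are scalar grids indexed `(i, j, k)` with per-axis
spacing in mm; the world coordinate of a voxel center is
`origin + index * spacing`.  The third index runs along the slice (sagittal
stack) direction.  Direction cosines present in NIfTI/DICOM headers are
normalized to identity with a logged warning: every operation here is
invariant to patient orientation, and one fixed convention keeps all
geometry testable.  Label codes are 0 background, 1 uterine body,
2 endometrium, 3 fibroid; where structures overlap, fibroid takes priority
over endometrium over body, so each lesion is a distinct solid.

## Semi-automatic segmentation

The operator traces each structure as closed polygons (counterclockwise,
simple, at least 3 vertices) on sparse key slices.  Processing stages:

1. **Rasterization.**  A voxel belongs to a contour's interior iff its
   center lies inside the polygon (even-odd rule); centers exactly on the
   boundary count as interior.  Implemented with matplotlib's point-in-path
   test, taking the union of a positive and a negative boundary nudge so
   the tie rule holds for either winding.  Multiple contours of one
   structure on one slice (multi-part cross-sections) are unioned.
2. **Shape-based interpolation.**  For each pair of consecutive key slices
   the signed Euclidean distance fields (negative inside, positive
   outside, mm, anisotropy-aware) of the two masks are blended linearly
   with slice position and thresholded at zero.  This deforms one contour
   smoothly into the next and is exact for identical endpoints.  When one
   endpoint is empty the missing field is a uniformly positive constant
   scaled to `depth / (gap + 1)`, where `depth` is the occupied mask's
   maximum interior distance: the structure then tapers strictly
   monotonically and is still present on every intermediate slice.  A
   caveat inherent to distance-field interpolation: cross-sections that do
   not overlap in-plane taper away and reappear rather than translating.
3. **Empty key slices.**  A multi-part structure (several fibroids) can
   vanish on slices between two of its parts.  Such slices are recorded as
   *inspected and empty* in the key-slice set (and in the contour JSON);
   propagation then tapers against an empty mask instead of bridging the
   gap with invented tissue.  With dense tracing (every slice) the
   reconstruction is voxel-exact by construction.
4. **Cross-plane correction.**  The validation pass that a human would do
   from orthogonal views is realized as 3D geometric consistency: body and
   endometrium keep only their largest 26-connected component; fibroid
   components below `min_fibroid_voxels` (default 5) are discarded;
   endometrium voxels outside the body's filled interior are removed.  The
   output is always a voxelwise subset of the input — correction removes
   false positives, never adds.

## Surface rendering

**Mesh extraction** walks every 2×2×2 voxel cube and triangulates the
isosurface from a 256-entry lookup table generated at import from the
Freudenthal/Kuhn decomposition of the cube into six tetrahedra sharing the
main diagonal.  That decomposition tiles space consistently (adjacent
cubes agree on every face diagonal), each tetrahedron is free of the
face-ambiguous cases that make naive cube tables leak, and the table is
complementary-symmetric by construction.  Grids are padded with one empty
layer, so every extracted surface is watertight (each edge shared by
exactly two faces) for any input; triangles are wound outward.  Vertices
are placed by linear interpolation along the edges of the tetrahedral
lattice — cube edges plus face and body diagonals; on a {0,1} mask at the
default isovalue 0.5 every vertex is an edge midpoint.  Vertex welding
uses exact lattice-edge identities (no coordinate rounding).

**Smoothing** is Taubin's two-step shrink/inflate filter with a
uniform-weight Laplacian: λ = 0.5, μ = −0.53, 40 iterations by default.
It preserves vertex count and topology exactly and `iterations=0` is the
identity.  Raw midpoint meshes of voxelized anatomy are faceted and
overestimate surface area substantially (about +9% for a 10 mm sphere even
with reference cube-table extractors, more for the denser tetrahedral
mesh); the tetrahedral lattice carries roughly twice the triangle density
of cube-based marching cubes, so diffusion smoothing needs more iterations
to reach the same smoothing scale — hence 40 rather than the 20 common
for cube-table meshes.  Measured across sphere radii 5–12 mm at 1 mm
spacing, the defaults give surface area within 3.3% and enclosed volume
within 1.2% of the analytic values, with volume drift below 2% relative to
the raw mesh.

**Scenes** contain one smoothed mesh per structure — one per 26-connected
component for fibroids — with the fixed clinical color map (body red,
endometrium yellow, fibroids green).  Body and endometrium meshes are
extracted from hole-filled masks, since the label holes carved by nested
structures are anatomy, not cavities.  Export formats: ASCII PLY with
per-vertex color, STL (geometry only), OBJ with a companion MTL carrying
per-structure materials.

## Fibroid characterization

Lesions are 26-connected components of the fibroid label (diagonal contact
does not split a lesion) of at least 5 voxels.  Measurements use voxel
centers in mm with anisotropic spacing: volume is voxel count × voxel
volume; the maximum diameter is the largest pairwise distance between
voxel centers, computed on the convex-hull vertices (the diameter of a
finite set equals the diameter of its hull) with a brute-force fallback
for small or degenerate components.

Anatomical typing, evaluated in priority order with configurable margins:
*submucosal* if the lesion's one-voxel dilation intersects the
endometrium; else *subserosal* if more than 10% of its voxels lie outside
the filled body label; else *intramural*.  The removal recommendation
(all submucosal and subserosal lesions; intramural lesions at or above a
25 mm diameter threshold) and the procedure suggestion (only submucosal →
TCR; any subserosal among removals → LAM; otherwise → TLM; abdominal
myomectomy never auto-suggested) are explicit heuristics chosen to be
consistent with the packaged gold-standard table's type-pattern → procedure
mapping.  They exercise the planning report end to end and are **not**
clinical decision rules.

## Synthetic phantom

The phantom emulates a sagittal T2-like pelvic volume with analytic ground
truth: an axis-aligned ellipsoidal uterine body of intermediate intensity
(default semi-axes 40×25×30 mm, intensity 110), a nested hyperintense
endometrial cavity (16×6×10 mm, 230), hypointense spherical fibroids (45),
background 20, and additive seeded Gaussian noise (σ = 8).  The default
grid is 96×96×48 voxels at 1.5×1.5×2 mm — a desk-scale crop of a clinical
stack that keeps the 2 mm section thickness along the slice axis; tests
that need sub-voxel geometric precision use a 1 mm isotropic variant.  The
default lesion load is three intramural fibroids plus one subserosal
(radii 5–9 mm), mirroring the intramural-dominant composition of clinical
fibroid series.  Identical configurations (including seed) produce
bit-identical output.

Random conforming lesion sets are drawn by rejection sampling: candidate
centers are proposed along random rays and accepted only if the *true*
Euclidean clearances to the serosal and cavity surfaces satisfy the
intended type with a 3 mm margin (intramural: 3 mm clear of both;
subserosal: protruding by 0.5–0.8 radii, hence well over the 10%
exterior-fraction threshold; submucosal: penetrating the cavity by at
least 3 mm).  Point-to-ellipsoid distance uses the standard largest-root
parametrization solved by bisection; along-ray clearances are insufficient
here because the nearest point of an elongated ellipsoid is generally off
the ray.

Simulated key-slice tracing extracts sub-voxel contours of the ground
truth (the 0.5 iso-contour of each slice mask, with body/endometrium
cross-sections hole-filled as an operator would outline them) on every
`slice_step`-th occupied slice plus the last.  Optional jitter adds
smooth, seeded radial noise; the jitter parameter is the approximate peak
(two-sigma) boundary displacement in mm.  Radial perturbation keeps the
star-shaped phantom cross-sections simple.

**What the phantom does not model:** MR physics (Rician noise, coil
profiles, partial-volume mixing), irregular and degenerating lesion
shapes, peristalsis and motion artifacts, and operator errors beyond
smooth boundary displacement.  Passing phantom tests therefore establishes
the geometric correctness of the pipeline, not clinical segmentation
accuracy on patient data.

## Reader-study arithmetic

The packaged JSON fixture (sha256-checksummed at load) transcribes the
10-case study: the gold-standard plan (procedure among AM/LAM/TLM/TCR and
removal counts by type; 25 removals in total, 22 intramural, 2 subserosal,
1 submucosal), both observers' per-case calls from sagittal and SR
viewing, and summary statistics of interpretation time and a 4-point
difficulty score.  Accuracy is exact concordance with the gold standard.
Group comparisons use the unpaired Student t test computed from summary
statistics (pooled variance, df = n₁+n₂−2); the pooled form reproduces the
published two-decimal p values (0.53 and 0.28 for difficulty) from the
rounded summaries, which is why it is the default; Welch is available.
Segmentation quality metrics are Dice overlap and the symmetric Hausdorff
distance between voxel-center sets, computed in mm via anisotropic
distance transforms; two empty masks compare as identical, one empty mask
gives infinite Hausdorff distance.

## Problem sizes and determinism

Test and acceptance runs use the 96×96×48 anisotropic phantom, a
110×80×90 isotropic phantom for sub-voxel checks, 21-voxel-radius spheres
for mesh accuracy, 50 random 7³ masks for the watertightness property, 20
random ellipsoids for the cross-implementation volume check, and five
seeded phantoms (30 lesions) for type recovery.  All randomness flows
through explicit seeds; the CLI funnels every stochastic step through one
`--seed`, and two identical invocations produce byte-identical artifacts
(uncompressed NIfTI carries no timestamps).

## Known limitations

- Interpolation is performed along the native slice axis only; the
  cross-plane correction is geometric (connected components and nesting),
  with no intensity information.
- Distance-field interpolation cannot translate non-overlapping
  cross-sections between key slices; sparse tracing of small, oblique
  lesions benefits from a finer slice step.
- The subserosal/submucosal margins assume roughly convex lesions;
  pedunculated fibroids (stalked, largely exterior) are classified
  subserosal but their stalk geometry is not modeled.
- The removal and procedure rules are reporting surrogates; no clinical
  validity is claimed.
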