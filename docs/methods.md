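# Methods

This note documents the models, numerical choices and limitations behind
`spinereg`, in the spirit of a methods appendix: what exactly is
computed, which knobs matter, and what the synthetic experiments do and
do not demonstrate.

## Coordinate conventions

World frame: right-handed, millimetres; +z cranial, +y anterior, +x
patient-left. Angles at API boundaries are degrees; sagittal rotations
are about the x axis; lordotic (extension) angles are positive.
Detector coordinates are millimetres with the origin at the principal
point; u is patient-left (frontal) / patient-anterior (sagittal), v is
cranial. Image rasters put row 0 at the most cranial row; the single
place where the y-down raster meets the v-up geometry is
`RadiographImage.mm_to_rowcol`.

## Biplanar environment

Each view is a point source plus a planar detector spanned by
orthonormal axes. Acquisition geometry is site configuration, not
physics, so the defaults are explicit and overridable in the JSON
calibration: source-to-image distance (SID) 1800 mm, source-to-object
distance (SOD) 1400 mm, detector 420 x 520 mm at 0.5 mm/px, frontal beam
along −y, sagittal along −x, detectors orthogonal. An orthographic mode
(source at infinity) exists for analytic checks. `place_environment`
translates sources and detectors rigidly together — the once-per-case
adjustment that puts repeated registrations into one shared frame.

## Silhouettes

The silhouette of a posed mesh is computed exactly: the mesh is split
once into connected components (cached, with convexity flags); a convex
component contributes the convex hull of its projected vertices — the
exact central-projection silhouette of a convex solid — and a
non-convex component contributes the union of its projected triangles
(shapely). The union's outer ring, densified at the requested
`resolution`, is the silhouette contour. Rasterisation appears only in
radiograph rendering, never in the silhouette itself, so `resolution`
controls boundary sampling density, not accuracy. When a projection
splits into several disjoint footprints the largest is used.

## Contours and gradient snapping

Contours live in detector millimetres. Manual tracing is emulated two
ways: sub-ranges of an exact silhouette (`contour_from_silhouette`,
e.g. corpus-dominant 40% selections), and gradient attraction
(`snap_contour`): a Catmull–Rom spline (or polyline) through control
points is densified and every sample moves along its local normal to the
maximum Gaussian-derivative gradient magnitude (sigma 1 px) within the
search radius, provided that maximum exceeds 10% of the image-wide
maximum — otherwise the sample stays, so the tool degrades to plain
splines in flat regions. The attraction model of interactive clinical
tools is proprietary; this ridge-snapping is an explicit, documented
stand-in.

## Registration

Per vertebra, 6 degrees of freedom, both views simultaneously:

1. **Initialisation** (surrogate for manual alignment): translation by
   least squares so the projected silhouette centroid meets the target
   centroid in both views (the four ray constraints over-determine the
   three unknowns); in-plane rotation per view from 2D second-moment
   principal axes, composed about the object centroid. A warning is
   raised when the target's principal axes are degenerate within 5%
   (orientation ambiguous, e.g. near-circular footprints).
2. **Refinement** (iterative closest point on contours): densified
   target samples are matched to nearest points on the current
   silhouette outline (pairs beyond `correspondence_cap`, default
   10 mm, are discarded; an empty view is an error naming the view);
   each matched silhouette point is anchored to the mesh vertex that
   projects closest to it; a Levenberg–Marquardt step
   (`scipy.optimize.least_squares`) on an axis-angle + translation
   increment about the object centroid minimises the point-to-tangent
   residuals, weighted per view (default 1:1). The true cost — pooled
   squared target-to-silhouette distance — is re-evaluated after each
   step; increases trigger step halving (up to 5 times), so the cost is
   non-increasing by construction. Convergence: change in pooled RMS
   below `convergence_tol` (0.01 mm) or `max_iterations` (60).

Point-to-tangent rather than point-to-point residuals let partial
contours slide along the silhouette, which is what makes 40% corpus-like
selections register to sub-degree accuracy. The vertex-anchor
discretisation (~4 mm vertex spacing) is annealed away by the normal
projection: recovered poses on exact targets are accurate to ~0.05
degrees / 0.02 mm, far below the anchor spacing.

Both views are optimised simultaneously (pooled); per-view residuals are
reported separately so an inconsistent frontal/sagittal pair (non-
simultaneous acquisition) is visible rather than silently averaged.

The modelling interface is `VertebraRegistration(mesh, targets, env,
options).fit(init)` returning a `RegistrationResult` (pose, pooled and
per-view RMS residuals, iteration history, converged flag, `summary()`);
`register_spine` runs six of these independently — the method is
strictly per-vertebra rigid — and returns results in anatomical order.

## Synthetic spines

A vertebra is a union of closed convex primitives: a vertebral body
(convex hull of two rounded-rectangle endplate rings, tilted to the
wedge angle, plus a bulged mid ring — a barrel shape with exactly planar
endplates), two pedicle boxes, two transverse-process cylinders, a
caudally sloped spinous-process box, and a midline bridge joining body
and spinous process so the midsagittal cut of each vertebra is one
connected region. Primitives overlap slightly (<1% of volume) rather
than being boolean-unioned; every component is watertight and the
voxeliser/sectioner union the per-component polygons so overlap is never
double-counted. Meshes are mirror-symmetric about their local sagittal
plane and deterministic per parameter set; the seed drives only the
barrel bulge. Anatomical realism is deliberately limited to what the
method exercises: projected edges, planar endplates, posterior elements
that occlude and clutter the silhouette.

Stacking: intersegmental angles are defined endplate-based (caudal of
upper vs cranial of lower), so vertebra tilts are chained with
half-wedge corrections and disc gaps along the endplate normals. The
assembled model records its implied ground truth: the plan's five
segment angles, and LL = sum of segment angles + sum of L1–L5 body
wedges (with wedge-free shapes, LL is exactly the plan sum). Facing
endplates diverging faster than the disc height allows raise an
interpenetration error (analytic test on the plate dihedral; posterior
elements are not checked).

Study conditions (the generator defaults used by the validation
experiment): supine lordosis ~ N(38°, 6°) clipped to [20°, 55°], split
over segments by the physiological fractions (0.08, 0.13, 0.19, 0.26,
0.34) plus ±1.5° jitter; standing-minus-supine lordosis ~ N(5.6°, 1.5°)
clipped to [1°, 9.5°] — 5.6° being the typical supine-to-standing
increase this class of cohort shows — distributed the same way, so no
vertebra moves more than ~10°/10 mm between positions; lumbar wedges
±3°, sacral wedge 12°; disc heights 9.5–12.5 mm; body sizes ±8%.

## Midsagittal sections and angles

The midsagittal plane has the left-right axis as normal and passes
through the midpoint of the extreme left/right vertex coordinates of the
whole model. Sections are exact mesh-plane cross-section polygons
(convex components again by hull) rasterised at 0.3 mm. The 0.3 mm
default matters: a binary raster expresses a sub-degree endplate slope
as flat runs joined by single-pixel steps, and at 0.5 mm that
quantisation alone costs up to ~0.5°; at 0.3 mm the section path agrees
with the exact mesh path to ~0.25° worst-case.

Endplate detection is an explicit geometric rule standing in for a human
reader. Mesh path: candidate vertices with outward normals within 30° of
the vertebra's own cranio-caudal axis, restricted to the densest 3 mm
height window (which rejects stray edge vertices of the posterior
elements), then a trimmed least-squares line fit in the sagittal plane.
Section path: component boundaries are traced on Gaussian-smoothed
masks (sigma 1.2 px — raw binary marching squares yields staircase
normals), candidates taken in a wider 40° cone, and the endplate found
as the dominant collinear boundary run by a deterministic consensus
search; the final fit keeps every candidate within 0.7 mm of the winning
line (including quantisation-step points, which an alignment filter
would wrongly drop) and trims the rounded run ends. Components are
assigned to L1…S cranial-to-caudal; anything other than six components
is an error.

`compute_angles` on a model measures in the model's intrinsic sagittal
basis (mean vertebra rotation), which makes the angle differences
exactly invariant under whole-body motion; the standalone
`endplate_line` reports against the world transverse plane as its
contract states. Intersegmental angle i = caudal-of-upper minus
cranial-of-lower endplate angle; LL = cranial L1 minus cranial S1.

## Metrics

* **Voxelisation**: slice-by-slice along z; per slice the closed
  components' cross-sections are unioned and voxel centres tested with
  vectorised point-in-polygon. Grids align to integer multiples of the
  voxel size (0.6 mm default, the CT reconstruction grid), so
  co-translated mesh and origin reproduce identical masks. Voxel centres
  exactly on a face are a knife-edge and not guaranteed either way.
* **Dice** is computed strictly on matching grids; 0/0 (two empty
  masks) is an error, as is a non-watertight input to the voxeliser.
* **Mean surface distance** is the one-sided area-weighted mean of
  *exact* point-to-triangle distances from stratified per-triangle
  samples (default 10 /mm²; the batch experiment uses 2 /mm², which
  changes estimates by <0.5%). Candidate triangles are pruned by a
  KD-tree with a nearest-vertex upper bound plus circumradius margin —
  a conservative bound, so the pruning is exact, validated against an
  exhaustive all-triangles oracle. The symmetric variant takes the max
  of the two one-sided means; `hausdorff_max` takes the symmetrised
  maximum over samples plus vertices (a sampling lower bound of the true
  supremum).
* **ICC** is implemented from the two-way ANOVA mean squares:
  ICC(A,1) and ICC(A,k) (absolute agreement) with the F-based 95%
  confidence limits; degenerate inputs (missing cells, zero between-case
  variance, fewer than 5 cases) are errors. The implementation is
  cross-checked in the tests against an independent reference
  implementation and the classic four-judges worked example.

## Validation experiment

One case = one supine/standing pose pair of identical meshes. Standing
silhouettes (full, or 40% partial, or gradient-snapped on a rendered
radiograph) are the refinement targets; the supine model is registered,
twice, with per-run random perturbations (±2°, ±2 mm) of the coarse
initial poses — emulating two independent manual initialisations. The
coarse initialisation always works from the full silhouette, mirroring
the workflow it stands in for: the manual alignment step sees the whole
projection, and only the automatic step is restricted to the selected
edges (a partial contour's centroid and principal axes are not those of
the silhouette, so initialising from partial contours alone would not
emulate any step of the workflow); sections are measured
and compared against the recorded plan; registered vertebrae are
compared to their ground-truth standing poses (mean surface distance,
Dice at 0.6 mm) and across the two runs (pair distances, per-angle
ICCs). All randomness flows from named seeds spawned off the config
seed; a run is byte-reproducible. Problem sizes: 20 cases x 6 vertebrae
x 2 runs, silhouette sampling 0.5 mm, section raster 0.3 mm, distance
sampling 2 /mm² — a full run takes roughly 5–6 minutes on one CPU.

## What the synthetic tests do and do not show

The generator emulates geometry, projection and partial/noisy contour
selection, so the experiments validate the registration optimiser, the
measurement chain and the agreement statistics end-to-end against known
ground truth. They do not emulate: radiographic attenuation (no DRR —
silhouettes only), segmentation error (meshes are identical between
supine and standing, unlike two investigators' segmentations),
inter-view posture change during non-simultaneous acquisition, coronal
or axial deformity (pose pairs differ by sagittal rotations only,
matching a cohort without severe coronal malalignment), or the
variability of human contouring beyond the partial/snapped variants.
Accuracy numbers from the synthetic batch are therefore best-case
bounds: they show the pipeline's own error is far below the clinical
accuracy envelope, not that real-data error will be.

## Known limitations

* Per-vertebra rigid only; no deformable or affine registration.
* Initialisation relies on second moments: near-symmetric silhouettes
  can flip 180° in-plane (a warning is raised; the refinement residual
  exposes a wrong basin — never a silent success).
* The voxeliser requires closed components; arbitrary triangle soups
  are rejected rather than healed.
* `hausdorff_max` is sampling-based and thus a lower bound of the true
  supremum; density is the caller's accuracy control.
* DICOM calibration parsing is out of scope; geometry comes from JSON.
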