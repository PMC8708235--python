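# Methods

## Coordinate model

Four right-handed-up-to-convention frames tie the rig together. The object
coordinate system (OCS) has its origin on the floor, Y along the rotation
axis of the arm, Z toward the subject's front. A device (scanner or camera)
mounted at height h and radius r on the arm at angle α relates to the OCS by
a translation followed by a rotation about Y:

    p_OCS = R_y(α) · (p_DCS + [0, h, −r]ᵀ)

The camera transform inverts this and adds a 3×3 calibration matrix Q and
offset vector T that absorb mounting imperfections:

    p_CCS = Q · (R_y(−α) · p_OCS − [0, h, −r]ᵀ) + T

Projection is an ideal pinhole, [x_t, y_t]ᵀ = [x, y]ᵀ/(d·z) + principal
point; the constant d (image units per meter per meter of depth) encodes
focal length and sensor resolution together. No lens distortion is modeled.
Image coordinates are 0-based pixels, origin at the top-left pixel center,
x right, y down. Angles are degrees at config boundaries and radians
internally; lengths are meters; ortho scale is given in px/mm and converted.

The virtual (orthographic) frame at a surface point V with outward unit
normal n stacks as rows: Z = −n; X = [g_zz, 0, −g_zx]/√(g_zz²+g_zx²)
(horizontal); Y = X × Z. G is orthonormal with det G = −1 — the frame is
deliberately left-handed so that patch y runs down like image y. When n is
within ~1e-6 of ±Y the horizontal direction is undefined and X falls back to
(1, 0, 0), a deterministic choice among the equally valid horizontals.
The triangle normal is the normalized cross product of two edges;
normalization (rather than the |B−A||C−A| denominator, which is only unit
for right-angle corners) is required for G to be orthonormal.

## Model-building pipeline

Per scan: crop to a closed subject box (boundary points kept), voxel-grid
downsample (floor-convention buckets against the global origin, centroid per
occupied voxel; default 1 cm), estimate normals as the smallest-eigenvalue
eigenvector of the k-NN covariance (k = 30), oriented toward the scanner.

Registration: scans of one arm stop are merged; consecutive stops are
registered around the full turn, including the closing pair. ICP supports
two metrics. `point_to_point` (closed-form Kabsch step on nearest-neighbor
pairs) is the textbook variant, but on smooth, discretely sampled surfaces
it stalls at roughly half the sample spacing and cannot observe the
tangential sliding modes of a near-cylindrical body, so the pipeline default
is `point_to_plane`: a damped linearized 6×6 solve against the target's
local tangent planes. Two safeguards matter on this geometry: light
Tikhonov damping (1e-4 of the mean diagonal) keeps the nearly unconstrained
vertical mode from exploding on noise, and correspondences whose normals
disagree by more than 25° are rejected, which removes the biased pairings
that partial overlap produces near coverage boundaries. Correspondence
distance follows a coarse-to-fine schedule (8 → 4 → 2 cm) because mount
errors of a few degrees displace points far beyond the final radius.

Loop closure is a pose graph over the ring of pairwise edges: absolute poses
(first stop fixed) parameterized as rotation vector + translation, residual
per edge the log of the edge mismatch, solved by Levenberg–Marquardt least
squares. Corrected edges compose to the identity exactly. A global
refinement then re-registers every stop (including the first) against the
union of the others and re-gauges to the first stop; this averages the
~1–2 mm per-edge biases the pairwise ring leaves behind and cancels the
common-mode drift of the consensus frame. Four rounds at 1.2 cm
correspondence distance are the default.

Cleanup: statistical outlier removal discards point i when its mean k-NN
distance exceeds μ + 1.0·σ of those means over the cloud (the 1.0 reflects
a one-standard-deviation threshold; a second pass may remove more points —
the operation is not idempotent). MLS smoothing projects each point onto a
local weighted quadratic fit (neighborhood radius 5 cm, Gaussian weight with
bandwidth radius/2), collapsing double-wall artifacts and depth-noise
waviness; isolated points pass through.

Surface reconstruction estimates a signed distance field from the oriented
points — at a query point, the inverse-distance-weighted mean of
n_i · (x − p_i) over the 10 nearest oriented points — samples it on a
`2^depth` per-axis grid over the padded bounding box (depth 7 default,
keeping octree-depth semantics: each +1 doubles resolution per axis), and
polygonizes the zero level with marching cubes. The outermost grid layer is
forced positive so coverage gaps (e.g. the underside of the lowest scanned
region) close instead of leaving boundary holes. The mesh is cleaned,
restricted to its largest connected component, and wound outward.

## Rendering, texturing, picking

The rasterizer is deterministic scan conversion: a pixel belongs to a
triangle when its center lies inside the projected triangle (boundary
inclusive); overlaps resolve nearest-first with a strict depth test, ties to
the lower triangle id because triangles are processed in ascending order.
Back faces (normal pointing away from the projection center) are never
rasterized. Barycentric weights are perspective-correct by default
(screen-space linear available for comparison experiments). Triangle ids
are encoded in 24-bit RGB as id = R + 256·G + 65536·B with 0 reserved for
background; barycentric buffers export as three 16-bit grayscale PNGs, since
8-bit quantization (≈ 4e-3 in a weight) would dominate the picking error
budget while 16-bit keeps it below 1e-4.

Visibility of a triangle in a view is decided by sampling the mosaic at its
projected centroid and the three edge midpoints pulled 25% toward the
centroid; the inset keeps the rounded samples inside their own triangle
instead of leaking into the neighbor across the shared edge. All four
samples must show the triangle's own id. Triangles projecting thinner than
a pixel fail naturally and are treated as not visible in that view — a
conservative choice. Texture assignment takes, per triangle, the visible
view with the largest projected area (the closest, most frontal camera, i.e.
best effective resolution); ties break to the lowest view id, making the
result independent of view-list order. Texture coordinates are stored per
corner because adjacent triangles may use different views.

Picking decodes the triangle id at a pixel from the index buffer, reads the
barycentric weights, and forms V as the weighted vertex combination;
reprojecting V lands within half a pixel of the picked pixel center.

## Orthorectification

The patch is resampled by inverse mapping on the tangent plane at V (a local
planar approximation, taken literally: curvature error grows quadratically
with patch half-extent, so patches default to 40 mm and the marker study
uses 56 mm on a 140 mm-radius phantom, where the sagitta stays under 1 mm).
The whole patch comes from the single view anchored at the picked triangle,
even if neighboring triangles were assigned other views; the source view is
recorded in the patch sidecar. Samples falling off the source image, behind
the camera, or on mosaic background (past the silhouette) are masked invalid
rather than extrapolated. Interpolation is bilinear (bicubic behind a
flag).

## Marker metrics

Segmentation thresholds the patch at the maximum-between-class-variance
split of its histogram, computed by an explicit 256-bin scan whose ties
(plateaus across empty histogram gaps) resolve to the middle of the plateau
— this keeps exact two-level images from landing the threshold on a
populated bin edge. The mask is the largest dark component within 3 px of
the patch center, holes filled. Ellipse axes come from second central
moments (a = 2√λ₁, b = 2√λ₂), a closed-form fit with no iterative failure
modes; area is pixel count / scale²; tag shear is the deviation from 90° of
the angle between the two tag edges meeting at the first corner, with
corners taken from the generator's ground truth projected analytically
(a corner detector is out of scope). A 2 cm-diameter disk has area
π·1² ≈ 3.14 cm²; that geometric truth is the reference for area recovery.

## Synthetic data: what it does and does not emulate

The phantom torso is an elliptic cylinder (default semi-axes 16 × 11 cm,
spanning 0.5–1.5 m) capped by hemi-ellipsoids; optional vertical arm
cylinders create occlusions. All cylinders are developable, so the
(arc length, height) chart is isometric and marker disks painted in chart
coordinates have exactly their nominal geodesic size — the texture is an
analytic function of the surface point, never a resampled raster, removing
texture interpolation from the error budget. Markers are 2 cm black disks
in ~3.2 cm light rectangular tags on skin-toned albedo.

The virtual rig mirrors a prototype: by default 4 camera heights and 3
scanner heights on the arm, 8 stops of 45°. Camera intrinsics default to
d = 2.5e-4 with a 1280×960 (studies: 1920×1080) frame, making a 2 cm marker
span ≥ 100 px at typical distance; scanner intrinsics default to 424×240
with an ~87° horizontal field of view, i.e. half the native resolution of a
RealSense-class depth camera. Depth scans are rendered through the same
pinhole geometry as the photographs (one shared geometry core), perturbed by
Gaussian noise of σ = 2 mm along each viewing ray, with optional dropout and
background clutter. Pose errors are injected per arm stop (all devices of a
stop share the arm's error), rotation ≤ bound about a uniform axis,
translation ≤ bound, first stop exact as the reference gauge.

Not emulated: photorealistic skin appearance, lens distortion, subject
motion during the turn, and non-rigid deformation. Passing tests therefore
validate the geometry and the algorithms, not robustness to those real-world
effects; on real scans the dominant error sources would be subject motion
and calibration residuals.

## Validation experiments and problem sizes

The experiment suite (`orthoskin.study`, driven by `scripts/acceptance.py`
and the acceptance tests) uses these sizes, chosen to exercise the full
pipeline at desk scale:

* Marker study: 12 markers (2 rings × 6 tilts {0, 15, 30, 45, 55, 60}°,
  rings at different camera radii/offsets for distance variation),
  1920×1080 photographs, patches 280×280 px at 5 px/mm. Mean rectified
  axis ratio ≈ 1.01 vs ≈ 1.39 in the raw images; rectified area within 1%
  of π cm² with relative spread ≈ 0.015 vs ≈ 0.24 uncorrected.
* Homography oracle: 200×200 patch of a planar face at 60°, closed-form
  plane-to-image homography assembled independently of the resampling chain;
  agreement is at machine precision (< 1e-12 px).
* Self-checks: 1000 random points/normals; pick-reproject on 300 pixels of
  a 96×96 sphere render; rasterizer vs exhaustive ray casting on a 64×64
  render of a 50-triangle shell.
* Registration recovery: 8 stops × 3 scanners, σ = 2 mm, injected errors
  ≤ 3° / 2 cm; recovered to ≲ 0.15° and ≲ 0.8 mm worst-stop.
* Reconstruction: same session class, full pipeline at depth 7; ~2.6–3.5 mm
  RMS to the true surface, watertight.

## Known limitations

* The implicit reconstruction is a signed-distance/marching-cubes scheme;
  like any such method it rounds sharp features at the grid scale and the
  sealed boundary layer fabricates a lid across unscanned openings.
* Point-to-point ICP is provided for reference but is not accurate enough
  for sub-millimeter recovery on smooth bodies; the pipeline relies on the
  point-to-plane metric.
* Orthorectification is strictly local (tangent plane); large curved regions
  cannot be unfolded into a single chart.
* The marker study measures each marker in its designated view. With the
  full 8-view rig and largest-area selection, no triangle is ever textured
  from a view more oblique than ~25°, so in production use the rectification
  errors are smaller than the 60°-tilt worst cases studied here.
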