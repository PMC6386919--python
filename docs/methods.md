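# Methods

This note documents the models, algorithms and numerical choices behind
`slvol`, in the order the pipeline runs, together with what the synthetic
scenes do and do not emulate.

## Coordinate conventions

Pixels are 0-based, origin top-left, x rightward, y downward. The camera
frame has its origin at the optical centre, z along the viewing axis
(positive away from the camera); units are centimetres throughout. The world
frame of a scan is z-up with the supporting table at z = 0.

Pixel→world conversion uses the horizontal field of view θ only:
`x = tan(θ/2)·z·x_ratio + C_x` and `y = f_y·tan(θ/2)·z·y_ratio + C_y` with
`f_y = 2/3` by default. The 2/3 factor corresponds to a 3:2 sensor whose
vertical ratio is normalised by the image half-height; `CameraModel` exposes
it (`y_axis_factor`) so other aspect ratios can be configured. The device
shifts (C_x, C_y) are treated as calibration outputs, zero for the synthetic
rig. No lens-distortion or intrinsic-matrix calibration is modelled — the
device's calibration procedure deliberately sidesteps camera intrinsics.

## Synthetic scenes

The projector is a pinhole ray fan: an 11 × 11 grid of rays with a fixed
angular pitch (2.2° by default), emitted from a point offset 4 cm from the
camera along x, with a small toe-in so the central ray crosses the optical
axis at 35 cm (the folded-mirror arrangement of the physical add-on is
absorbed into offset + toe-in; geometry, not optics, is what the pipeline
consumes). With the offset purely horizontal, each grid row maps to a fixed
image row and all depth information travels along x — the classic
structured-light epipolar layout. The pixel pitch between neighbouring dots
is ≈ 21 px and is depth-independent; a dot's pixel position is affine in 1/z,
so its locus over depth is a straight segment, monotone in depth.

Dots are rendered as flat-top super-Gaussian splats
(α(r) = 0.97·exp(−½ (r/σ)⁴), σ = 2.5 px) of a saturated laser green
(RGB ≈ (14, 230, 14)), alpha-blended over the scene. The flat core mimics an
overexposed laser spot; a plain Gaussian profile would leave almost no pixels
above the 90 % saturation gate once background bleeds in. The centre dot is
brighter (`center_dot_gain` = 1.5 on the green channel, clipped at 255, ≈ +10 %
in luminance — the cue the detector uses). Reflection artifacts are dimmer
satellite splats 4–8 px from a parent dot; Gaussian pixel noise (σ = 2 of
255) is added last. Every frame is bit-reproducible from the scene seed.

Scene radiometry is chosen so that surfaces sit below the laser in luminance
(as a camera exposing for the laser would render them): neutral table at
RGB 75, food colours red (120, 45, 40), brown (90, 60, 35), green
(40, 120, 40), light gray "white" (150, 150, 150). Dots on white items wash
out (luminance above the dot core) and are lost — reproducing the real
system's white-object failure mode; dark and red items detect best.

Scans orbit the camera at 42 cm from the item at 22° elevation, looking at
the item's mid-height, six evenly spaced azimuths by default. The low
elevation matches how the handheld device is swept around a plate — it is
what lets the camera see the sides and partially the under-curve of convex
items; at steep elevations the side bands are essentially unobserved and
resting ellipsoids would be over-estimated by the column model (see Volume
integration below). The IMU trace is gravity in the body frame plus
Ornstein–Uhlenbeck jitter, with quiet windows centred on the frame
timestamps, and a gyro consistent with a smooth-step yaw profile that
plateaus at each frame.

Not emulated: texture, speckle, shadows cast by the item, photometric
falloff with distance, rolling shutter, and motion blur. Passing tests on
these scenes therefore demonstrate the geometric/algorithmic correctness of
the pipeline, not robustness to real-camera radiometry.

## Dot detection

The cascade multiplies three binary masks:

* HSV gate: hue ∈ [90°, 180°] and saturation ≥ 90 % (hue in degrees,
  saturation on the 0–100 scale; the value channel is not used). Comparisons
  carry a 1e-9 degree epsilon so exact boundary colours are stable.
* Cosine-similarity mask: the angle between a pixel's RGB vector and the
  reference colour, pure green (0, 255, 0), thresholded at 0.9 by default.
  Black pixels have no direction and are rejected. An optional iterative
  mode re-estimates the reference from the brightest retained pixels (≤ 5
  iterations, stops when the retained count stabilises within 1 %).
* Luminance mask: BT.709 luminance minus its morphological opening by a
  disk (radius 5 px), thresholded at 0.6 × the maximum residual with an
  absolute floor of 1 (so a uniform image yields an empty mask). The
  opening — erosion then dilation — removes everything larger than the
  disk, leaving compact bright blobs.

Components touching an 8 px image-border band are removed. Each remaining
component (≥ 3 px) becomes a sub-pixel centroid weighted by the
*background-subtracted* residual luminance over the component dilated by
4 px: using the raw luminance instead biases centroids ≈ 0.3 px toward the
mask's geometric centre, which at the far end of the depth range (where the
trajectory moves < 1 px/cm) costs ≈ 0.4 cm of depth. Components much larger
than the median dot (> 1.6×) are re-centroided in a 4 px radius around their
peak — a reflection satellite blended into its parent would otherwise drag
the centroid by several pixels. Clusters of dots closer than 12 px collapse
to their brightest member (ties go to the dot nearest the cluster centroid);
the brightest surviving dot is the grid centre (ties toward the image
centre). Manual correction is a file-driven edit list (add/remove/move) with
per-dot provenance, replacing the original GUI with something testable.

## Grid indexing

The four nearest neighbours of the centre dot define the two axis vectors
(canonical orientation: u the more horizontal axis with positive x, v with
positive y, so calibration and scan frames agree). Assignment grows from the
centre *best-first*: every candidate link (cell, dot) carries a residual
cost, measured in the lattice basis against a consensus prediction from all
already-assigned neighbours (each using the locally observed step one cell
back). Confident links are committed before dubious ones, which prevents a
single bad link from shifting a whole region by one column. Acceptance is
anisotropic: |residual| ≤ 0.6 pitch along the baseline axis u (where surface
depth legitimately shifts the pattern) but ≤ 0.35 pitch across rows (which
carry no disparity). Dots the growth cannot reach — e.g. across a sharp
depth discontinuity at a silhouette — are dropped with a warning rather than
mis-indexed, because a one-column error maps to a ~10 cm depth error. On
planar scenes the scheme reduces to the global affine lattice. Fewer than
five dots fall back to a degraded single-axis mode.

Missing interior indices are imputed in pixel space: each grid axis
contributes an estimate (interpolation across the gap when dots exist on
both sides, extrapolation from the nearest observed step otherwise), and the
index is filled with the average only when *both* axes yield one. Observed
dots are never moved. A grid below 50 % occupancy raises a
rescan-recommended flag.

## Calibration

Each stack image runs through detection + indexing; per-index samples
(depth, x, y) are sorted by depth. Indices need ≥ 2 samples; a trajectory
whose displacement along its dominant direction regresses by more than 1 px
(tolerance for centroid noise at the far end, where steps shrink below 1 px)
is rejected as a detection failure. Images with no detectable centre are
skipped with a warning; partial grids contribute whatever indices they have.
A straight line is fit per trajectory by total least squares and its maximum
perpendicular residual stored as a quality diagnostic (< 0.5 px on clean
synthetic stacks).

Depth lookup projects the query pixel onto the stored polyline and
interpolates depth linearly within the bracketing segment — piecewise-linear
along the trajectory rather than a single global line, which tolerates the
mild 1/z curvature (and real-optics nonlinearity) while remaining exact at
every stored sample. Queries beyond the calibrated span clamp to the nearest
end and are flagged; the reconstruction stage drops such dots entirely,
since a clamped depth would fabricate a floating point. Validation reports
`accuracy = 100·(1 − mean |Δz|/z)` over a holdout; the model serialises to
JSON with full float round-trip (lookups preserved to 1e-9 cm).

## Reconstruction and volume

Frame selection splits the frames into k = 6 contiguous temporal segments
(equal frame counts) and picks, per segment, the frame minimising the RMS of
the high-pass-filtered (0.5 s moving-average removed) acceleration magnitude
in a ±0.3 s window; exact ties go to the segment midpoint, so a motionless
trace selects evenly spread frames.

Each selected frame runs detection → indexing → imputation → depth lookup →
pixel→world. Dots are classified food vs background by comparing the mean
colour of a 7–10 px annulus around the centroid (outside the splat) with the
background colour estimated from the image border. Poses come either from
the scan's recorded ground truth (default in synthetic mode) or from gyro
integration (trapezoidal rotation-vector steps) with a fixed-pivot
assumption for translation; both sit behind one interface and the choice is
logged. Frames fuse by rigid transform into the world frame with voxel-hash
averaging at the 0.5 cm merge radius; an optional capped-iteration ICP
refinement against the accumulated cloud exists for imperfect poses (off by
default). The fused cloud is then cleaned: background points must lie within
0.75 cm of a robust table plane (seeded at the 5th percentile of background
heights — the lowest coherent background layer — and refit once), and food
points need ≥ 2 food neighbours within 2.5 cm; everything else is a
mis-indexed or mis-classified outlier and is dropped.

The support plane is fit to the lowest 5 % of point heights and then refit
once on the inlier slab within ±0.4 cm — the raw lowest band is the noisy
lower tail of the table points and a plain fit sits ~2σ below the surface,
which over a 300–500 cm² footprint costs tens of cm³. The plane is flagged
low-confidence when the band spans fewer than 3 grid indices.

Volume is a 2.5D prism sum: points project onto the support plane, the
footprint is Delaunay-triangulated, and each triangle contributes its area
times the mean column height of its vertices (heights below the plane clip
to zero). Three refinements keep the prism model honest:

* Integration is restricted to food points plus the near-plane background
  skirt within 1.5 cm of a food point (≤ 1 cm high) — the plate is not part
  of the food, and integrating sensor noise over the whole visible table
  adds a spurious E|N(0,σ)| per cm².
* Side views observe the *under-surface* of items that tuck under (the
  lower half of a resting ellipsoid). Food points whose PCA normal —
  oriented toward the observing camera — points clearly below the support
  plane (n·ẑ < −0.2), or which sit directly beneath much higher food, are
  marked as under-surface, provided they lie below 60 % of the local top and
  form a floating connected band of ≥ 8 points that never reaches the plane
  (those guards keep walls and steep rims out). Columns in neighbourhoods
  containing under-surface points span upper-minus-lower, and the observed
  base ring is extrapolated inward with a quadratic descent toward the
  footprint centroid — the approximate shape of a convex base approaching
  its contact point. Where the underside was never observed the column
  still reaches the plane: the device's flat-bottom air-gap limitation
  (loose items with trapped air read high) is retained, only *observed*
  under-surface is credited.
* An optional per-item multiplicative correction-factor table (config) for
  known low-density/high-volume items; identity by default.

Volume is invariant under rigid rotation of cloud + plane, and deterministic
given the inputs. Degenerate inputs (coplanar cloud, < 4 points, failed
triangulation) return 0 cm³ with a warning.

Touching items are separated by RGB gradient-magnitude edges (Sobel per
channel) partitioning the non-background region into labelled masks; dots
are assigned to items by containment with a small label expansion across the
edge rings.

## Problem sizes and accuracy levels

The standard synthetic bench uses 720 × 480 frames, 51-frame calibration
stacks (10–60 cm), 50-plane holdouts, 180 single-view detection frames and
20 six-view volume fixtures with 2–8 cm axes. On this bench depth
calibration holds ≈ 98.7 % accuracy under 1 px centroid noise, detection
averages ≈ 94 % (white items ≈ 80 %, red/brown ≈ 99 %), and volume errors are
typically 1–8 % with a median ≈ 3–5 %; small (< 4 cm) and flat items are the
worst cases because an 11 × 11 grid at 42 cm lands only a handful of dots on
them. These levels are what the tests and `scripts/acceptance.py` compute;
nothing beyond them is claimed, and real-food performance additionally
depends on radiometric effects the renderer does not model.

## Known limitations

* Unobserved undersides and trapped air are counted as food volume.
* Items wider than the projected grid (> ~16 cm at the default range) are
  under-sampled at their rim.
* A one-column indexing error maps to a large depth error; the indexer
  prefers dropping dots over guessing, so clouds thin out near sharp depth
  steps.
* Gyro-only poses drift a few degrees over a scan and assume a fixed pivot;
  ground-truth poses are the synthetic default.
* The food/background classifier is colour-based and fails when food and
  plate colours match (the real device shares this failure).
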