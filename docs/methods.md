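# Methods

## The marker and its coordinate model

The marker is a flat print wrapped once around a cylindrical shaft of
radius `R`. Marker-plane coordinates are millimetres with `x` along the
cylinder axis and `y` along the circumference; the surface map is

```
X = x,   Y = R sin(y/R),   Z = R (1 − cos(y/R)),
```

equivalent to the two-branch square-root form on `y ≤ 3πR/2` and valid on
the whole wrap `[0, 2πR]`. Useful arc relations for an angle `α`:
arc length `A = αR`, chord `C = 2R sin(α/2)`, segment height
`h = R(1 − cos(α/2))`.

The default design targets a 10 mm tool (`R = 5`):

* three **dot patterns** of 2 rows × 5 dots (⌀ 1.6 mm, axial pitch
  3.2 mm, row gap 2.4 mm). Each row is a ruling of the cylinder, so the
  ten dots of a pattern are *exactly* coplanar — the property the planar
  pose solver and the tracking homography rely on. The top and bottom
  patterns carry an asymmetry device (the last dot of the second row is
  shifted by half a pitch); the bottom pattern is the top pattern rotated
  180° in the plane, and the middle pattern is symmetric under that
  rotation. This is what makes the three patterns distinguishable from a
  single view together with the assumption (valid for tools constrained
  by an incision point) that the image can never be mirrored.
* three **vertex rows** of five isolated 2×2 checker crosses (1.2 mm
  squares) between the dot patterns. All crosses of a row share one
  checker phase; the middle row's phase is flipped, rotating its corner
  orientation by 90°. Crosses are printed in mid-grey (150/255) rather
  than black: grey stays above the dot detector's binarisation ladder, so
  checker squares can never masquerade as circular dots, while the corner
  contrast against the white shaft remains ample. (With black crosses the
  squares of a vertex row form a regular 2×5 grid that fits the
  dot-pattern template projectively — an imposter no rejection radius
  separates at all scales. The dot/vertex conflict-rejection operator, an
  area-per-grid-cell plausibility veto and an orientation-label veto are
  still implemented and tested for dark-ink variants.)

`MarkerSpec.for_tool_diameter(d)` scales the design for 6–14 mm shafts.

## Feature detection

**Dots.** The grayscale frame is binarised at thresholds 70–100 in steps
of 10 (object = below threshold; the printed dots are nearly black, the
shaft white, the background mid-grey). Connected components are traced
per binary image and merged across thresholds when centres agree within
2 px. A merged candidate survives four filters, with defaults: area
50–2000 px², convexity (area / convex-hull area) ≥ 0.85, circularity
`4πE/P²` ≥ 0.75, and repeatability (number of thresholds at which it
reappears) ≥ 2. Finally centres are refined by a darkness-weighted
centroid over the full edge transition: binarising near the dark end of
the edge expands blobs asymmetrically under foreshortening gradients and
biases the binary centroid by a few tenths of a pixel; integrating the
whole transition is unbiased to first order in the edge width.

**Vertices.** After a σ = 1.5 px Gaussian pre-filter, 16 intensities are
sampled on a radius-5 ring around every pixel. The response is
`sum − difference − mean`: the largest contrast between complementary
half-sets of the eight opposite-pair sums (maximal for the 4-quadrant
corner layout), minus the total opposite-pair disagreement (penalising
edges), minus 8× the deviation of a local mean (σ = 2) from a larger
spatial mean (σ = 8) (penalising blob interiors). Peaks above
`max(40, 0.15 × global max)` survive 7×7 non-maximum suppression. The
orientation label is the phase of the ring's second circular harmonic —
the dark-quadrant axis, defined modulo 180° because a chessboard corner
is 180°-symmetric — quantised into 8 bins of 22.5°. A 90° checker-phase
change shifts the label by 4; a 45° image rotation by 2. Comparisons are
circular (mod 8) with a ±1 tolerance.

## Identification

Candidate dots are clustered by single linkage at 3× the median
nearest-neighbour distance (scale-free over the working range; within a
pattern the nearest neighbour is the row partner, and because both that
distance and the inter-pattern gap run along the circumference their
ratio also survives anisotropic foreshortening). Clusters are classified
largest-first; a failing cluster is re-clustered at 0.8× the link
distance (patterns merged across the gap under strong foreshortening
separate after a few shrink steps). For each cluster: the four sharp
(< 150°) convex-hull corners are ordered so the two long near-parallel
edges are the rows; the asymmetric and the symmetric template are fitted
through both 180°-related corner correspondences (mirrored ones are
excluded by the no-flip assumption); each detected dot takes the identity
of the nearest transformed template dot within 0.4× the projected pitch;
the fit explaining the most dots with mean residual below 0.08× the
pitch wins, and must assign ≥ 8 of 10 dots covering ≥ 75 % of the
cluster. If the winning template is the asymmetric one, the pattern is
*top* when its first dot lies left of its last dot in the image and
*bottom* otherwise; the symmetric middle pattern's reading direction is
fixed the same way.

Vertex identities: for the vertex rows adjacent to a classified pattern,
expected positions come from the pattern homography applied to each
vertex's orthogonal projection onto the pattern plane (an affine map,
fitted on the dots, converts plane coordinates to template coordinates),
and expected labels from the print phase pushed through the homography
Jacobian. Detections match within 0.5× the projected vertex pitch *and*
±1 label; everything else — including the spurious corner responses that
appear between stacked dot rows, whose labels are perpendicular rather
than diagonal — is rejected.

## Temporal tracking

The flat template coordinates of the best identified pattern are the
reference `p_r`; its image points `p_m` satisfy `p_m ~ H p_r` exactly
(plane-to-plane homography, 8 DoF, estimable from four non-collinear
pairs; normalised DLT, with a seeded 3 px-inlier random-sampling loop
when more pairs are available). On detection failure the previous points
are tracked by pyramidal Lucas–Kanade flow (3 levels, 21×21 window,
forward–backward consistency within 1 px); if ≥ 4 tracked inliers
survive, `H` is re-estimated and missing dots are filled by `H p_r`
(mode *flow_tracking*), else the state degrades to *lost* and no pose is
emitted until detection recovers. Detection is attempted on every frame
regardless of mode, and a successful detection always re-initialises the
point set.

## Pose estimation

Normalised image points of one pattern and its planar model coordinates
give a homography whose Zhang-style decomposition (column scaling + SVD
orthonormalisation) seeds the first pose. The second, reflection-related
candidate is constructed by rotating the camera frame so its z axis runs
along the translation, decomposing the rotation as ZYZ Euler angles and
negating the middle (tilt) angle. Both candidates are polished by
Levenberg–Marquardt on the pixel reprojection error; if the second
collapses onto the first (no second local minimum exists — the
strong-perspective case) the raw reflection is kept as the alternative so
its error honestly reports how bad it is. Candidates are ordered by mean
reprojection error.

**Ambiguity.** The pose is ambiguous when both errors are below 2 px and
their ratio is below 1.5. Ambiguous poses are resolved by the vertex
reprojection error: the vertices' full 3D cylinder coordinates lie off
the dot plane, so the reflected solution projects them far away. With no
matched vertices (e.g. while occluded), the candidate closer in rotation
to the previous frame's pose wins; with no prior either, the lower-error
candidate is kept and flagged unresolved.

**Refinement.** The chosen pose is refined over every identified feature:
vertices as point correspondences, dots through a curved-boundary
measurement model — the predicted observation is the area centroid of the
projected 24-point dot-boundary ring, not the projection of the dot
centre. A disk wrapped on a 5 mm cylinder projects with its centroid a
few tenths of a pixel away from its centre's projection, which otherwise
leaves a systematic ~1° rotation bias. Multiple patterns and the vertices
are jointly non-planar, so the fused refinement also conditions the
weak-perspective tilt directions.

## Synthetic scenes

Frames are rendered by inverse mapping: each pixel ray is intersected
with the cylinder, hit points are unrolled to print coordinates and the
texture is sampled bilinearly (exact silhouettes, no holes at grazing
angles). Degradations, in order: polygonal occluders (the fake-blood
scenario), Gaussian blur, multiplicative illumination gain, additive
Gaussian noise clipped to [0, 255]; all randomness flows through one
seed, and identical seeds give byte-identical frames. Ground truth per
frame: the pose, exact feature projections, and visibility (outward
normal within 60° of the view ray, inside the image with a 6 px margin,
outside every occluder).

What the renderer does **not** emulate: specular highlights, smoke,
tissue texture, rolling shutter, lens flare, print/wrap distortion and
calibration error. Passing tests therefore demonstrate the geometric and
algorithmic correctness of the pipeline under controlled degradations,
not robustness to every clinical nuisance.

## Study protocols and problem sizes

* **Pose accuracy**: 50 frames, 95–105 mm depth, superposed ±12°/±15°/±15°
  roll/pitch/yaw sinusoids, ±3 mm lateral motion, noise σ = 2, blur
  0.5 px, camera facing 25° off the middle pattern so a vertex row stays
  well visible. Reported as mean (± SD) translation and rotation of
  `truth⁻¹ · estimate`. Typical result ≈ 0.12 mm / 0.33°.
* **Detection rate**: 300 frames, 50–100 mm depth, sequential ±30° roll,
  ±35° pitch, ±35° yaw sweeps (one axis per third). The rotation
  amplitudes sit inside the default layout's single-pattern visibility
  envelope: with three patterns 115° apart around the circumference and
  dots filtered beyond ≈ 55–60° incidence by the circularity test, a
  full pattern stays visible for rolls within about ±36° of facing a
  pattern; larger excursions are the temporal tracker's job.
* **Ambiguity property**: ≥ 50 seeded views at 130–160 mm with ≥ 2
  matched vertices; the reflected candidate's vertex reprojection error
  must strictly exceed the true candidate's in every trial.
* **Occlusion recovery**: a static scene occluded progressively to 45 %
  (flow tracking) and ~100 % (lost), then cleaned (detected again).

## Numerical choices and degenerate inputs

Homography DLT uses Hartley normalisation and rejects configurations
whose second singular value collapses; homographies are scaled to
`H[2,2] = 1`. Collinear point sets, < 4 correspondences, rings touching
the image border, zero perimeters, empty threshold lists and empty
trajectories raise typed errors. The hull-corner sharpness threshold is
150° (the asymmetric corner reaches ≈ 145° under strong foreshortening
while collinear row dots stay near 180°). Blob perimeters use the
region-props contour estimator with diagonal weighting; its few-percent
overshoot on smooth contours is why the circularity gate is 0.75 rather
than something closer to 1. Convexity tolerates ~0.02 of hull
discretisation. Ties in cluster size break toward the image centre;
greedy identity assignment is globally ordered by distance, one dot per
model point.

## Known limitations

* Dots below the 50 px² area floor (10 mm marker beyond ≈ 165 mm at
  f = 1000 px, or rows beyond ≈ 60° incidence) are filtered out, so the
  far end of the working range relies on near-fronto rows — consistent
  with a maximal working distance rather than a defect, but a smaller
  area floor would be needed for longer ranges.
* The middle pattern alone in view has a 180° ambiguity resolved only by
  the reading-direction convention; a camera rolled beyond ±90° violates
  the no-flip assumption and is out of contract.
* The temporal tracker refreshes its reference on every successful
  detection and drifts under long occlusions (it degrades to *lost*
  rather than emitting poses once fewer than four inliers survive).
* Illumination gains that push the grey crosses under the binarisation
  ladder (gain ≲ 0.6) would re-introduce checker-square dot candidates;
  the vetoes for that regime are tested synthetically but not exercised
  by the default protocols.
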