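# Methods

`facetfit` reconstructs the evolving 3D shape of a single faceted crystal
from 2D keypoints observed in transmission optical microscopy, exercised
end-to-end on synthetic crystals through a built-in observation simulator.
This note records the models, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Shape model

A convex crystal habit is a set of `m` bounding lattice planes with unit
normals `N_i` (the normalized reciprocal-lattice vectors `h a* + k b* + l c*`
of the Miller indices, computed from the unit cell), grouped into
crystallographic forms and equipped with the point-group rotations that
permute the face set.  A *configuration* adds per-face center-to-plane
distances `d_i` (mm), an internal origin `P` (mm, cell frame, `z` toward
the camera, glass at `z = 0`), an axis-angle rotation `R` (applied before
translation), a refractive index `eta`, and material/light scalars carried
only for metric parity.

Vertices are enumerated as the intersections of all linearly independent
plane triples (condition number below 1e8), kept when they satisfy every
half-space constraint within `1e-8 * max d_i`, and deduplicated at the same
relative tolerance — symmetric habits routinely produce vertices where four
or more planes meet, and all incident faces are recorded.  Face cycles are
ordered counter-clockwise about the outward normal; areas come from the
centroid-fan triangulation and the volume from signed tetrahedra.
Boundedness is a property of the normal set alone (they must positively
span R^3, checked once per habit by a small LP and cached).

### Canonical morphology

Three ambiguities are resolved, in order: (i) grown-out planes are clamped
to the threshold of appearance `d_i <- max_v N_i . v`; (ii) among the
habit's symmetry rotations, the one whose composition with the pose has the
smallest geodesic angle to the identity is applied, permuting the distances
(ties prefer the identity, then the lowest op index — this makes the map
idempotent); (iii) the origin moves to the least-squares point of the plane
system, with the pose translation compensated so the posed shape is
unchanged.

## Refraction-aware projection

The camera is orthographic along `-z` (pixel scale configurable; image
origin top-left, x right, y down, pixel centers at integer coordinates).
Faces whose posed normal has positive z-component are *front*; each front
face is a refraction *window*.  A view ray entering a planar window refracts
once by the vector Snell law with relative index `1/eta`; because the
refracted direction is constant across a planar window, a straight back
edge maps to a straight 2D segment, so endpoints suffice.  Refracted
segments are clipped to the window's projected polygon (convex clipping);
clip points on the window boundary are keypoints in their own right,
alongside all projected (direct and refracted) vertices.  Points in front
of the window plane are not visible through it and the segment is dropped.
Keypoints closer than the detector merge radius — 20 px at the full
2160 px detector resolution, scaled to the configured image width — merge
to their centroid.  Heatmaps place Gaussian blobs of height 1 and variance
5 px² at the keypoints, combined with the max operation.

Profile faces (normal perpendicular to the view) are windows of zero
projected area and contribute only silhouette edges; they are classed back
with a 1e-12 tolerance on the normal's z-component.

## Losses

Two keypoint representations coexist.  *Emitted* keypoints (CSV, heatmaps,
detector emulation) merge within the detector radius, as a detector would.
The *fitting* experiments instead collapse only coincident projections
(1 px): the multiplicity of the wireframe — how many refracted segments
terminate at the same feature — is exactly what disambiguates alternative
front/back-edge interpretations, and wide merging discards it (measured:
switching the fitting loss to 1 px merging removed the catastrophic
wrong-basin refinements of the improvement experiment entirely).

* `L_K` — a debiased entropic optimal-transport (Sinkhorn) divergence
  between projected and observed keypoint sets, squared Euclidean cost,
  uniform weights, blur 4 px (regularization eps = blur²).  By default the
  marginals are KL-relaxed with reach 50 px (rho = reach²): wireframe
  keypoint sets change cardinality and multiplicity whenever the projection
  combinatorics shift, and real detectors drop and invent points; strictly
  balanced transport then teleports the mass imbalance across the image,
  an irreducible cost that swamps the geometric signal (we measured
  refinements under 2% shape noise getting *worse* with balanced
  transport).  `reach=None` restores the balanced divergence.  The solver
  is a log-domain Sinkhorn with epsilon-scaling (temperature annealed from
  the squared diameter by 0.7 per iteration), capped at 100 iterations.
  Warm-starting the potentials across refinement iterations was tried and
  removed: starting at the target temperature from slightly stale
  potentials converges worse than the annealed cold solve.
* `L_z = (min_z V)²` — substrate contact at the glass plane.
* `L_R = R_x² + R_y²` — crystals rest nearly flat, so out-of-plane rotation
  is penalized.
* `L_o = mean_i max(0, d_i - dbar_i)²` with `dbar_i = max_v N_i . v` —
  grown-out faces are held at the threshold of appearance.

Default weights `w_K = 1, w_z = 10, w_R = 1, w_o = 10` (configurable; the
keypoint term dominates by magnitude, the regularizers act near their
zeros).

### Gradients

No autodiff framework is used.  The projection's discrete combinatorics
(plane triples, window assignments, clip edges, merge groups) are frozen
per evaluation; with fixed combinatorics the map from parameters to
keypoints is smooth and is re-evaluated for a whole batch of perturbed
parameter vectors at once, giving the Jacobian by central differences.
The gradient of the transport term with respect to keypoint positions is
the exact envelope (Danskin) gradient read off the converged transport
plans; epsilon-scaling is essential here — without it the capped solver's
potentials are far from the fixed point and the envelope gradient is
unusable.  The chain of the two gives `dL/d(D, P_xy, R, eta)`; `P_z` is
not a free parameter (substrate physics), and `eta` is frozen by default
(1.7 for alpha-LGA, the value manual fitting favors).

The gradient check in the test suite compares this hybrid gradient against
central differences of the loss along the smooth path with the transport
re-solved from scratch, using the unbalanced solver at blur 10 px: its
damped iteration is a contraction (factor rho/(rho+eps)) and reaches its
fixed point to 1e-13, where the envelope gradient is exact.  The balanced
solver can stagnate on near-ties at small blur (observed residuals ~1e-3
after 5000 iterations), which is a property of the solver, not the
gradient.

## Single-frame refinement

Adam (lr 1e-2 on normalized parameters: distances and in-plane origin in
units of the crystal size = mean distance, rotation in radians), gradient
clipped at norm 10, best-so-far iterate returned, distances projected
positive after each step; the result is snapped to substrate contact and
canonicalized.  The iteration budget (default 300) is spent in a
coarse-to-fine schedule:

1. *rigid warmup* (first 24%): rotation and in-plane shift only, shape
   frozen.  Joint descent from a 10-degree pose error reliably walks into
   wrong-correspondence minima (0/6 recoveries in our pilot); rigid
   pre-alignment makes the transport landscape effectively unimodal for
   moderate rigid perturbations (6/6).
2. *full phase* (next 36%): all free parameters at blur 4 px, reach 50 px.
3. *polish* (final 2 x 20%): all free parameters at blur 2 px / reach
   20 px (lr 3e-3), then blur 1 px / reach 10 px (lr 1e-3).  Near the
   optimum the wide blur/reach limit precision; the tight phases cut the
   final distance error severalfold.

Two stabilizers wrap the schedule.  The coarse stages run in *blocks* of
50 iterations: between blocks the iterate is snapped to the substrate and
canonicalized (grown-out faces clamped, origin recentred — a projection
back onto the representative manifold) and the Adam moments reset;
restarted, reprojected descent escapes the limit cycles that long
uninterrupted runs fall into on this loss, while the polish stages run
contiguously so Adam can settle.  And a catastrophe brake compares the
final iterate's base-settings loss with the starting point's: a run that
ends worse than it began returns its start, so a refinement can degrade an
estimate by at most nothing.

## Perturbation-recovery and refinement-improvement experiments

Both experiments (in `facetfit.experiments`) draw alpha-LGA crystals from
the bundled morphology prior, scaled to cover 15-35% of a 400 px frame
(the imaged crystals in growth cells are large in frame) and posed
*resting*: tilt of at most 3 degrees from flat with uniform in-plane
rotation — sedimented crystals lie on a face (for alpha-LGA the (100) face
contacts the cell bottom), which is also the prior the `L_R` regularizer
encodes.  Observations are the truth's own noiseless projected keypoints.

* Return rate: a self-consistency check first verifies the reference fits
  its own keypoints; then seeded runs of 10-degree 3D rotations and 10%
  relative in-plane shifts (50 pooled runs in the bundled script, 52 in
  the test suite) are refined for 300 iterations and scored
  against tau = 0.1 on the size-normalized bidirectional mean
  nearest-neighbor vertex distance (size = mean distance of the
  reference).
* Refinement improvement: initializations emulate one-shot prediction
  error with 5 degrees of rotation, 5% in-plane shift and 5% relative
  distance noise; per-crystal relative reductions of `E_v` (bidirectional
  nearest-neighbor vertex error) and `E_d` (mean absolute distance error)
  are averaged over 20 crystals.

Both experiments fit against keypoints merged at 1 px (coincident
projections only; see above).  Expect strong typical-case recovery with a
minority of crystals converging to an alternative front/back-edge
interpretation that explains the single-view keypoints comparably well —
the same ambiguity that full reconstruction pipelines resolve with manual soft
constraints or an additional image-space loss.  Initializations drawn as
*random* independent perturbations also sit outside the basin of the
generating shape more often than a trained predictor's in-distribution
estimates would.

## Growth sequences

The truth generator draws per-form base distances from the prior, grows
them affinely in time with per-form nonnegative rates, and holds the
intra-form asymmetry as *additive* offsets fixed over time.  With complete
symmetry forms (every orbit of normals sums to zero) this keeps the
canonical origin constant along the sequence, so per-face monotonicity
survives canonicalization exactly and the negative-growth penalty is
identically zero on the truth.  Pose is static (drawn so the final, largest
frame fits the image); only the origin's z-component varies, keeping the
bottom face on the glass as the crystal grows.

The sequence generator is a four-hidden-layer GELU network (width 256 by
default; tests use smaller widths) mapping normalized time `t' = t/(T-1)`
to normalized distances, with rotation shared across the sequence as a
static trainable parameter and origin/refractive index frozen at reference
values.  It is pretrained by plain regression onto per-frame initial
estimates (1000 batches of 256 uniform time points, Adam lr 1e-3), then
trained end-to-end through the projection: batches of 16 frames are drawn
from a multinomial over cached per-frame errors without replacement
(uniform before the first evaluation, refreshed lazily), the batch loss
adds a negative-growth penalty
`L+ = mean over ordered pairs and faces of min(0, d_later - d_earlier)²`
with weight 1e4, learning rate 1e-4 decayed by 0.8 after 200 steps without
sequence-error improvement, non-finite batches skipped with a one-time
halving.  Manual soft constraints add the mean squared distance deviation
at constrained frames.  Backpropagation through the network is
hand-written; the loss gradients with respect to the per-frame distances
and the static rotation come from the same hybrid path as single-frame
refinement.

## Observation simulator

The detector stand-in drops each true keypoint independently (default
10%), jitters survivors with isotropic Gaussian noise (default 2 px), adds
Poisson-distributed spurious points uniform over the image, optionally
merges within the detector radius, and clips to the frame.  Channel
statistics are Monte-Carlo verified in the tests.  What it does *not*
emulate: spatially correlated detector failures, bubble/defect artifacts
clustered near edges, intensity-dependent localization error, or any
rendering-level effect — conclusions from passing tests are therefore
about the geometric pipeline under idealized detector noise, not about
real-image robustness.

## Problem sizes and limitations

The bundled experiments use 400 px images, 100 runs for the return-rate
study and 20 crystals for the improvement study; sequence tests use 6-8
frames with reduced network width and step counts.  These sizes keep the
full suite in the minutes range while leaving the estimators' confidence
intervals meaningful.

Known limitations: single refraction event per window (no
total-internal-reflection paths, no second interface); balanced/unbalanced
transport is solved to a capped iteration budget during fitting, so
gradients near the optimum are approximate at blur 4 px; keypoint-only
refinement retains a minority of wrong-correspondence local minima under
combined pose-and-shape perturbations (full reconstruction pipelines
additionally use a rendered-image loss, out of scope here); and the
perspective camera of a real microscope is approximated as orthographic at
matched substrate scale.
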