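# Methods

This note documents the models, numerical choices and assumptions behind
`footclear`, and what its synthetic validation does and does not show.

## Geometry and units

Images use the raster convention: origin top-left, rows increase
downward, columns rightward; sub-pixel positions are `(column, row)`
floats.  The walking surface is a line through two user-supplied image
points; it may be gently sloped (a validation warning fires above
|slope| = 0.2, which would indicate a mis-aligned camera).  Clearance is
always the vertical pixel distance from a mask's per-column lowest point
to the ground line, minimized over columns.  The conversion factor
`k = D / x` (mm/px) assumes the two laser beams are parallel and the
pedestrian walks in a plane perpendicular to the optical axis; beam
non-parallelism is a systematic error source that cannot be estimated
from the video itself.  `x` is the Euclidean distance between dot
centers; at the enforced near-vertical alignment (column offset ≤ 12 px
at separations ≥ 30 px) it differs from the vertical component by well
under 0.1%.

## Laser-dot detection

Lighting varies between recording sites, so the bright-pixel threshold
is a quantile of the frame's intensity distribution (default 0.999)
rather than a fixed value.  Candidate blobs must satisfy
3 px² ≤ area ≤ 400 px² and circularity 4πA/P² ≥ 0.6 (perimeter from the
region boundary); dot centers are intensity-weighted centroids, which
localize a saturated spot to well under half a pixel.  Among valid pairs
(vertical alignment, separation inside [30, 600] px) the brightest pair
wins, ties by tighter column alignment.

A single frame is not trusted.  The beams land on the leg for one
contiguous run of frames, so the sequence-level scan groups per-frame
detections into runs and accepts the first run with at least three
detections whose separations agree within 5% of the run median; the
member with the median separation becomes the calibration.  This
consistency requirement exists because bright scenes produce occasional
false pairs from sensor-noise clusters whose separations are essentially
random, while genuine detections repeat the same separation to a tenth
of a percent.  When no run qualifies, the pipeline falls back to
manually annotated centers, or emits pixel-only results flagged
`incomplete_calibration`.

## Frame-state machine

Each frame is classified from the previous state and the number of
backend masks (0, 1 or 2): *no one*, *begin* (one foot entering),
*fully visible*, *overlap*.  The 12-entry transition table is total and
deterministic; more than two masks (a second pedestrian, out of scope)
keeps the current state with a warning.  The table is normative for this
package and exhaustively tested.

## Swing/stance labeling

With both feet visible, the mask whose lowest point is further above the
ground line is the swing foot.  Near-ties (< 0.5 px) are resolved by
centroid displacement since the previous frame — the moving foot swings;
without history both stay unlabeled for that frame.  On synthetic scenes
this labels 100% of non-overlap frames correctly.

## Occlusion recovery

When the feet merge into one mask, the previous swing mask's bottom-edge
point set is searched over 9 rotations (±20° in 5° steps, about the
bottom-edge centroid, which keeps the sole anchored) × integer
translations (±40 columns, ±15 rows — sized to foot motion at 60 fps HD
and configurable).  Each placement is scored by the mean
distance-transform value of the frame's edge map at the transformed
points; the minimum wins, ties prefer the smaller translation then the
smaller |rotation|.

Two refinements to the plain chamfer score proved necessary:

* **Oriented matching.**  Edges are binned by undirected tangent
  orientation (8 bins of π/8; template points match edges within ±1 bin;
  the two endpoints are wildcards because their one-sided tangents are
  unreliable where the bottom edge meets the side walls).  With
  unoriented scoring, the toe profile's points can "cheat" onto the long
  horizontal sole edge, which biases the match a few pixels toward the
  trailing side each frame; at swing-foot speeds near the window edge
  the lag compounds into track loss.  Oriented chamfer removes the
  cheap wrong matches while leaving a perfect self-match at score
  exactly 0.
* **Stance veto.**  The two shoes are near-identical, so the stationary
  stance foot's outline is an exact-score decoy for the template.
  Placements whose mean distance to the remembered stance bottom edge
  falls below 1.5 px are rejected (with a fallback to the unrestricted
  optimum if everything is rejected).

The edge map is computed on a padded crop around the search region
(Sobel magnitude, Otsu threshold unless configured), which keeps the
per-frame cost at a few milliseconds.  A window with no edges returns
the previous mask flagged low-confidence.

## Stride segmentation and the quintic model

The swing-foot trajectory is sampled as (frame, clearance, centroid
column).  Per-frame centroid-column velocity is median-smoothed over 3
frames; a reversal against the inferred walking direction or speed below
0.5 px/frame sustained for ≥ 3 frames ends a stride; segments shorter
than 8 points (6 quintic unknowns plus slack) are discarded.  Walking
direction comes from the half of the image where the swing foot first
appeared (ties default to right-to-left and are logged).

Within a stride, clearance is modeled as a 5th-degree polynomial — the
foot trajectory has three inflection points (rise after toe-off, the
mid-swing dip, the terminal rise).  The fit is ordinary least squares on
abscissae affinely mapped to [−1, 1] for conditioning; coefficients are
also reported in the raw frame-index basis.  The second derivative of a
quintic is cubic, so ≤ 3 inflections is a structural guarantee, asserted
on every fit.  The MFC is extracted from the analytic derivative roots
of the fitted curve (interior, positive second derivative, value clipped
at zero, lowest minimum wins); the raw-series interior minimum is
available as an alternative via `mfc_method: raw_series`.  Minima at the
stride boundary are not reported — a boundary minimum means the true MFC
may lie outside the field of view.

## Synthetic scenes

The generator is the package's test instrument, not a photorealistic
renderer.  A scene is: a linear horizontal illumination gradient; a
stationary stance shoe on the ground line; a swing shoe (flat sole,
quarter-ellipse toe) translating along a smoothstep column path with a
clearance curve built so that its derivative is
`h'(t) = c·t(t−t_a)(t−t_b)(t−t_c)` — critical points exactly at the
stride start, the first peak (`h(t_a) = h_a`), the minimum
(`h(t_b) = h_b`, the true MFC) and the second peak, whose height is
implied by the other choices; laser dots drawn as saturated discs with a
Gaussian skirt (a pure Gaussian profile leaves too few near-peak pixels
above an adaptive threshold in bright scenes, unlike a real overdriven
sensor); and per-pixel Gaussian intensity noise added last.  Truth
(masks, clearances, MFC, laser centers, stride bounds) is recorded
before noise; geometry is never perturbed.  A few empty lead-in frames
precede the pedestrian so the state machine and the
background-subtraction backend have a clean reference.

Default conditions: HD 1080×1920 frames, 72 frames per scene (~1.1 s at
60 fps, one stride in view), swing and stance silhouettes at distinct
grey levels (so a merged blob retains an internal boundary, as real
footage does), sole 140 px, shoe height 60 px, laser separation 120 px
with D = 164 mm (k_true ≈ 1.367 mm/px).  Dataset sampling varies walking
direction, true MFC uniformly in [3, 30] px, shoe size, laser separation
and ground row, and assigns one of three site presets — two shaded
(base ~150/160, σ = 4/5) and one in bright sun (base ~205, σ = 7) —
mirroring the lighting spread of outdoor data collection.  The stance
shoe sits at 45% of the swing path, which makes the silhouettes merge
for several mid-stride frames, exercising overlap recovery in every
scene.  All randomness flows from a single seed; rendering is
bit-deterministic.

Because the generator's clearance curve is itself a quintic, noise-free
parameter recovery is an exact oracle for the whole pipeline: the
measured end-to-end MFC error is ≤ 0.3 px over 20 seeded scenes
(tolerance 1 px), and ≥ 90% of scenes stay within 3 px under σ = 5
intensity noise (measured: all of them).  A `nonquintic_amplitude`
option adds a sinusoidal perturbation for model-mismatch experiments.

**What this does not show.**  The synthetic scenes have rigid shoes,
no clothing, textureless backgrounds, a single pedestrian, exact
silhouette edges and level ground.  Passing the synthetic suite
validates the algorithmic chain, not performance on real footage — that
depends on the segmentation backend (a trained detector behind the
`SegmentationBackend` contract) and on real-world error sources
(camera alignment, walking angle, beam parallelism) documented above.

## Agreement statistics

Per-pedestrian rater agreement uses RMS deviation from the rater mean
with divisor *n*, so `rms = sd·√((n−1)/n)` with the sample SD (divisor
*n*−1); the overall figure is the arithmetic mean of per-pedestrian RMS
values — the only aggregation consistent with the packaged reference
table (the root-mean-of-squares alternative gives 2.75 mm and is
rejected).  Bland–Altman limits are bias ± 1.96·SD of pairwise
differences, pooled over all rater pairs.  The packaged ten-pedestrian,
five-rater reference table reproduces an overall manual RMS of 2.32 mm;
two of its printed per-pedestrian RMS entries appear transposed relative
to their SDs and one is inconsistent with the √((n−1)/n) relation —
they are shipped as printed, and the aggregate is insensitive to the
transposition.

## Degenerate inputs and tie-breaks

Constant frames yield laser not-found, never an exception.  Masks
rendered below the ground line clip to zero clearance with a warning.
A backend failure on a frame counts as zero detections.  Strides whose
fitted curve is monotone in view produce no MFC (logged), and an
analysis with no estimate at all exits nonzero.  Tie conventions (first
detection at the exact midline → right-to-left; equal chamfer scores →
smaller translation, then smaller |rotation|) are fixed and tested.

## Problem sizes

The shipped validation uses 20 scenes per noise arm at the default HD
geometry for end-to-end recovery, 50 frames for laser detection, 100
random mask pairs for the metric oracles, and 2 scenes for bit-level
determinism; unit tests run on a quarter-scale scene with the same
proportions.
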