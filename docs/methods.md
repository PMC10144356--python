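# Methods

This note documents the models, parameters and numerical choices behind
`wireskill`, and what the synthetic validation does and does not establish.

## Coordinate and unit conventions

Pixel coordinates are 0-based, origin top-left, x = column, y = row. Times
are seconds with t = frame_index / fps (default 20 fps); forces are newtons;
image-plane metrics are pixels unless an `mm_per_px` calibration scalar is
supplied, which converts path length and slope variations only.

## Vessel phantom

The phantom is the camera's 2-D view of a transparent aortic-arch model: a
straight descending aorta (lumen half-width 14 px), a circular arch
(radius 130 px), and three branch targets — brachiocephalic, left common
carotid, left subclavian (half-widths 8–9 px) — taking off from the arch at
fixed angles. The lumen is the union of constant-radius tubes around the
segment centerlines; `wall_clearance(p)` is the distance from an interior
point to the nearest wall (radius on a centerline, 0 on the wall, negative
outside), the quantity the collision rule thresholds. Dimensions and take-off
angles are representative of an adult arch as seen in a 640×480 top-down
camera frame, not a replica of any particular silicone model; take-off turn
angles are kept near 80° (a bend a real wire can make) and each task path is
filleted with a Gaussian of σ = 10 px arc length, because a hard fold in the
centerline would both be unphysical and mimic a tip corner. Vascular
difficulty is the configured ordinal level per branch (brachiocephalic 1;
carotid and subclavian 2); a continuous score
`w1/diameter + w2·distance + w3·take-off angle` is available for sensitivity
analyses.

## Trial simulator

A trial advances the tip along the arc-length parameterization s(t) of the
task path with a skill-conditioned AR(1) speed process
(v ← v0 + ρ(v−v0) + σ√(1−ρ²)ε, clipped to [0, 2.5·v0]). Defaults:

| parameter | expert | novice | meaning |
|---|---|---|---|
| advance_speed v0 (px/s) | 60 | 45 | mean tip speed |
| speed_sd σ (px/s) | 8 | 28 | speed innovation (smoothness) |
| speed_rho ρ | 0.9 | 0.85 | speed persistence |
| pause_prob | 0.02 | 0.08 | per-step dwell probability (2–8 frames) |
| reversal_prob | 0.05 | 0.5 | per-bifurcation withdraw-and-retry probability |
| jitter_sd (px) | 0.5 | 2.5 | lateral tip noise (AR(1), ρ = 0.85) |
| contact_rate | 0.2 | 3.0 | expected wall-contact episodes per trial |
| force_spike_scale (N) | 0.3 | 1.2 | contact force spike amplitude |
| body_wiggle (px) | 0.3 | 0.8 | baseline lateral body wave |

Expert values strictly dominate novice values on the contrasts the metrics
measure. Chosen once so that a default expert finishes a task in roughly
8–11 s and a default novice in 20–30 s with visible hesitation, retries and
wall contacts; they were not revisited afterwards.

Mechanics worth noting:

- **Pre-inserted tail.** The wire enters the lumen 60 px below the tip's
  start point and that tail is static in every frame. This mirrors a sheath
  at the access site and keeps the insertion-end corner away from the moving
  tip's search region.
- **Lateral jitter** is clipped at (actual wall clearance − 4 px), so jitter
  alone can never produce wall contact; the tip's lateral offset is blended
  into the last 20 px of the body with a smoothstep so the wire reaches the
  tip without a fold.
- **Contact episodes.** The number per trial is Poisson(contact_rate); each
  lasts 2–5 frames at a position at least 80 px into the path, away from
  branch mouths, at a wall point validated by `wall_clearance ≤ 0.6`.
  During an episode the tip is pinned exactly at the wall, the body bows to
  (radius − 3 px) so only the tip vertex is in contact, and the bow's
  amplitude flips sign every frame: consecutive contact frames always differ
  by a clearly visible body-shape change, which is the event the collision
  rule is defined to detect. Episodes are separated by at least 3 frames.
- **Force trace.** Per-axis Gaussian sensor noise (sd 0.05 N) plus a
  half-sine spike of amplitude ≈ force_spike_scale in a random 3-D direction
  aligned with each contact episode.
- **Ground truth** (tip path, per-frame wire polylines, collision pairs,
  controller-style speed log |Δs|·fps, progress s(t)) shares the frame count
  across streams, and a trial is bit-identical when regenerated from its
  recorded seed.

The default cohort design is 2 groups × 3 surgeons × 5 tasks × 5 repetitions
= 150 trials; the five tasks map to the three branches as (brachiocephalic
×2, carotid ×2, subclavian ×1), populating both difficulty levels. Per-trial
seeds derive from the master seed via `SeedSequence`.

**What the simulator does not emulate:** fluoroscopy artifacts, occlusion or
non-uniform illumination, wire torsion and elasticity (the body is a
centerline with a smooth lateral displacement field, re-posed each frame),
3-D foreshortening, multi-wire scenes, or inter-surgeon variability beyond
the two skill profiles. Passing the validation therefore shows the pipeline
recovers the quantities it defines under clean phantom-like imaging; it does
not certify performance on clinical fluoroscopy.

## Tip tracking

- Binarization: fixed threshold means `mask = frame ≥ t`; the automatic
  policy maximizes inter-class variance (Otsu) and takes the wire strictly
  above the returned (dark-class) bin.
- Corner score: smaller eigenvalue of the gradient structure tensor,
  central-difference gradients, box-summed over a (2w+1)² window (default
  w = 2), zero outside the image; scores clipped at 0.
- `detect_tip` returns the highest-scoring local maximum above a score floor
  (default 1% of the first frame's maximum score); ties break by smaller y
  then smaller x; a seed hint switches selection to the nearest qualifying
  corner. A failure is a recorded signal, not an exception.
- Inside the per-frame ROI (side 41 px, doubled once on failure) the tracker
  ranks candidates by *endpointness* first — the minimum count of binarized
  wire pixels in a radius-3 disk near the candidate — and score second. Both
  the end-cap and a tight bend of the wire are strong min-eigenvalue
  corners and pixel noise can swap their ranking, but only the tip sits at a
  free end of the wire.
- The winning corner is refined to the wire-mask extremity (the nearby mask
  pixel with the fewest wire neighbors), pulled back 1 px toward the wire:
  the eigenvalue peak of a line termination sits 2–3 px inside the wire, a
  bias larger than the tracking tolerance. Sub-pixel parabolic refinement of
  the score peak is applied where the extremity step is disabled.
- Invalid frames are filled by linear interpolation between neighboring
  valid tips (nearest-valid at the ends) and flagged `interpolated`; manual
  fixes override anything and are flagged `manual`. First-frame failure with
  no seed hint raises; the fallback with no hint picks the qualifying corner
  nearest the configured insertion-side border.

## Metrics

Path length, slope variations and the force summaries are literal sums as
defined in the README; slope variations are summed over *all* consecutive
frame pairs. The speed-peak rule uses strict inequalities (plateau ties are
not peaks) and compares against the mean over all samples of the trial,
idle included. The speed source defaults to the controller log when present,
else the trajectory (v_i = step length × fps); the source is recorded in the
metric provenance. Untrimmed procedure time is the span (n−1)/fps between
first and last frame; optional trimming restricts to frames where the tip
moves more than 1 px/frame.

Collision parameters: contact_eps = 2 px (tip-to-wall contact),
delta_stationary = 1.5 px (tip motion bound between the two frames),
body_change_tau = 1 px mean per-vertex displacement after arc-length
resampling of the non-tip body to 50 vertices. All four clauses are literal;
maximal runs of qualifying consecutive pairs count as one episode. On
tracked (rather than simulated) video the per-frame wire polyline is
recovered by skeletonizing the binary mask and walking it from the tip to
the farthest connected pixel.

## Statistics

`two_sample_t` is the two-sided t-test, Welch by default (the pooled form is
selectable); two zero-variance samples with equal means give p = 1. The
within-group table compares the two difficulty levels per metric inside each
skill group; the between-group table compares the groups inside each level;
strata with fewer than two trials yield NaN cells rather than errors. No
multiple-testing correction is applied by default, matching a per-cell
α = 0.05 reading; Benjamini–Hochberg is available. Trials are the analysis
unit (unpaired across levels, not aggregated per surgeon) — a deliberate
simplification and a known limitation.

## Classifier

Features follow the fixed order (PT, CN, PL, SPN, SV_x, SV_y, VD, MF, MFV)
with VD encoded as its ordinal numeric. Scaling is fitted on the training
partition only. Min-max normalization to [0, 1] is the default: with
γ = 20 the RBF kernel width is about 0.22 in normalized units, a meaningful
neighborhood, whereas z-scored features at the same γ leave nearly every
pair of points at kernel ≈ 0 and the machine degenerates toward the majority
class (measured: 0.83 hold-out accuracy on a cohort that 1-nearest-neighbor
separates perfectly, versus 0.98 with min-max). z-scoring and no scaling
remain selectable. Splits and cross-validation folds are stratified by
ranking one uniform draw per trial within each class, which makes the
partition invariant to relabeling — swapping the class names provably flips
predictions without moving accuracy. Defaults: C = 0.8, γ = 20, 65/35
hold-out, k = 5 folds.

## Validation problem sizes

The test suite and `scripts/acceptance.py` validate at these sizes, chosen
to make the Monte-Carlo bands tight while a full run stays within a few
minutes on one CPU: 1000 random inputs per metric/oracle comparison
(tolerance 1e-9 relative for sums, exact for counts); 20 rendered trials
(pixel noise sd 2) for tracking recovery, asserting ≥ 99% of frames valid
with tip error ≤ 2 px; 200 novice trials for collision-rule recovery,
asserting exact episode-count agreement in ≥ 90% of trials; the 150-trial
default cohort for the SVM (hold-out ≥ 0.95; permuted-label mean accuracy
within [0.35, 0.65] over 50 seeds); 10,000 null replicates (n = 15 per arm)
for t-test calibration within [0.041, 0.059]; 500 random profiles for the
speed-peak affine invariance.

## Known limitations

- The tracker assumes one bright wire on a darker, roughly uniform
  background; it has no appearance model for occlusions or other devices.
- The collision rule needs wire-body shape evidence; with masks too noisy to
  skeletonize coherently, CN degrades before the other metrics do.
- Significance tables treat trials as independent; repeated measures per
  surgeon are not modeled.
- The classifier is validated on synthetic cohorts whose class separation is
  set by the simulator profiles; accuracy numbers characterize the pipeline,
  not human populations.
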