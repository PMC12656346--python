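# Methods

## The measure

Two swing clips are compared phase by phase. Within one phase, for one joint
and one coordinate, both clips contribute a trajectory; the dissimilarity is
the area between the two curves,

    DS = ∫₀¹ |x_A(u) − x_B(u)| du,

evaluated by the trapezoidal rule on a shared uniform grid of M samples
(default M = 100), which is O(N) in the trajectory length and is an L1
metric on the sampled curves (non-negative, symmetric, triangle inequality,
zero iff the samples coincide).

Each phase's time axis is rescaled to unit length before integration. This
is a deliberate choice: integrating over raw seconds would make a slow
backswing look dissimilar to an identically *shaped* fast backswing, mixing
tempo into a measure meant to capture path geometry. Phase boundaries
already encode timing, and tempo can be read off them directly, so the
per-phase unit-time convention separates the two effects. A config flag
(`time_normalize`) restores raw-time integration.

Per-joint DS is the mean of the x-area and y-area. We compare coordinates
one-dimensionally rather than computing a 2D area between parametric curves
because the latter is ill-defined for self-intersecting paths — and a swing's
hand path self-intersects by design. Joint scores are combined by
non-negative weights (uniform default; a preset emphasizing hands ×2 and
hips ×1.5 reflects their biomechanical leverage, with trunk posture handled
by the separate spine-angle channel, since no 2D landmark set has a spine
point). The bounded similarity is s = 1/(1 + DS/λ) with λ = 1 by default:
monotone, s(0) = 1, and λ is interpretable as the DS at which similarity
halves.

Crucially, each clip is segmented with its **own** phase boundaries and no
cross-clip frame alignment is ever performed; the unit-time rescaling within
matching phases absorbs natural timing variation that frame-aligned measures
must warp away.

## Preprocessing

- **Body-scale normalization.** All coordinates are divided by the mean
  left–right shoulder distance over the address region (first 10 % of frames
  when segmentation has not yet run; this breaks the circular dependency
  between normalization and segmentation). The result is scale-free:
  doubling the pixel resolution of either clip changes DS by < 1e-6.
- **Smoothing.** Centered moving average, default window 5 frames at 30 fps;
  edges use shrunken windows rather than padding, so no data is invented at
  clip boundaries where the pose is static anyway. The filter never widens
  the signal's range.
- **Resampling.** Trajectories are resampled on uniform grids by a
  not-a-knot cubic spline (default). A monotone-preserving PCHIP variant is
  available (`interpolation="pchip"`), but it is not the default because its
  derivative clipping at local extrema makes its worst-case error on smooth
  oscillatory signals equal to plain linear interpolation — measured on a
  30 Hz-sampled sine, PCHIP and linear both err by 5.5e-3 while the cubic
  spline errs by 1.2e-5. Endpoints are reproduced exactly; linear
  interpolation is the automatic fallback below 4 samples.
- **Swing-window cropping.** A raw recording is trimmed to
  [onset − 2 s, onset + 1 s], clamped to the clip. Onset = first frame at
  which the smoothed lead-wrist speed exceeds θ_v for ≥ 3 consecutive
  frames, with θ_v = 0.02 body-scale units per frame at 30 fps (converted
  internally to 0.6 units/s, making it frame-rate independent). In the
  automatic pipeline, cropping is applied only when the clip is longer than
  the 3 s window *and* carries more than 2 s of lead-in before the onset;
  an already-trimmed swing clip passes through unchanged, because the fixed
  1 s post-onset budget would otherwise truncate the follow-through of any
  full swing measured from its takeaway.
- **Address alignment.** Each clip is translated so its mean address mid-hip
  sits at the origin, synchronizing starting postures; relative geometry is
  untouched, making DS invariant to global translation.

## Phase segmentation

Seven phases are delimited by eight strictly increasing boundaries
b0 … b7; phase k is [b_k, b_{k+1}). Events are read off the smoothed
lead-wrist trajectory (image coordinates, y down):

1. takeaway: first sustained speed above θ_v;
2. half: first backswing frame with the wrist at or above the per-frame lead
   shoulder height (per-frame, not the address value, to tolerate vertical
   body drift);
3. top: an *interval* — the contiguous region of speed below θ_top = θ_v/2
   around the wrist's highest point between the half event and the downswing
   speed peak. Treating the top as an interval keeps all seven phases
   non-empty, as the partition requires;
4. impact: lowest wrist point after the top region;
5. release: first post-impact frame with the wrist back above shoulder
   height;
6. finish: everything to the clip end.

Ties at extrema resolve to the earliest frame (determinism). Left-handed
clips simply use the right wrist/shoulder as the lead side; the grammar uses
only y and speed, both mirror-invariant.

One numerical subtlety: a centered moving average of half-width h smears
every motion edge outward by h frames — onsets appear h frames early and the
low-speed top region appears shrunk by h on each side. Detected onset and
top-region edges are therefore corrected by the half-width of the smoothing
the sequence carries (recorded by the smoothing step in sequence metadata).
Without the correction, boundary estimates carry a systematic 2-frame bias
at the default window; with it, noiseless synthetic swings are recovered to
±1 frame.

## Baselines

- **DTW + cosine**: frame-wise motion vectors (concatenated per-joint
  coordinate deltas) aligned by standard DP dynamic time warping (steps
  (1,0), (0,1), (1,1), Euclidean local cost); the score is the mean cosine
  over aligned pairs. Pairs in which either vector's norm is below 1e-9 are
  skipped rather than defining a cosine with a zero vector; an all-static
  clip is an error.
- **Euclidean**: mean per-frame pose-vector distance after resampling both
  clips to the shorter one's length, normalized by √(n_joints) so that a
  constant global offset d yields DS = d, then mapped through the similarity
  map.
- **Phase-wise Pearson**: mean correlation over joints/coordinates of
  per-phase resampled trajectories; constant channels are excluded with a
  warning (undefined correlation), and the score is an error only if every
  channel is constant.
- **Joint angles**: interior angles at the elbows (shoulder–elbow–wrist) and
  shoulders (hip–shoulder–elbow); DS = mean absolute angular difference in
  radians, mapped with λ = π/6 (a 30° mean error halves the similarity).
  Translation- and scale-invariant by construction.

## Biomechanical diagnostics

The spine surrogate is the mid-hip→mid-shoulder segment; its angle to the
image vertical (degrees, 0 = upright) tracks trunk tilt. The spine-angle
delta between two clips is the area between their unit-time spine-angle
curves over takeaway-through-impact — the region where trunk stability
matters; including the finish pose would let terminal posture dominate. The
region is configurable.

The matched-frame analysis selects, in the backswing (takeaway+half) and in
the downswing (impact+release), the frame whose tracked-joint height is
closest to a reference (lead-shoulder height by default; a match farther
than 0.1 units is an error). At those two equal-height frames it compares
the lateral hand-path magnitude |x − mid-shoulder x| — the hand's distance
from the trunk axis, deliberately measured per frame so trunk sway does not
masquerade as a plane difference. A downswing passing wider than the
backswing marks a hand path dropping under/outside the backswing
(`backswing_lower`); the converse is `downswing_lower`; differences below
0.01 units (below pose-estimator jitter) are `indeterminate`.

## Synthetic data

The generator emulates what a pose estimator reports for a side-view swing;
it is the test bed for every end-to-end property, so its construction
matters:

- Static legs and hips; shoulder width exactly 1 body unit (so the
  normalization target is known); trunk tilt 8° with a configurable
  sinusoidal sway (default ±2°) over the swing.
- Wrists ride a circular arc of radius 1.8 units about the mid-shoulder
  pivot. The angular schedule is C¹ piecewise-cubic through the phase
  boundaries: zero angular velocity at rest, at the top reversal and in the
  final pose, but *nonzero* velocity at the interior boundaries, so the
  shoulder-height crossings that define the half and release events are
  transversal exactly at the parametric phase transitions — this is what
  makes the emitted ground-truth boundaries recoverable to ±1 frame. The top
  phase is a low-speed recoil bump (amplitude 0.006 rad), below θ_top
  throughout.
- `top_height` (wrist rise from address to top) defaults to 2.3 units. It
  must exceed the arc radius, otherwise the top of the swing stays below the
  shoulder line and no shoulder-crossing grammar can segment the swing; the
  constructor enforces `arc_radius < top_height < 1.95 × arc_radius`.
- `plane_offset` widens (+) or narrows (−) the *downswing* arc radius,
  ramping in smoothly over the first 18 % of the downswing (complete before
  the trail-side shoulder crossing) and persisting through the finish. A
  positive offset produces the wider downswing associated with amateur
  swings (`backswing_lower` at matched heights); negative, the
  professional-like inside path. A pure translation of the downswing would
  be invisible to the matched-frame analysis (both paths still cross the
  reference height), which is why the offset is radial.
- Default phase durations (0.5, 0.3, 0.25, 0.15, 0.25, 0.3, 0.55 s) give a
  2.3 s swing; static lead-in and hold-out padding of 0.35 s each make the
  default clip exactly 3 s = 90 frames at 30 fps, the typical practice-range
  clip length. `tempo_ratio` is None by default (durations are
  authoritative; the defaults imply backswing:downswing = 2.8); setting it
  rescales the downswing duration.
- Gaussian jitter (default σ = 0.01 units ≈ 1 % of shoulder width, a
  realistic pose-estimator noise floor) is added to every coordinate from a
  generator seeded by the style's seed: clips are bit-reproducible.
- `sample_player` draws same-player repeats by perturbing style parameters
  multiplicatively (default s.d. 5 %, clipped at ±3 s.d.), so same-base
  clips are statistically closer than cross-base clips.

What the generator does **not** emulate: occlusion and tracking dropouts
beyond brief gaps, camera motion, perspective foreshortening, club and ball,
correlated (non-Gaussian) pose-estimator error, and genuinely human
kinematic variability (it has one arc geometry family). Passing tests
therefore demonstrate that the pipeline recovers what it is designed to
recover under controlled conditions — not field accuracy on real video.

## Evaluation protocol

All unordered clip pairs are scored (self-pairs excluded); pairs are classed
same-player or cross-player. The separation is mean(cross DS) − mean(same
DS). The two classes are independent samples of unequal size, so the class
contrast uses Welch's t, with per-class Shapiro–Wilk normality checks
(skipped with a warning below 3 values), Cohen's d on the pooled s.d., and a
seeded percentile bootstrap (default 2000 resamples) for the 95 % CI of the
separation. Method-vs-method contrasts *are* paired — identical clip pairs
scored by each method — and use the paired t-test on per-pair similarities.
Clips that fail preprocessing or segmentation are excluded with a logged
reason rather than failing the batch, mirroring real practice-range data
quality.

The built-in benchmark generates 8 synthetic players × 4 clips (496 pairs)
at within-player s.d. 5 % and σ = 0.01 jitter — a scale chosen to mirror a
small practice-range dataset while keeping the full suite fast.

## Numerical choices and degenerate inputs

- Trapezoid grids must match exactly (length and spacing); mismatches are
  caller errors, not silently resampled.
- Dropouts of ≤ 3 consecutive frames per joint are linearly interpolated on
  read; longer gaps (or gaps touching the clip edge) are errors.
- Shoulder width below 1e-6 of the image diagonal, coincident mid-hip and
  mid-shoulder, and zero-length limb segments raise degenerate-skeleton
  errors rather than producing NaN geometry.
- Phase slices may legitimately hold a single frame (a momentary phase);
  similarity code treats such a slice as a constant trajectory.
- fps metadata must agree with the median frame interval within 5 %.

## Known limitations

- The segmentation grammar presumes a full swing containing all seven
  phases; chips, punch shots, or clips cut before the finish fail with a
  named missing event rather than degrading gracefully.
- The rule-based boundary detector is tuned for 30–60 fps side views; very
  low frame rates make the 3-frame sustain test coarse.
- The similarity scale λ = 1 is a convention, not a calibration; absolute
  similarity values are comparable within a configuration, not across
  different joint sets or weights.
- 2D side-view geometry only: out-of-plane rotation is invisible, and the
  spine surrogate conflates lateral bend with flexion.
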