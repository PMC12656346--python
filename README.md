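# dmsm — phase-wise dynamic motion similarity for golf swings

`dmsm` compares side-view golf swings recorded as 2D pose-keypoint sequences
(e.g. BlazePose/MediaPipe output). Conventional similarity measures compare
static postures frame by frame — even after DTW alignment — and therefore
miss the thing golfers and coaches actually judge: the *shape and flow* of
the motion within each part of the swing. This package implements a Dynamic
Motion Similarity Measurement: it segments each swing into the seven
canonical phases (address, takeaway, half, top, impact, release, finish) and
integrates trajectory differences within each phase, so two swings are
compared path against path rather than frame against frame.

For two clips, each joint coordinate's trajectory x(t), y(t) is compared per
phase by the area between the curves,

```
DS = ∫ |x_A(t) − x_B(t)| dt           (trapezoidal rule, O(N))
```

after body-scale normalization (coordinates divided by the address-phase
shoulder width), smoothing, address alignment, and rescaling of each phase
to unit time so tempo differences are not conflated with path differences.
Per-joint areas are weight-averaged into a phase dissimilarity and mapped to
a bounded similarity `s = 1/(1 + DS/λ)`.

The package also provides:

- **phases** — rule-based seven-phase segmentation from lead-wrist
  kinematics (speed threshold for takeaway, shoulder-height crossings,
  low-speed top region, lowest-point impact);
- **baselines** — DTW-aligned cosine similarity of motion vectors, Euclidean
  pose distance, phase-wise Pearson correlation, interior joint-angle
  similarity;
- **biomech** — spine-angle (mid-hip→mid-shoulder tilt) trajectories, the
  area Δ between two clips' spine-angle curves, and matched
  backswing/downswing frame analysis of the hand path;
- **synth** — a deterministic synthetic swing generator with ground-truth
  phase boundaries and controllable style (arc geometry, tempo, swing-plane
  offset, spine sway, jitter), used throughout the tests;
- **evaluation** — batch all-pairs comparison with same-player vs
  cross-player separation statistics (Welch t, Shapiro–Wilk, Cohen's d,
  seeded percentile-bootstrap CI).

## Worked example

Generate two synthetic players and compare a pair of their swings:

```python
from dmsm import SwingStyle, generate_swing, dmsm_compare

pro = generate_swing(SwingStyle(plane_offset=-0.08, seed=1)).sequence
amateur = generate_swing(
    SwingStyle(arc_radius=1.5, top_height=2.0, plane_offset=0.08, seed=3)
).sequence

report = dmsm_compare(pro, amateur)
print(f"overall similarity {report.overall_similarity:.3f}  "
      f"overall DS {report.overall_DS:.4f}")
for score in report.phase_scores:
    print(f"{score.phase_name:9s} DS={score.weighted_DS:.4f} "
          f"similarity={score.similarity:.3f}")
```

Output:

```
overall similarity 0.946  overall DS 0.0572
address   DS=0.0609 similarity=0.943
takeaway  DS=0.0799 similarity=0.926
half      DS=0.0697 similarity=0.935
top       DS=0.0666 similarity=0.938
impact    DS=0.0446 similarity=0.957
release   DS=0.0361 similarity=0.965
finish    DS=0.0429 similarity=0.959
```

The per-phase scores localize the disagreement: the two styles differ most
through the backswing (takeaway–top), where the shorter amateur arc and the
opposite swing-plane offset pull the hand paths apart. Comparing the same
clip against a same-style repeat instead yields an overall DS of ≈ 0.007, an
order of magnitude closer.

The same pipeline is available from the shell:

```
dmsm synth --style pro --n 6 --seed 42 --out clips/
dmsm compare clips/pro-0.csv clips/pro-1.csv --method dmsm
dmsm eval --manifest clips/manifest.tsv --methods dmsm,dtw_cosine --out results/
```

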