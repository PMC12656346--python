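"""Spine-angle trajectories and matched backswing/downswing frame analysis.

No 2D landmark set carries an explicit spine point, so the standard surrogate
is used: the mid-hip → mid-shoulder segment. Its angle to the image vertical
(degrees, 0 = upright) tracks trunk tilt through the swing; the area between
two clips' time-normalized spine-angle curves over the takeaway-through-
impact region summarizes postural stability differences.

The matched-frame analysis finds, on each side of the top of the swing, the
frame whose tracked-joint height is closest to a reference height (the lead
shoulder by default), then compares how far the hands travel laterally at
those matched heights: a downswing passing at greater lateral magnitude than
the backswing marks a hand path that drops *under* the backswing — the
pattern associated with professional swings — and vice versa for amateurs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSkeletonError, NoMatchError, ValidationError
from .io_pose import PoseSequence
from .phases import PhaseSegmentation, detect_phases
from .preprocess import PreprocessConfig, Trajectory, preprocess_sequence, resample_uniform
from .similarity import trajectory_area_dissimilarity

#: |Δ lateral magnitude| below which the two paths are indistinguishable
#: (body-scale units; below typical pose-estimator jitter).
INDETERMINATE_TOL = 0.01

#: Required closeness (body-scale units) of the best match to the reference.
MATCH_TOL = 0.1

#: Phases spanned by the spine-angle comparison: takeaway through impact.
DELTA_REGION = ("takeaway", "impact")


@dataclass(frozen=True)
class MatchedFramePair:
    """Backswing/downswing frames matched at a common height."""

    reference_height: float
    backswing_frame: int
    downswing_frame: int
    top_frame: int
    backswing_x: float
    downswing_x: float
    backswing_y: float
    downswing_y: float
    label: str

    def __post_init__(self) -> None:
        if not (self.backswing_frame < self.top_frame < self.downswing_frame):
            raise ValidationError(
                "matched frames must bracket the top: "
                f"{self.backswing_frame} < {self.top_frame} < {self.downswing_frame}"
            )
        if self.label not in ("backswing_lower", "downswing_lower", "indeterminate"):
            raise ValidationError(f"unknown label {self.label!r}")


def spine_angle_trajectory(seq: PoseSequence) -> Trajectory:
    """Per-frame angle of the mid-hip→mid-shoulder segment to the vertical.

    Degrees in [0, 180); 0 means upright. Invariant to translation and
    uniform scaling, so raw pixel clips are fine.
    """
    v = seq.midpoint("left_shoulder", "right_shoulder") - seq.midpoint("left_hip", "right_hip")
    norm = np.linalg.norm(v, axis=1)
    if np.any(norm < 1e-9):
        raise DegenerateSkeletonError("mid-hip and mid-shoulder coincide")
    # up direction in image coordinates is (0, -1)
    cosang = np.clip(-v[:, 1] / norm, -1.0, 1.0)
    deg = np.degrees(np.arccos(cosang))
    dt = float(np.median(np.diff(seq.times)))
    return Trajectory(deg, t0=float(seq.times[0]), dt=dt)


def _segmented(seq: PoseSequence, seg, cfg) -> tuple[PoseSequence, PhaseSegmentation]:
    cfg = cfg or PreprocessConfig()
    if seq.units != "body_scale":
        seq = preprocess_sequence(seq, cfg)
    if seg is None:
        seg = detect_phases(seq, cfg)
    return seq, seg


def spine_angle_delta(
    seq_a: PoseSequence,
    seq_b: PoseSequence,
    seg_a: PhaseSegmentation | None = None,
    seg_b: PhaseSegmentation | None = None,
    cfg: PreprocessConfig | None = None,
    n_samples: int = 100,
) -> float:
    """Area between the two spine-angle curves (degrees x unit time).

    Each clip's takeaway-through-impact region is rescaled to [0, 1] and the
    absolute angle difference integrated; symmetric, zero iff the curves
    coincide on the common grid.
    """
    vals = []
    for seq, seg in ((seq_a, seg_a), (seq_b, seg_b)):
        seq, seg = _segmented(seq, seg, cfg)
        lo = seg.phase_range(DELTA_REGION[0])[0]
        hi = seg.phase_range(DELTA_REGION[1])[1]
        ang = spine_angle_trajectory(seq.slice_frames(lo, hi))
        tr = resample_uniform(Trajectory(ang.values, 0.0, 1.0 / (len(ang) - 1)), n_samples)
        vals.append(tr)
    return trajectory_area_dissimilarity(vals[0], vals[1])


def matched_frame_analysis(
    seq: PoseSequence,
    joint: str | None = None,
    reference: str | float = "shoulder_height",
    seg: PhaseSegmentation | None = None,
    cfg: PreprocessConfig | None = None,
) -> MatchedFramePair:
    """Match backswing and downswing frames at a common joint height.

    The backswing search region spans takeaway+half, the downswing region
    spans impact+release (both half-open); within each, the frame whose
    joint y is closest to the reference height is selected. The label
    compares the lateral hand-path magnitude — |x − mid-shoulder x| at the
    matched frame, i.e. the hand's distance from the trunk axis, which is
    insensitive to trunk sway — at the two matched frames: greater downswing
    magnitude means the downswing passes outside/under the backswing
    ("backswing_lower"), the converse "downswing_lower"; differences below
    0.01 body-scale units are "indeterminate". The matched y values are
    reported as well.
    """
    seq, seg = _segmented(seq, seg, cfg)
    joint = joint or seq.lead_wrist
    xy = seq.xy(joint)
    if isinstance(reference, str):
        if reference != "shoulder_height":
            raise ValidationError(f"unknown reference {reference!r}")
        b1, b6 = seg.phase_range("takeaway")[0], seg.phase_range("release")[1]
        ref = float(np.mean(seq.xy(seq.lead_shoulder)[b1:b6, 1]))
    else:
        ref = float(reference)

    back_lo, back_hi = seg.phase_range("takeaway")[0], seg.phase_range("half")[1]
    down_lo, down_hi = seg.phase_range("impact")[0], seg.phase_range("release")[1]
    top_lo, top_hi = seg.phase_range("top")

    def closest(lo: int, hi: int, region: str) -> int:
        dev = np.abs(xy[lo:hi, 1] - ref)
        i = int(np.argmin(dev))
        if dev[i] > MATCH_TOL:
            raise NoMatchError(
                f"{region}: joint {joint!r} never approaches the reference height "
                f"{ref:.3f} within {MATCH_TOL} (closest {dev[i]:.3f})"
            )
        return lo + i

    b_frame = closest(back_lo, back_hi, "backswing")
    d_frame = closest(down_lo, down_hi, "downswing")
    top_frame = top_lo + int(np.argmin(xy[top_lo:top_hi, 1]))

    trunk_x = seq.midpoint("left_shoulder", "right_shoulder")[:, 0]
    mag_b = abs(float(xy[b_frame, 0] - trunk_x[b_frame]))
    mag_d = abs(float(xy[d_frame, 0] - trunk_x[d_frame]))
    if abs(mag_d - mag_b) < INDETERMINATE_TOL:
        label = "indeterminate"
    elif mag_d > mag_b:
        label = "backswing_lower"
    else:
        label = "downswing_lower"
    return MatchedFramePair(
        reference_height=ref,
        backswing_frame=b_frame,
        downswing_frame=d_frame,
        top_frame=top_frame,
        backswing_x=float(xy[b_frame, 0]),
        downswing_x=float(xy[d_frame, 0]),
        backswing_y=float(xy[b_frame, 1]),
        downswing_y=float(xy[d_frame, 1]),
        label=label,
    )
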