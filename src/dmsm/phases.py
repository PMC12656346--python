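"""Seven-phase swing segmentation from lead-wrist kinematics.

The seven canonical phases — address, takeaway, half, top, impact, release,
finish — are delimited by eight strictly increasing frame indices
``b0..b7``; phase *k* spans the half-open interval ``[b_k, b_{k+1})``.

Events are read off the smoothed lead-wrist trajectory (image coordinates,
y down, so "above the shoulder" means smaller y):

* takeaway onset: first sustained speed above the onset threshold;
* half: first backswing frame with the wrist at/above the lead shoulder;
* top: the contiguous low-speed region around the wrist's highest point
  between the half event and the downswing speed peak — an *interval*, so
  every phase is non-empty;
* impact: the lowest wrist point after the top region;
* release: first post-impact frame with the wrist back above the shoulder;
* finish: everything up to the clip end.

Ties at extrema resolve to the earliest frame for determinism. Left-handed
clips use the right wrist/shoulder as the lead side; no mirroring is needed
because only y and speed enter the event grammar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SegmentationError, ValidationError
from .io_pose import PoseSequence
from .preprocess import PreprocessConfig, lead_wrist_speed, ONSET_SUSTAIN_FRAMES

PHASE_NAMES: tuple[str, ...] = (
    "address",
    "takeaway",
    "half",
    "top",
    "impact",
    "release",
    "finish",
)

#: Top-of-swing speed threshold as a fraction of the onset threshold.
TOP_SPEED_FRACTION = 0.5


@dataclass(frozen=True)
class PhaseSegmentation:
    """Eight ordered boundary indices defining the seven phases."""

    boundaries: tuple[int, ...]
    phase_names: tuple[str, ...] = PHASE_NAMES

    def __post_init__(self) -> None:
        b = tuple(int(x) for x in self.boundaries)
        object.__setattr__(self, "boundaries", b)
        if len(b) != 8:
            raise ValidationError(f"expected 8 boundaries, got {len(b)}")
        if b[0] < 0:
            raise ValidationError("b0 must be >= 0")
        if any(b[i + 1] <= b[i] for i in range(7)):
            raise ValidationError(f"boundaries must be strictly increasing: {b}")

    def phase_range(self, name: str) -> tuple[int, int]:
        k = self.phase_names.index(name)
        return self.boundaries[k], self.boundaries[k + 1]

    def validate_for(self, seq: PoseSequence) -> None:
        if self.boundaries[-1] > seq.n_frames:
            raise ValidationError(
                f"b7={self.boundaries[-1]} exceeds clip length {seq.n_frames}"
            )

    def to_dict(self) -> dict:
        return {"boundaries": list(self.boundaries), "phase_names": list(self.phase_names)}


def detect_phases(
    seq: PoseSequence, cfg: PreprocessConfig | None = None
) -> PhaseSegmentation:
    """Segment a preprocessed (normalized, smoothed) swing into seven phases."""
    cfg = cfg or PreprocessConfig()
    if seq.units != "body_scale":
        raise ValidationError("detect_phases expects a body-scale normalized sequence")
    n = seq.n_frames
    wrist_y = seq.xy(seq.lead_wrist)[:, 1]
    shoulder_y = seq.xy(seq.lead_shoulder)[:, 1]
    speed = lead_wrist_speed(seq, window=1)  # sequence is already smoothed
    theta_v = cfg.onset_speed * 30.0
    theta_top = TOP_SPEED_FRACTION * theta_v

    # A centered moving average of half-width h smears every motion edge by
    # h frames: onsets appear h frames early and the quiet region at the top
    # appears shrunk by h on each side. The detected edges are corrected by
    # the half-width of the smoothing the preprocessed input carries.
    h = (seq.meta.get("smoothed_window", cfg.smoothing_window) - 1) // 2

    # E_takeaway: first sustained speed above threshold
    above = speed > theta_v
    k = ONSET_SUSTAIN_FRAMES
    sustained = np.convolve(above.astype(int), np.ones(k, dtype=int), mode="valid") == k
    hits = np.flatnonzero(sustained)
    if len(hits) == 0:
        raise SegmentationError("takeaway")
    b1 = int(hits[0]) + h
    if b1 < 1 or b1 >= n - 1:
        raise SegmentationError("takeaway", "swing starts at the clip edge")

    # E_half: first backswing frame with wrist at/above shoulder height
    half_hits = np.flatnonzero(wrist_y[b1:] <= shoulder_y[b1:])
    if len(half_hits) == 0:
        raise SegmentationError("half")
    b2 = b1 + int(half_hits[0])

    # downswing speed peak bounds the backswing search
    i_vmax = b2 + int(np.argmax(speed[b2:]))

    # E_top: highest wrist point (smallest y) between half and the speed peak
    hi = max(i_vmax, b2 + 1)
    e_top = b2 + int(np.argmin(wrist_y[b2 : hi + 1]))

    # top region: contiguous sub-threshold speed frames around E_top
    lo = e_top
    while lo - 1 > b2 and speed[lo - 1] < theta_top:
        lo -= 1
    hi_top = e_top
    while hi_top + 1 < n - 1 and speed[hi_top + 1] < theta_top:
        hi_top += 1
    b3 = max(lo - h, b2 + 1)
    b4 = min(hi_top + 1 + h, n - 2)
    if b4 <= b3:
        b4 = b3 + 1
    if b3 <= b2:
        raise SegmentationError("top", "top region collides with the half event")

    # E_impact: lowest wrist point after the top region
    if b4 >= n:
        raise SegmentationError("impact")
    b5 = b4 + int(np.argmax(wrist_y[b4:]))
    if b5 <= b4:
        raise SegmentationError("impact", "no downswing after the top region")

    # E_release: first post-impact frame with wrist back above shoulder height
    rel_hits = np.flatnonzero(wrist_y[b5 + 1 :] <= shoulder_y[b5 + 1 :])
    if len(rel_hits) == 0:
        raise SegmentationError("release")
    b6 = b5 + 1 + int(rel_hits[0])
    if b6 >= n:
        raise SegmentationError("finish", "release event at the clip end leaves no finish")

    try:
        return PhaseSegmentation((0, b1, b2, b3, b4, b5, b6, n))
    except ValidationError as exc:
        raise SegmentationError("ordering", str(exc)) from exc


@dataclass(frozen=True)
class PhaseSlice:
    """One phase's frames, cut from a parent sequence.

    Unlike a full PoseSequence a slice may hold a single frame (a genuinely
    momentary phase); similarity code treats such a slice as a constant
    trajectory.
    """

    name: str
    start: int
    stop: int
    times: np.ndarray
    coords: np.ndarray
    joints: tuple[str, ...]
    handedness: str

    @property
    def n_frames(self) -> int:
        return self.stop - self.start

    def xy(self, joint: str) -> np.ndarray:
        try:
            k = self.joints.index(joint)
        except ValueError:
            raise ValidationError(f"joint {joint!r} not present") from None
        return self.coords[:, k, :]


def phase_slices(seq: PoseSequence, seg: PhaseSegmentation) -> list[PhaseSlice]:
    """Cut the clip into the seven named phase slices, in canonical order.

    The slices partition the clip exactly: they are disjoint and their
    concatenation reproduces the input frame for frame.
    """
    seg.validate_for(seq)
    if seg.boundaries[0] != 0 or seg.boundaries[-1] != seq.n_frames:
        raise ValidationError("segmentation does not span the clip")
    out = []
    for name in seg.phase_names:
        lo, hi = seg.phase_range(name)
        out.append(
            PhaseSlice(
                name=name,
                start=lo,
                stop=hi,
                times=seq.times[lo:hi].copy(),
                coords=seq.coords[lo:hi].copy(),
                joints=seq.joints,
                handedness=seq.handedness,
            )
        )
    return out
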