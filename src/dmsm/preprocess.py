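"""Body-scale normalization, smoothing, resampling, alignment and cropping.

All geometry lives in image coordinates (y down). Body-scale normalization
divides every coordinate by the subject's shoulder width measured during the
address phase, so downstream dissimilarities are in shoulder-width units and
directly comparable across players and camera zooms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

from .errors import (
    ContractError,
    DegenerateSkeletonError,
    NoSwingDetectedError,
    ParameterError,
    ValidationError,
)
from .io_pose import PoseSequence

#: Lead-wrist speed threshold for swing onset, expressed as body-scale units
#: per frame at 30 fps. Internally converted to units/second (x30), which
#: makes the threshold frame-rate independent.
ONSET_SPEED_PER_FRAME_30FPS = 0.02

#: Frames the onset speed must stay above threshold to count as takeaway.
ONSET_SUSTAIN_FRAMES = 3

#: Fraction of the clip treated as the address phase when no segmentation
#: is available yet (breaks the normalization <-> segmentation circularity).
ADDRESS_FRACTION = 0.10


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled 1D signal: one joint, one coordinate (or an angle).

    ``values`` are body-scale units or degrees; samples sit at
    ``t0 + i * dt``.
    """

    values: np.ndarray
    t0: float = 0.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ValidationError("trajectory needs at least 2 one-dimensional samples")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("trajectory contains non-finite values")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.values))

    @property
    def duration(self) -> float:
        return self.dt * (len(self.values) - 1)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PreprocessConfig:
    """Tunable preprocessing parameters.

    smoothing_window
        Centered moving-average width in frames; odd; 5 suppresses
        pose-estimator jitter at 30 fps without flattening the top.
    resample_hz
        Target uniform rate for trajectory densification (4x a 30 fps source).
    interpolation
        ``cubic`` (not-a-knot spline) or ``pchip`` (monotone-preserving) or
        ``linear``.
    crop_before_s / crop_after_s
        Swing window relative to the detected onset.
    onset_speed
        Lead-wrist onset threshold, body-scale units per frame at 30 fps.
    """

    smoothing_window: int = 5
    resample_hz: float = 120.0
    body_scale_reference: str = "shoulder_width"
    interpolation: str = "cubic"
    crop_before_s: float = 2.0
    crop_after_s: float = 1.0
    onset_speed: float = ONSET_SPEED_PER_FRAME_30FPS

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ParameterError("smoothing_window must be odd and >= 1")
        if self.resample_hz <= 0:
            raise ParameterError("resample_hz must be positive")
        if self.interpolation not in ("cubic", "pchip", "linear"):
            raise ParameterError(f"unknown interpolation {self.interpolation!r}")
        if self.body_scale_reference != "shoulder_width":
            raise ParameterError("only shoulder_width body-scale reference is supported")


# ---------------------------------------------------------------------------
# body-scale normalization


def _address_slice(seq: PoseSequence, address_end: int | None = None) -> slice:
    if address_end is not None:
        return slice(0, max(2, address_end))
    return slice(0, max(2, int(np.ceil(ADDRESS_FRACTION * seq.n_frames))))


def shoulder_width(seq: PoseSequence, address_end: int | None = None) -> float:
    """Mean left-right shoulder distance over the address region."""
    sl = _address_slice(seq, address_end)
    d = np.linalg.norm(seq.xy("left_shoulder")[sl] - seq.xy("right_shoulder")[sl], axis=1)
    return float(np.mean(d))


def normalize_body_scale(seq: PoseSequence, address_end: int | None = None) -> PoseSequence:
    """Divide all coordinates by the address-phase shoulder width.

    Idempotent up to floating point: applying it to an already-normalized
    sequence rescales by a factor ~1. Translation is left untouched.
    """
    scale = shoulder_width(seq, address_end)
    span = seq.coords.reshape(-1, 2)
    diag = float(np.linalg.norm(span.max(axis=0) - span.min(axis=0)))
    if scale < 1e-6 * max(diag, 1.0):
        raise DegenerateSkeletonError(
            f"shoulder width {scale:.3g} is degenerate relative to the image extent"
        )
    out = seq.copy()
    out.coords = out.coords / scale
    out.units = "body_scale"
    return out


# ---------------------------------------------------------------------------
# smoothing


def smooth_moving_average(traj: Trajectory, window: int) -> Trajectory:
    """Centered moving average; edge frames average over the samples available.

    Window must be odd so the filter is phase-neutral. ``window=1`` is the
    identity.
    """
    if window % 2 == 0:
        raise ParameterError("smoothing window must be odd")
    if window < 1:
        raise ParameterError("smoothing window must be >= 1")
    if window > len(traj):
        raise ParameterError("smoothing window exceeds trajectory length")
    return Trajectory(_smooth_values(traj.values, window), traj.t0, traj.dt)


def _smooth_values(values: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return values.astype(float, copy=True)
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values, dtype=float)))
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)


def smooth_sequence(seq: PoseSequence, window: int) -> PoseSequence:
    """Apply the moving average to every joint coordinate of a sequence."""
    if window % 2 == 0:
        raise ParameterError("smoothing window must be odd")
    if window > seq.n_frames:
        raise ParameterError("smoothing window exceeds clip length")
    out = seq.copy()
    for k in range(len(seq.joints)):
        for c in range(2):
            out.coords[:, k, c] = _smooth_values(seq.coords[:, k, c], window)
    out.meta["smoothed_window"] = window
    return out


# ---------------------------------------------------------------------------
# resampling


def _interpolator(times: np.ndarray, values: np.ndarray, kind: str):
    if kind == "cubic" and len(times) >= 4:
        return CubicSpline(times, values)
    if kind == "pchip" and len(times) >= 3:
        return PchipInterpolator(times, values)
    return lambda t: np.interp(t, times, values)


def resample_uniform(traj: Trajectory, n_samples: int, kind: str = "cubic") -> Trajectory:
    """Resample onto ``n_samples`` evenly spaced times spanning [t0, t_end].

    Piecewise-cubic by default; endpoints are reproduced exactly. Falls back
    to linear when too few samples exist for the requested kind.
    """
    if n_samples < 2:
        raise ParameterError("n_samples must be >= 2")
    if kind not in ("cubic", "pchip", "linear"):
        raise ParameterError(f"unknown interpolation {kind!r}")
    src_t = traj.times
    new_t = np.linspace(src_t[0], src_t[-1], n_samples)
    f = _interpolator(src_t, traj.values, kind)
    vals = np.asarray(f(new_t), dtype=float)
    vals[0], vals[-1] = traj.values[0], traj.values[-1]
    return Trajectory(vals, t0=traj.t0, dt=traj.duration / (n_samples - 1))


def resample_sequence(seq: PoseSequence, hz: float, kind: str = "cubic") -> PoseSequence:
    """Resample every joint trajectory onto a uniform grid at ``hz``.

    Densifies fast segments ahead of integration; the target rate must be at
    least the source frame rate (downsampling would discard motion detail).
    """
    if hz < seq.fps:
        raise ParameterError(f"resample rate {hz} below source fps {seq.fps}")
    n_new = int(round(seq.duration * hz)) + 1
    new_times = np.linspace(seq.times[0], seq.times[-1], n_new)
    coords = np.empty((n_new, len(seq.joints), 2))
    for k in range(len(seq.joints)):
        for c in range(2):
            f = _interpolator(seq.times, seq.coords[:, k, c], kind)
            coords[:, k, c] = f(new_times)
    out = seq.copy()
    out.times = new_times
    out.coords = coords
    out.confidence = None
    out.fps = (n_new - 1) / seq.duration
    out.validate()
    return out


# ---------------------------------------------------------------------------
# onset detection and cropping


def lead_wrist_speed(seq: PoseSequence, window: int = 5) -> np.ndarray:
    """Smoothed lead-wrist speed in body-scale units per second."""
    w = seq.xy(seq.lead_wrist)
    sm = np.column_stack([_smooth_values(w[:, 0], window), _smooth_values(w[:, 1], window)])
    vel = np.gradient(sm, seq.times, axis=0)
    return np.linalg.norm(vel, axis=1)


def detect_onset(seq: PoseSequence, cfg: PreprocessConfig | None = None) -> int:
    """First frame where lead-wrist speed stays above threshold for 3 frames."""
    cfg = cfg or PreprocessConfig()
    if seq.units != "body_scale":
        raise ContractError("onset detection expects a body-scale normalized sequence")
    # avoid re-smoothing an already smoothed sequence; either way correct the
    # onset for the filter's edge smear (half the window width)
    window = seq.meta.get("smoothed_window")
    if window is None:
        window = cfg.smoothing_window
        speed = lead_wrist_speed(seq, window)
    else:
        speed = lead_wrist_speed(seq, 1)
    thresh = cfg.onset_speed * 30.0  # units/s, frame-rate independent
    above = speed > thresh
    k = ONSET_SUSTAIN_FRAMES
    sustained = np.convolve(above.astype(int), np.ones(k, dtype=int), mode="valid") == k
    hits = np.flatnonzero(sustained)
    if len(hits) == 0:
        raise NoSwingDetectedError(
            f"lead-wrist speed never exceeds {thresh:.3g} units/s for {k} frames"
        )
    return min(int(hits[0]) + (window - 1) // 2, seq.n_frames - 1)


def crop_swing_window(seq: PoseSequence, cfg: PreprocessConfig | None = None) -> PoseSequence:
    """Trim to [onset - crop_before_s, onset + crop_after_s], clamped to the clip."""
    cfg = cfg or PreprocessConfig()
    onset = detect_onset(seq, cfg)
    t_on = seq.times[onset]
    t_lo = max(seq.times[0], t_on - cfg.crop_before_s)
    t_hi = min(seq.times[-1], t_on + cfg.crop_after_s)
    keep = np.flatnonzero((seq.times >= t_lo - 1e-12) & (seq.times <= t_hi + 1e-12))
    return seq.slice_frames(int(keep[0]), int(keep[-1]) + 1)


# ---------------------------------------------------------------------------
# address alignment


def _mid_hip_address(seq: PoseSequence, address_end: int | None) -> np.ndarray:
    if "left_hip" not in seq.joints or "right_hip" not in seq.joints:
        raise ValidationError("hip joints required for address alignment")
    sl = _address_slice(seq, address_end)
    return seq.midpoint("left_hip", "right_hip")[sl].mean(axis=0)


def center_address(seq: PoseSequence, address_end: int | None = None) -> PoseSequence:
    """Translate one sequence so its mean address mid-hip sits at the origin."""
    if seq.units != "body_scale":
        raise ContractError("address centering expects a body-scale normalized sequence")
    center = _mid_hip_address(seq, address_end)
    s = seq.copy()
    s.coords = s.coords - center
    return s


def align_address(
    seq_a: PoseSequence,
    seq_b: PoseSequence,
    address_end_a: int | None = None,
    address_end_b: int | None = None,
) -> tuple[PoseSequence, PoseSequence]:
    """Translate each sequence so its mean address mid-hip sits at the origin.

    Relative geometry is untouched; this synchronizes the starting posture of
    the two clips before any dynamic comparison.
    """
    return center_address(seq_a, address_end_a), center_address(seq_b, address_end_b)


def mirror_sequence(seq: PoseSequence) -> PoseSequence:
    """Exact x-reflection: mirror coordinates, swap left/right joints, flip flag."""
    out = seq.copy()
    cx = float(np.mean(seq.midpoint("left_hip", "right_hip")[:, 0]))
    out.coords = out.coords.copy()
    out.coords[:, :, 0] = 2.0 * cx - out.coords[:, :, 0]
    swapped = []
    for j in out.joints:
        if j.startswith("left_"):
            swapped.append("right_" + j[5:])
        elif j.startswith("right_"):
            swapped.append("left_" + j[6:])
        else:
            swapped.append(j)
    out.joints = tuple(swapped)
    out.handedness = "left" if seq.handedness == "right" else "right"
    return out


def preprocess_sequence(
    seq: PoseSequence,
    cfg: PreprocessConfig | None = None,
    crop: bool = "auto",  # type: ignore[assignment]
) -> PoseSequence:
    """normalize -> smooth -> (crop) convenience chain.

    ``crop="auto"`` crops only when the clip looks like an untrimmed
    recording: longer than the configured swing window *and* with more than
    ``crop_before_s`` of lead-in before the detected onset. Already-trimmed
    swing clips pass through unchanged.
    """
    cfg = cfg or PreprocessConfig()
    out = seq if seq.units == "body_scale" else normalize_body_scale(seq)
    out = smooth_sequence(out, cfg.smoothing_window)
    if crop is True:
        out = crop_swing_window(out, cfg)
    elif crop == "auto" and out.duration > cfg.crop_before_s + cfg.crop_after_s + 1e-9:
        try:
            onset = detect_onset(out, cfg)
        except NoSwingDetectedError:
            onset = None  # let segmentation report the failure downstream
        if onset is not None and out.times[onset] - out.times[0] > cfg.crop_before_s:
            out = crop_swing_window(out, cfg)
    return out
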