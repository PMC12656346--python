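"""Synthetic side-view swing generator with ground-truth phase boundaries.

The generator emulates what a pose estimator sees in a side-view swing clip:
a mostly static lower body, a torso whose spine tilt oscillates slightly,
and wrists sweeping a circular arc about the mid-shoulder pivot. The arc's
angular schedule is cosine-eased within each phase, which guarantees a
genuine low-speed reversal region at the top and a speed maximum
mid-downswing — exactly the cues the segmentation grammar keys on.

Conventions (image coordinates, y down, body-scale units before pixel
conversion): shoulder width is 1.0; the arc angle φ is 0 with the hands
hanging below the pivot, positive on the trail side (backswing), negative on
the target side (follow-through). ``plane_offset`` widens (+) or narrows (−)
the *downswing* arc radius relative to the backswing, reproducing the
amateur-vs-professional hand-path separation: a wider downswing arc passes
outside/below the backswing path at matched heights.

Every clip is deterministic given (style, fps): jitter comes from a
generator seeded by ``style.seed`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .io_pose import PoseSequence
from .phases import PhaseSegmentation
from .preprocess import mirror_sequence

#: Torso/limb geometry in shoulder-width units.
SHOULDER_HALF = 0.5
HIP_HALF = 0.35
TORSO_LEN = 1.4  # mid-hip to mid-shoulder
HEAD_OFFSET = 0.35
KNEE_Y, ANKLE_Y = 0.9, 1.8
ELBOW_BEND = 0.12
TRAIL_WRIST_OFFSET = np.array([0.05, 0.03])

#: Fraction of the downswing over which the plane offset ramps in (complete
#: before the wrist re-crosses shoulder height on the trail side).
PLANE_RAMP_FRACTION = 0.18

#: Angular recoil amplitude of the top phase (radians): small enough that
#: the wrist speed stays below the top threshold throughout the phase.
TOP_RECOIL_RAD = 0.006

#: Arm angle swept past the release event into the finish pose (radians).
FINISH_ANGLE_RAD = 2.0

#: Baseline forward spine tilt at address (degrees from vertical).
BASE_SPINE_TILT_DEG = 8.0


@dataclass(frozen=True)
class SwingStyle:
    """Parameter set of one synthetic swing style.

    phase_durations
        Seconds spent in (address, takeaway, half, top, impact, release,
        finish); defaults sum to 2.3 s of active swing.
    arc_radius
        Wrist arc radius about the mid-shoulder pivot (shoulder widths).
    top_height
        Wrist rise from address to the top (shoulder widths). Must exceed
        ``arc_radius`` so the top sits above the shoulder line, which the
        phase grammar requires.
    plane_offset
        Signed radial offset of the downswing arc; negative (narrower
        downswing, "inside" hand path) is professional-like, positive
        amateur-like.
    spine_sway_amp
        Peak spine-angle oscillation over the swing (degrees).
    tempo_ratio
        Backswing:downswing duration ratio; ``None`` leaves phase_durations
        authoritative, a number rescales the downswing duration.
    noise_sigma
        Gaussian jitter s.d. added to every coordinate (shoulder widths).
    lead_in_s / hold_out_s
        Static padding extending the address and finish phases so a default
        clip spans 3 s (90 frames at 30 fps).
    """

    phase_durations: tuple[float, ...] = (0.5, 0.3, 0.25, 0.15, 0.25, 0.3, 0.55)
    arc_radius: float = 1.8
    top_height: float = 2.3
    plane_offset: float = -0.08
    spine_sway_amp: float = 2.0
    tempo_ratio: float | None = None
    noise_sigma: float = 0.01
    seed: int = 0
    lead_in_s: float = 0.35
    hold_out_s: float = 0.35

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase_durations", tuple(float(d) for d in self.phase_durations))
        if len(self.phase_durations) != 7 or any(d <= 0 for d in self.phase_durations):
            raise ParameterError("phase_durations must be 7 positive values")
        if self.arc_radius <= 0:
            raise ParameterError("arc_radius must be positive")
        if not (1.05 * self.arc_radius < self.top_height < 1.95 * self.arc_radius):
            raise ParameterError(
                "top_height must lie in (1.05, 1.95) x arc_radius so the top "
                "of the swing clears the shoulder line"
            )
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be non-negative")
        if self.tempo_ratio is not None and self.tempo_ratio <= 0:
            raise ParameterError("tempo_ratio must be positive")
        if self.lead_in_s < 0 or self.hold_out_s < 0:
            raise ParameterError("padding durations must be non-negative")

    @property
    def effective_durations(self) -> tuple[float, ...]:
        d = list(self.phase_durations)
        if self.tempo_ratio is not None:
            d[4] = (d[1] + d[2] + d[3]) / self.tempo_ratio
        return tuple(d)


@dataclass
class SyntheticClip:
    sequence: PoseSequence
    truth_boundaries: tuple[int, ...]
    style: SwingStyle

    def __post_init__(self) -> None:
        PhaseSegmentation(self.truth_boundaries)  # enforce the invariants


def _smoothstep(z: np.ndarray) -> np.ndarray:
    z = np.clip(z, 0.0, 1.0)
    return z * z * (3.0 - 2.0 * z)


def _interior_slope(h1: float, h2: float, s1: float, s2: float) -> float:
    """Weighted harmonic mean of adjacent secant slopes (shape-preserving)."""
    if s1 * s2 <= 0:
        return 0.0
    w1, w2 = 2.0 * h2 + h1, 2.0 * h1 + h2
    return (w1 + w2) / (w1 / s1 + w2 / s2)


def _arc_schedule(style: SwingStyle, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Arc angle φ(t) and effective radius r(t) for frame times ``t``.

    The schedule is C¹ piecewise-cubic through the angular waypoints at the
    phase boundaries. Interior boundaries (half, impact, release) carry
    nonzero angular velocity so threshold events (shoulder-height crossings)
    are transversal exactly at the parametric transitions; the takeaway
    start, the top region and the finish pose have zero velocity (rest /
    reversal / hold).
    """
    from scipy.interpolate import CubicHermiteSpline

    r = style.arc_radius
    phi_top = float(np.arccos((r - style.top_height) / r))
    phi3 = phi_top - TOP_RECOIL_RAD
    if phi3 <= np.pi / 2:
        raise ParameterError("top angle does not clear the shoulder line")
    d = style.effective_durations
    # phase start times (active swing begins after the static lead-in)
    starts = style.lead_in_s + np.concatenate(([0.0], np.cumsum(d)))
    t1, t2, t3, t4, t5, t6, t7 = starts[1:]

    # backswing: rest -> shoulder crossing -> just short of the top
    s1, s2 = (np.pi / 2) / d[1], (phi3 - np.pi / 2) / d[2]
    m2 = _interior_slope(d[1], d[2], s1, s2)
    backswing = CubicHermiteSpline([t1, t2, t3], [0.0, np.pi / 2, phi3], [0.0, m2, 0.0])

    # downswing through finish: top -> impact -> release crossing -> pose
    sd1, sd2, sd3 = -phi3 / d[4], (-np.pi / 2) / d[5], (np.pi / 2 - FINISH_ANGLE_RAD) / d[6]
    m5 = _interior_slope(d[4], d[5], sd1, sd2)
    m6 = _interior_slope(d[5], d[6], sd2, sd3)
    downswing = CubicHermiteSpline(
        [t4, t5, t6, t7],
        [phi3, 0.0, -np.pi / 2, -FINISH_ANGLE_RAD],
        [0.0, m5, m6, 0.0],
    )

    phi = np.zeros_like(t)
    back = (t >= t1) & (t < t3)
    top = (t >= t3) & (t < t4)
    down = (t >= t4) & (t < t7)
    hold = t >= t7
    phi[back] = backswing(t[back])
    s_top = (t[top] - t3) / d[3]
    phi[top] = phi3 + TOP_RECOIL_RAD * 0.5 * (1.0 - np.cos(2.0 * np.pi * s_top))
    phi[down] = downswing(t[down])
    phi[hold] = -FINISH_ANGLE_RAD

    # downswing plane offset: ramps in over the first part of the downswing
    # (complete before the trail-side shoulder crossing), then stays applied
    # through release and finish
    impact = (t >= t4) & (t < t5)
    s_imp = np.zeros_like(t)
    s_imp[impact] = (t[impact] - t4) / d[4]
    ramp = np.where(t >= t5, 1.0, np.where(impact, _smoothstep(s_imp / PLANE_RAMP_FRACTION), 0.0))
    radius = r + style.plane_offset * ramp
    return phi, radius


def _boundary_indices(style: SwingStyle, fps: float, n_frames: int) -> tuple[int, ...]:
    d = style.effective_durations
    starts = style.lead_in_s + np.cumsum(d)[:-1]  # b1..b6 times
    b = [0] + [int(round(ts * fps)) for ts in starts] + [n_frames]
    return tuple(b)


def generate_swing(
    style: SwingStyle,
    fps: float = 30.0,
    handedness: str = "right",
    pixel_scale: float = 100.0,
    image_center: tuple[float, float] = (480.0, 270.0),
    clip_id: str = "synthetic",
    player_id: str = "synthetic",
) -> SyntheticClip:
    """Generate one clip: deterministic given (style, fps, handedness).

    Output is a pixel-unit PoseSequence (the full pipeline, including
    body-scale normalization, is exercised on it) whose shoulder width is
    ``pixel_scale`` pixels, plus the ground-truth boundary indices at the
    parametric phase transitions.
    """
    d = style.effective_durations
    total = style.lead_in_s + sum(d) + style.hold_out_s
    n = int(round(total * fps))
    t = np.arange(n) / fps
    phi, radius = _arc_schedule(style, t)

    # spine tilt: baseline forward lean plus one sway cycle over the swing
    swing_lo = style.lead_in_s + d[0]
    swing_hi = style.lead_in_s + sum(d[:6])
    u = np.clip((t - swing_lo) / (swing_hi - swing_lo), 0.0, 1.0)
    tilt = np.deg2rad(BASE_SPINE_TILT_DEG + style.spine_sway_amp * np.sin(2.0 * np.pi * u))

    mid_hip = np.zeros((n, 2))
    mid_sh = mid_hip + TORSO_LEN * np.column_stack([np.sin(tilt), -np.cos(tilt)])

    coords = {}
    coords["left_hip"] = mid_hip + [-HIP_HALF, 0.0]
    coords["right_hip"] = mid_hip + [HIP_HALF, 0.0]
    coords["left_shoulder"] = mid_sh + [-SHOULDER_HALF, 0.0]
    coords["right_shoulder"] = mid_sh + [SHOULDER_HALF, 0.0]
    coords["nose"] = mid_sh + [0.0, -HEAD_OFFSET]
    coords["left_knee"] = np.tile([-0.3, KNEE_Y], (n, 1))
    coords["right_knee"] = np.tile([0.3, KNEE_Y], (n, 1))
    coords["left_ankle"] = np.tile([-0.3, ANKLE_Y], (n, 1))
    coords["right_ankle"] = np.tile([0.3, ANKLE_Y], (n, 1))

    arm = np.column_stack([np.sin(phi), np.cos(phi)]) * radius[:, None]
    lead_wrist = mid_sh + arm
    coords["left_wrist"] = lead_wrist
    coords["right_wrist"] = lead_wrist + TRAIL_WRIST_OFFSET

    for side in ("left", "right"):
        sh = coords[f"{side}_shoulder"]
        wr = coords[f"{side}_wrist"]
        seg_vec = wr - sh
        norm = np.linalg.norm(seg_vec, axis=1, keepdims=True)
        norm[norm < 1e-12] = 1.0
        unit = seg_vec / norm
        perp = np.column_stack([-unit[:, 1], unit[:, 0]])
        coords[f"{side}_elbow"] = 0.5 * (sh + wr) + ELBOW_BEND * perp

    joints = tuple(coords)
    arr = np.stack([coords[j] for j in joints], axis=1)

    rng = np.random.default_rng(style.seed)
    if style.noise_sigma > 0:
        arr = arr + rng.normal(0.0, style.noise_sigma, size=arr.shape)

    cx, cy = image_center
    arr_px = arr * pixel_scale + np.array([cx, cy])

    seq = PoseSequence(
        times=t,
        coords=arr_px,
        joints=joints,
        fps=fps,
        units="pixels",
        handedness="right",
        clip_id=clip_id,
        player_id=player_id,
    )
    if handedness == "left":
        seq = mirror_sequence(seq)
        seq.clip_id, seq.player_id = clip_id, player_id
    elif handedness != "right":
        raise ParameterError(f"unknown handedness {handedness!r}")
    return SyntheticClip(seq, _boundary_indices(style, fps, n), style)


_PERTURBED_FIELDS = ("arc_radius", "top_height", "plane_offset", "spine_sway_amp")


def sample_player(
    base: SwingStyle,
    n_clips: int,
    within_player_sd: float = 0.05,
    seed: int = 0,
    fps: float = 30.0,
    player_id: str = "player",
) -> list[SyntheticClip]:
    """Draw ``n_clips`` same-player repeats around a base style.

    Each clip multiplies the style parameters by independent Gaussian factors
    of s.d. ``within_player_sd`` (clipped to +-3 s.d.), so clips from the same
    base are statistically closer to each other than to clips from a
    different base.
    """
    if n_clips < 1:
        raise ParameterError("n_clips must be >= 1")
    if not (0 <= within_player_sd < 0.5):
        raise ParameterError("within_player_sd must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    clips = []
    for i in range(n_clips):
        factors = {
            f: float(np.clip(rng.normal(1.0, within_player_sd), 1 - 3 * within_player_sd, 1 + 3 * within_player_sd))
            for f in _PERTURBED_FIELDS
        }
        dur_f = np.clip(
            rng.normal(1.0, within_player_sd, size=7), 1 - 3 * within_player_sd, 1 + 3 * within_player_sd
        )
        durations = tuple(d * f for d, f in zip(base.phase_durations, dur_f))
        top = base.top_height * factors["top_height"]
        radius = base.arc_radius * factors["arc_radius"]
        top = float(np.clip(top, 1.10 * radius, 1.90 * radius))
        style = replace(
            base,
            phase_durations=durations,
            arc_radius=radius,
            top_height=top,
            plane_offset=base.plane_offset * factors["plane_offset"],
            spine_sway_amp=base.spine_sway_amp * factors["spine_sway_amp"],
            seed=int(rng.integers(2**31)),
        )
        clips.append(
            generate_swing(style, fps=fps, clip_id=f"{player_id}-{i}", player_id=player_id)
        )
    return clips


def style_preset(name: str, **overrides) -> SwingStyle:
    """Named presets: ``pro`` (inside downswing path, stable spine) and
    ``amateur`` (outside downswing path, larger sway)."""
    presets = {
        "pro": dict(plane_offset=-0.08, spine_sway_amp=1.5),
        "amateur": dict(plane_offset=+0.08, spine_sway_amp=5.0),
    }
    if name not in presets:
        raise ParameterError(f"unknown preset {name!r}")
    return SwingStyle(**{**presets[name], **overrides})


def random_style(rng: np.random.Generator, seed: int | None = None) -> SwingStyle:
    """Draw a plausible style for benchmark banks: varied tempo, arc, plane."""
    radius = float(rng.uniform(1.6, 2.0))
    dur_scale = float(rng.uniform(0.9, 1.15))
    base = SwingStyle()
    return SwingStyle(
        phase_durations=tuple(d * dur_scale for d in base.phase_durations),
        arc_radius=radius,
        top_height=float(rng.uniform(1.2, 1.45)) * radius,
        plane_offset=float(rng.choice([-1, 1]) * rng.uniform(0.04, 0.12)),
        spine_sway_amp=float(rng.uniform(1.0, 5.0)),
        noise_sigma=0.01,
        seed=int(rng.integers(2**31)) if seed is None else seed,
    )
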