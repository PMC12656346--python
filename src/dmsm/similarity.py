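"""Phase-wise trajectory-integral dissimilarity and baseline metrics.

The core measure is, per phase and per joint coordinate, the integral of the
absolute difference between the two clips' trajectories,

    DS = ∫ |x(t) − y(t)| dt,

approximated by the trapezoidal rule on a common uniform grid. Each phase's
time axis is rescaled to [0, 1] before integration (configurable), so phases
of unequal duration are comparable and tempo differences are not conflated
with path differences. The per-joint score averages the x- and y-coordinate
areas; a weighted average across joints gives the phase score, mapped to a
bounded similarity by s = 1 / (1 + DS/λ).

Baselines implemented for benchmarking: DTW-aligned cosine similarity of
frame-wise motion vectors, direct Euclidean pose-vector distance, phase-wise
Pearson correlation, and an interior-joint-angle metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ContractError,
    DegenerateSkeletonError,
    ParameterError,
    SegmentationError,
    UndefinedSimilarityError,
    ValidationError,
)
from .io_pose import PoseSequence
from .phases import PHASE_NAMES, PhaseSegmentation, PhaseSlice, detect_phases, phase_slices
from .preprocess import (
    PreprocessConfig,
    Trajectory,
    align_address,
    preprocess_sequence,
    resample_uniform,
)

DEFAULT_JOINTS: tuple[str, ...] = (
    "left_wrist",
    "right_wrist",
    "left_elbow",
    "right_elbow",
    "left_shoulder",
    "right_shoulder",
    "left_hip",
    "right_hip",
)

#: Joint-weight preset emphasizing hands and hips (trunk rotation is carried
#: by the hip/shoulder joints in 2D; the spine channel lives in `biomech`).
BIOMECH_WEIGHTS: dict[str, float] = {
    "left_wrist": 2.0,
    "right_wrist": 2.0,
    "left_elbow": 1.0,
    "right_elbow": 1.0,
    "left_shoulder": 1.0,
    "right_shoulder": 1.0,
    "left_hip": 1.5,
    "right_hip": 1.5,
}

METHODS = ("dmsm", "dtw_cosine", "euclidean", "pearson", "joint_angle")


@dataclass
class SimilarityConfig:
    """Knobs of the similarity computation.

    joints / weights
        Joints entering the comparison and their non-negative weights
        (uniform by default; ``weights="biomech"`` selects the hand/hip
        emphasis preset).
    samples_per_phase
        Uniform grid size M each phase trajectory is resampled to.
    similarity_scale
        λ in s = 1/(1 + DS/λ); DS = λ maps to similarity 0.5.
    time_normalize
        Rescale each phase to unit duration before integrating (default);
        switching it off integrates over raw seconds.
    """

    joints: tuple[str, ...] = DEFAULT_JOINTS
    weights: dict[str, float] | str | None = None
    samples_per_phase: int = 100
    similarity_scale: float = 1.0
    method: str = "dmsm"
    time_normalize: bool = True
    interpolation: str = "cubic"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)

    def __post_init__(self) -> None:
        self.joints = tuple(self.joints)
        if self.samples_per_phase < 2:
            raise ParameterError("samples_per_phase must be >= 2")
        if self.similarity_scale <= 0:
            raise ParameterError("similarity_scale must be positive")
        if self.method not in METHODS:
            raise ParameterError(f"unknown method {self.method!r}")
        if isinstance(self.weights, str):
            if self.weights != "biomech":
                raise ParameterError(f"unknown weight preset {self.weights!r}")
            self.weights = dict(BIOMECH_WEIGHTS)
        if self.weights is None:
            self.weights = {j: 1.0 for j in self.joints}
        if any(w < 0 for w in self.weights.values()):
            raise ParameterError("weights must be non-negative")
        if sum(self.weights.get(j, 0.0) for j in self.joints) <= 0:
            raise ParameterError("weights must sum to a positive value")


@dataclass(frozen=True)
class PhaseScore:
    phase_name: str
    per_joint_DS: dict[str, float]
    weighted_DS: float
    similarity: float


@dataclass(frozen=True)
class SimilarityReport:
    clip_ids: tuple[str, str]
    method: str
    phase_scores: tuple[PhaseScore, ...]
    overall_similarity: float
    overall_DS: float

    def __post_init__(self) -> None:
        if len(self.phase_scores) != len(PHASE_NAMES):
            raise ValidationError("report must carry exactly 7 phase scores")

    def per_phase_DS(self) -> dict[str, float]:
        return {p.phase_name: p.weighted_DS for p in self.phase_scores}


# ---------------------------------------------------------------------------
# core integral


def trajectory_area_dissimilarity(x: Trajectory, y: Trajectory) -> float:
    """Trapezoidal approximation of ∫|x(t) − y(t)| dt on a shared grid.

    The two trajectories must share length and sample spacing; the result is
    the L1 distance between the sampled curves scaled by dt — symmetric,
    non-negative, zero iff the samples coincide, O(N).
    """
    if len(x) != len(y) or abs(x.dt - y.dt) > 1e-12 * max(x.dt, y.dt):
        raise ContractError(
            f"mismatched grids: lengths {len(x)}/{len(y)}, dt {x.dt}/{y.dt} "
            "(resample to a common grid first)"
        )
    diff = np.abs(x.values - y.values)
    return float(np.trapezoid(diff, dx=x.dt))


def dissimilarity_to_similarity(ds: float, scale: float = 1.0) -> float:
    """Bounded monotone map (0, 1]: s = 1/(1 + DS/λ); DS=0 -> 1, DS=λ -> 0.5."""
    if ds < 0:
        raise ContractError("dissimilarity must be non-negative")
    if scale <= 0:
        raise ParameterError("scale must be positive")
    return 1.0 / (1.0 + ds / scale)


# ---------------------------------------------------------------------------
# phase-wise DMSM


def _slice_trajectories(
    sl: PhaseSlice, joints: tuple[str, ...], m: int, time_normalize: bool, kind: str
) -> dict[str, tuple[Trajectory, Trajectory]]:
    """Per-joint (x, y) trajectories resampled to M samples on [0, 1]."""
    out = {}
    duration = float(sl.times[-1] - sl.times[0]) if sl.n_frames > 1 else 0.0
    span = 1.0 if time_normalize or duration == 0.0 else duration
    for j in joints:
        xy = sl.xy(j)
        if sl.n_frames == 1:  # momentary phase: constant trajectory
            tx = Trajectory(np.full(m, xy[0, 0]), 0.0, span / (m - 1))
            ty = Trajectory(np.full(m, xy[0, 1]), 0.0, span / (m - 1))
        else:
            tx = resample_uniform(Trajectory(xy[:, 0], 0.0, duration / (sl.n_frames - 1)), m, kind)
            ty = resample_uniform(Trajectory(xy[:, 1], 0.0, duration / (sl.n_frames - 1)), m, kind)
            if time_normalize:
                tx = Trajectory(tx.values, 0.0, 1.0 / (m - 1))
                ty = Trajectory(ty.values, 0.0, 1.0 / (m - 1))
        out[j] = (tx, ty)
    return out


def phase_dissimilarity(
    slice_a: PhaseSlice, slice_b: PhaseSlice, cfg: SimilarityConfig | None = None
) -> PhaseScore:
    """Score one phase: per-joint mean of x/y area dissimilarities, weighted.

    Both slices must come from body-scale normalized, address-aligned clips;
    each is resampled on its own [0, 1] time axis so the phases need not have
    equal frame counts.
    """
    cfg = cfg or SimilarityConfig()
    if slice_a.n_frames < 1 or slice_b.n_frames < 1:
        raise ValidationError("empty phase slice")
    m = cfg.samples_per_phase
    tra = _slice_trajectories(slice_a, cfg.joints, m, cfg.time_normalize, cfg.interpolation)
    trb = _slice_trajectories(slice_b, cfg.joints, m, cfg.time_normalize, cfg.interpolation)
    return _score_from_trajectories(slice_a.name, tra, trb, cfg)


def resampled_phase_trajectories(
    seq: PoseSequence, seg: PhaseSegmentation, cfg: SimilarityConfig
) -> list[tuple[str, dict[str, tuple[Trajectory, Trajectory]]]]:
    """Per-phase resampled joint trajectories for one clip (cacheable)."""
    return [
        (sl.name, _slice_trajectories(sl, cfg.joints, cfg.samples_per_phase,
                                      cfg.time_normalize, cfg.interpolation))
        for sl in phase_slices(seq, seg)
    ]


def _score_from_trajectories(
    name: str,
    tra: dict[str, tuple[Trajectory, Trajectory]],
    trb: dict[str, tuple[Trajectory, Trajectory]],
    cfg: SimilarityConfig,
) -> PhaseScore:
    per_joint = {}
    for j in cfg.joints:
        ds_x = trajectory_area_dissimilarity(tra[j][0], trb[j][0])
        ds_y = trajectory_area_dissimilarity(tra[j][1], trb[j][1])
        per_joint[j] = 0.5 * (ds_x + ds_y)
    w = np.array([cfg.weights.get(j, 0.0) for j in cfg.joints])
    ds = np.array([per_joint[j] for j in cfg.joints])
    weighted = float(np.sum(w * ds) / np.sum(w))
    return PhaseScore(
        phase_name=name,
        per_joint_DS=per_joint,
        weighted_DS=weighted,
        similarity=dissimilarity_to_similarity(weighted, cfg.similarity_scale),
    )


def _prepare_pair(
    seq_a: PoseSequence, seq_b: PoseSequence, cfg: SimilarityConfig
) -> tuple[PoseSequence, PoseSequence, PhaseSegmentation, PhaseSegmentation]:
    """Shared pipeline: normalize -> smooth -> crop -> align -> segment."""
    if not set(cfg.joints) <= set(seq_a.joints) or not set(cfg.joints) <= set(seq_b.joints):
        raise ValidationError("clips do not share the configured joint set")
    a = preprocess_sequence(seq_a, cfg.preprocess)
    b = preprocess_sequence(seq_b, cfg.preprocess)
    a, b = align_address(a, b)
    segs = []
    for seq, raw in ((a, seq_a), (b, seq_b)):
        try:
            segs.append(detect_phases(seq, cfg.preprocess))
        except SegmentationError as exc:
            raise SegmentationError(exc.event, f"clip {raw.clip_id!r}: {exc}") from exc
    return a, b, segs[0], segs[1]


def dmsm_compare(
    seq_a: PoseSequence, seq_b: PoseSequence, cfg: SimilarityConfig | None = None
) -> SimilarityReport:
    """Full phase-wise comparison of two clips.

    Each clip is segmented with its *own* boundaries; no cross-clip frame
    alignment is performed — the per-phase unit-time rescaling absorbs tempo
    differences. Deterministic for fixed inputs and config.
    """
    cfg = cfg or SimilarityConfig()
    a, b, seg_a, seg_b = _prepare_pair(seq_a, seq_b, cfg)
    return dmsm_compare_segmented(a, b, seg_a, seg_b, cfg, clip_ids=(seq_a.clip_id, seq_b.clip_id))


def dmsm_compare_segmented(
    a: PoseSequence,
    b: PoseSequence,
    seg_a: PhaseSegmentation,
    seg_b: PhaseSegmentation,
    cfg: SimilarityConfig | None = None,
    clip_ids: tuple[str, str] | None = None,
) -> SimilarityReport:
    """dmsm_compare for already preprocessed, aligned, segmented clips."""
    cfg = cfg or SimilarityConfig()
    slices_a = phase_slices(a, seg_a)
    slices_b = phase_slices(b, seg_b)
    scores = tuple(
        phase_dissimilarity(sa, sb, cfg) for sa, sb in zip(slices_a, slices_b)
    )
    return _assemble_report(scores, clip_ids or (a.clip_id, b.clip_id))


def report_from_cached(
    cached_a: list[tuple[str, dict]],
    cached_b: list[tuple[str, dict]],
    cfg: SimilarityConfig,
    clip_ids: tuple[str, str],
) -> SimilarityReport:
    """Build a report from two clips' pre-resampled phase trajectories."""
    scores = tuple(
        _score_from_trajectories(name_a, tra, trb, cfg)
        for (name_a, tra), (_, trb) in zip(cached_a, cached_b)
    )
    return _assemble_report(scores, clip_ids)


def _assemble_report(scores: tuple[PhaseScore, ...], clip_ids: tuple[str, str]) -> SimilarityReport:
    return SimilarityReport(
        clip_ids=clip_ids,
        method="dmsm",
        phase_scores=scores,
        overall_similarity=float(np.mean([s.similarity for s in scores])),
        overall_DS=float(np.mean([s.weighted_DS for s in scores])),
    )


# ---------------------------------------------------------------------------
# DTW + cosine baseline


def dtw_align(a: np.ndarray, b: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Dynamic time warping with steps {(1,0),(0,1),(1,1)} and Euclidean cost.

    Returns the optimal monotone warping path (list of index pairs from
    (0,0) to (n-1, m-1)) and its total cost.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a.reshape(-1, 1)
    if b.ndim == 1:
        b = b.reshape(-1, 1)
    if a.size == 0 or b.size == 0:
        raise ValidationError("empty input to dtw_align")
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValidationError("dtw_align inputs must share feature dimension")
    n, m = a.shape[0], b.shape[0]
    local = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        prev = np.minimum(acc[i - 1, 1:], acc[i - 1, :-1])
        row = acc[i]
        row[0] = np.inf
        for j in range(1, m + 1):
            row[j] = local[i - 1, j - 1] + min(prev[j - 1], row[j - 1])
    # backtrack (ties prefer the diagonal, then the vertical step)
    path = [(n - 1, m - 1)]
    i, j = n, m
    while (i, j) != (1, 1):
        candidates = []
        if i > 1 and j > 1:
            candidates.append((acc[i - 1, j - 1], (i - 1, j - 1)))
        if i > 1:
            candidates.append((acc[i - 1, j], (i - 1, j)))
        if j > 1:
            candidates.append((acc[i, j - 1], (i, j - 1)))
        _, (i, j) = min(candidates, key=lambda c: c[0])
        path.append((i - 1, j - 1))
    path.reverse()
    return path, float(acc[n, m])


def motion_vectors(seq: PoseSequence, joints: tuple[str, ...]) -> np.ndarray:
    """Frame-wise motion vectors: concatenated per-joint coordinate deltas."""
    cols = [seq.xy(j) for j in joints]
    stacked = np.concatenate(cols, axis=1)  # (n, 2*J)
    return np.diff(stacked, axis=0)


def dtw_cosine_similarity(
    seq_a: PoseSequence, seq_b: PoseSequence, cfg: SimilarityConfig | None = None
) -> float:
    """Mean cosine similarity of motion vectors over the DTW-aligned path.

    Aligned pairs where either vector's norm is below 1e-9 (static frames)
    are skipped; an all-static clip is an error.
    """
    cfg = cfg or SimilarityConfig()
    a = preprocess_sequence(seq_a, cfg.preprocess)
    b = preprocess_sequence(seq_b, cfg.preprocess)
    mv_a = motion_vectors(a, cfg.joints)
    mv_b = motion_vectors(b, cfg.joints)
    path, _ = dtw_align(mv_a, mv_b)
    cosines = []
    for i, j in path:
        u, v = mv_a[i], mv_b[j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-9 or nv < 1e-9:
            continue
        cosines.append(float(np.dot(u, v) / (nu * nv)))
    if not cosines:
        raise UndefinedSimilarityError("all aligned motion vectors are near zero")
    return float(np.mean(cosines))


# ---------------------------------------------------------------------------
# other baselines


def _resampled_pose_matrix(
    seq: PoseSequence, joints: tuple[str, ...], n: int, kind: str
) -> np.ndarray:
    dur = seq.duration
    cols = []
    for j in joints:
        xy = seq.xy(j)
        for c in range(2):
            tr = resample_uniform(
                Trajectory(xy[:, c], 0.0, dur / (seq.n_frames - 1)), n, kind
            )
            cols.append(tr.values)
    return np.column_stack(cols)


def euclidean_similarity(
    seq_a: PoseSequence, seq_b: PoseSequence, cfg: SimilarityConfig | None = None,
    align: bool = True,
) -> float:
    """Mean per-frame Euclidean pose-vector distance, mapped to (0, 1].

    The per-frame distance is normalized by sqrt(n_joints) (per-joint RMS),
    so a constant global offset d yields DS = d regardless of how many
    joints enter the comparison. No temporal alignment beyond resampling
    both clips to the shorter one's frame count.
    """
    cfg = cfg or SimilarityConfig()
    a = preprocess_sequence(seq_a, cfg.preprocess)
    b = preprocess_sequence(seq_b, cfg.preprocess)
    if align:
        a, b = align_address(a, b)
    n = min(a.n_frames, b.n_frames)
    ma = _resampled_pose_matrix(a, cfg.joints, n, cfg.interpolation)
    mb = _resampled_pose_matrix(b, cfg.joints, n, cfg.interpolation)
    ds = float(np.mean(np.linalg.norm(ma - mb, axis=1))) / np.sqrt(len(cfg.joints))
    return dissimilarity_to_similarity(ds, cfg.similarity_scale)


def pearson_phase_correlation(
    slice_a: PhaseSlice, slice_b: PhaseSlice, cfg: SimilarityConfig | None = None
) -> float:
    """Mean Pearson correlation over joints/coordinates of resampled slices.

    Constant trajectories (undefined correlation) are excluded with a
    warning; if every channel is constant the correlation is undefined.
    """
    cfg = cfg or SimilarityConfig()
    m = cfg.samples_per_phase
    tra = _slice_trajectories(slice_a, cfg.joints, m, True, cfg.interpolation)
    trb = _slice_trajectories(slice_b, cfg.joints, m, True, cfg.interpolation)
    rs = []
    for j in cfg.joints:
        for c in range(2):
            u = tra[j][c].values
            v = trb[j][c].values
            if np.std(u) < 1e-12 or np.std(v) < 1e-12:
                warnings.warn(
                    f"constant trajectory for joint {j} coord {'xy'[c]}; "
                    "excluded from the phase correlation",
                    stacklevel=2,
                )
                continue
            rs.append(float(np.corrcoef(u, v)[0, 1]))
    if not rs:
        raise UndefinedSimilarityError("all trajectories constant: correlation undefined")
    return float(np.mean(rs))


def _interior_angle(p: np.ndarray, vertex: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Angle at ``vertex`` subtended by p and q, per frame, radians."""
    u = p - vertex
    v = q - vertex
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu < 1e-9) or np.any(nv < 1e-9):
        raise DegenerateSkeletonError("zero-length limb segment in angle computation")
    cosang = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
    return np.arccos(cosang)


ANGLE_DEFS: tuple[tuple[str, str, str, str], ...] = (
    # (name, point, vertex, point): elbow flexion and shoulder elevation
    ("left_elbow", "left_shoulder", "left_elbow", "left_wrist"),
    ("right_elbow", "right_shoulder", "right_elbow", "right_wrist"),
    ("left_shoulder", "left_hip", "left_shoulder", "left_elbow"),
    ("right_shoulder", "right_hip", "right_shoulder", "right_elbow"),
)

JOINT_ANGLE_SCALE = np.pi / 6  # a 30° mean angular error maps to similarity 0.5


def joint_angle_trajectories(seq: PoseSequence) -> dict[str, np.ndarray]:
    """Interior angles (radians) at elbows and shoulders, per frame."""
    return {
        name: _interior_angle(seq.xy(a), seq.xy(v), seq.xy(b))
        for name, a, v, b in ANGLE_DEFS
    }


def joint_angle_similarity(
    seq_a: PoseSequence, seq_b: PoseSequence, cfg: SimilarityConfig | None = None
) -> float:
    """Mean absolute interior-angle difference mapped to (0, 1].

    Angles are translation- and scale-invariant, so this baseline probes
    local limb configuration only.
    """
    cfg = cfg or SimilarityConfig()
    a = preprocess_sequence(seq_a, cfg.preprocess)
    b = preprocess_sequence(seq_b, cfg.preprocess)
    ang_a = joint_angle_trajectories(a)
    ang_b = joint_angle_trajectories(b)
    n = min(a.n_frames, b.n_frames)
    diffs = []
    for name in ang_a:
        ta = resample_uniform(Trajectory(ang_a[name], 0.0, 1.0 / (a.n_frames - 1)), n, cfg.interpolation)
        tb = resample_uniform(Trajectory(ang_b[name], 0.0, 1.0 / (b.n_frames - 1)), n, cfg.interpolation)
        diffs.append(np.abs(ta.values - tb.values))
    ds = float(np.mean(np.concatenate(diffs)))
    return dissimilarity_to_similarity(ds, JOINT_ANGLE_SCALE)


# ---------------------------------------------------------------------------
# unified dispatch


def compare(
    seq_a: PoseSequence, seq_b: PoseSequence, method: str = "dmsm",
    cfg: SimilarityConfig | None = None,
) -> tuple[float, float, dict[str, float] | None]:
    """Run any method; returns (similarity, dissimilarity, per-phase DS | None).

    For bounded-similarity baselines the dissimilarity is 1 − similarity so
    that all methods report separation on a common "larger = more different"
    scale.
    """
    cfg = cfg or SimilarityConfig()
    if method == "dmsm":
        rep = dmsm_compare(seq_a, seq_b, cfg)
        return rep.overall_similarity, rep.overall_DS, rep.per_phase_DS()
    if method == "dtw_cosine":
        s = dtw_cosine_similarity(seq_a, seq_b, cfg)
        return s, 1.0 - s, None
    if method == "euclidean":
        s = euclidean_similarity(seq_a, seq_b, cfg)
        return s, 1.0 - s, None
    if method == "pearson":
        a, b, seg_a, seg_b = _prepare_pair(seq_a, seq_b, cfg)
        vals = [
            pearson_phase_correlation(sa, sb, cfg)
            for sa, sb in zip(phase_slices(a, seg_a), phase_slices(b, seg_b))
        ]
        s = float(np.mean(vals))
        return s, 1.0 - s, None
    if method == "joint_angle":
        s = joint_angle_similarity(seq_a, seq_b, cfg)
        return s, 1.0 - s, None
    raise ParameterError(f"unknown method {method!r}")
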