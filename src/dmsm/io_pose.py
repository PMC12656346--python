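"""Pose-keypoint sequence containers and file I/O.

Two on-disk dialects are supported:

* **csv** — one row per frame with columns
  ``frame, time_s, <joint>_x, <joint>_y[, <joint>_conf]``; header mandatory;
  self-describing and diff-friendly.
* **landmark_records** — newline-delimited JSON records carrying the full
  33-landmark set (BlazePose order) in image-normalized coordinates, preceded
  by a single sidecar header line declaring frame width/height and clip
  metadata; converted to pixels on read.

Coordinates are image coordinates throughout: origin top-left, y increases
downward, so "higher point" always means *smaller* y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Joints that every valid sequence must carry.
REQUIRED_JOINTS: frozenset[str] = frozenset(
    {
        "left_shoulder",
        "right_shoulder",
        "left_hip",
        "right_hip",
        "left_wrist",
        "right_wrist",
    }
)

#: The 13 semantic joints the pipeline reasons about (others are preserved
#: on read but ignored downstream).
CORE_JOINTS: tuple[str, ...] = (
    "nose",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

#: Full 33-landmark set in BlazePose canonical order.
BLAZEPOSE_LANDMARKS: tuple[str, ...] = (
    "nose",
    "left_eye_inner",
    "left_eye",
    "left_eye_outer",
    "right_eye_inner",
    "right_eye",
    "right_eye_outer",
    "left_ear",
    "right_ear",
    "mouth_left",
    "mouth_right",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_pinky",
    "right_pinky",
    "left_index",
    "right_index",
    "left_thumb",
    "right_thumb",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
    "left_heel",
    "right_heel",
    "left_foot_index",
    "right_foot_index",
)

#: Maximum per-joint dropout (consecutive missing frames) repaired by
#: linear interpolation; longer gaps are a hard error.
MAX_GAP_FRAMES = 3

_LANDMARK_HEADER = "#dmsm-landmarks"


@dataclass(frozen=True)
class PoseFrame:
    """A single frame: time plus per-joint (x, y) and optional confidence."""

    time: float
    coords: dict[str, tuple[float, float]]
    confidence: dict[str, float] | None = None


@dataclass
class PoseSequence:
    """Time-ordered joint coordinates for one swing clip.

    Internally array-backed: ``coords`` has shape ``(n_frames, n_joints, 2)``
    with the last axis being (x, y). ``units`` distinguishes raw pixel
    coordinates from body-scale (shoulder-width) normalized ones.
    """

    times: np.ndarray
    coords: np.ndarray
    joints: tuple[str, ...]
    fps: float
    units: str = "pixels"
    handedness: str = "right"
    clip_id: str = ""
    player_id: str = ""
    confidence: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    # -- construction / validation ------------------------------------------

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.joints = tuple(self.joints)
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.times)
        if n < 2:
            raise ValidationError("sequence must contain at least 2 frames")
        if self.coords.shape != (n, len(self.joints), 2):
            raise ValidationError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"{n} frames x {len(self.joints)} joints"
            )
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite time or coordinate values")
        if np.any(self.times < 0):
            raise ValidationError("negative timestamps")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValidationError("frame times must be strictly increasing")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        med = float(np.median(dt))
        if abs(med - 1.0 / self.fps) > 0.05 / self.fps:
            raise ValidationError(
                f"fps {self.fps} inconsistent with median frame interval {med:.6f}s"
            )
        missing = REQUIRED_JOINTS - set(self.joints)
        if missing:
            raise ValidationError(f"required joints missing: {sorted(missing)}")
        if self.units not in ("pixels", "body_scale"):
            raise ValidationError(f"unknown units {self.units!r}")
        if self.handedness not in ("right", "left"):
            raise ValidationError(f"unknown handedness {self.handedness!r}")
        if len(set(self.joints)) != len(self.joints):
            raise ValidationError("duplicate joint names")

    # -- accessors -----------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def lead_wrist(self) -> str:
        return "left_wrist" if self.handedness == "right" else "right_wrist"

    @property
    def lead_shoulder(self) -> str:
        return "left_shoulder" if self.handedness == "right" else "right_shoulder"

    def joint_index(self, joint: str) -> int:
        try:
            return self.joints.index(joint)
        except ValueError:
            raise ValidationError(f"joint {joint!r} not present") from None

    def xy(self, joint: str) -> np.ndarray:
        """(n_frames, 2) view of one joint's coordinates."""
        return self.coords[:, self.joint_index(joint), :]

    def midpoint(self, joint_a: str, joint_b: str) -> np.ndarray:
        return 0.5 * (self.xy(joint_a) + self.xy(joint_b))

    @property
    def frames(self) -> Iterator[PoseFrame]:
        for i in range(self.n_frames):
            conf = (
                {j: float(self.confidence[i, k]) for k, j in enumerate(self.joints)}
                if self.confidence is not None
                else None
            )
            yield PoseFrame(
                time=float(self.times[i]),
                coords={
                    j: (float(self.coords[i, k, 0]), float(self.coords[i, k, 1]))
                    for k, j in enumerate(self.joints)
                },
                confidence=conf,
            )

    def slice_frames(self, start: int, stop: int) -> "PoseSequence":
        """Sub-sequence over frame indices [start, stop)."""
        if not (0 <= start < stop <= self.n_frames):
            raise ValidationError(f"slice [{start}, {stop}) out of range")
        if stop - start < 2:
            raise ValidationError("slice must contain at least 2 frames")
        return replace(
            self,
            times=self.times[start:stop].copy(),
            coords=self.coords[start:stop].copy(),
            confidence=None if self.confidence is None else self.confidence[start:stop].copy(),
        )

    def copy(self) -> "PoseSequence":
        return replace(
            self,
            times=self.times.copy(),
            coords=self.coords.copy(),
            confidence=None if self.confidence is None else self.confidence.copy(),
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class ClipRecord:
    clip_id: str
    player_id: str
    path: str
    handedness: str
    fps: float
    level: str


@dataclass
class ClipManifest:
    """Table of clips: id, player, file path, handedness, fps, player level."""

    records: list[ClipRecord]

    def __post_init__(self) -> None:
        ids = [r.clip_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate clip_id(s): {dupes}")
        for r in self.records:
            if r.level not in ("amateur", "professional"):
                raise ValidationError(f"unknown level {r.level!r} for clip {r.clip_id}")
            if r.handedness not in ("right", "left"):
                raise ValidationError(f"unknown handedness {r.handedness!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ClipRecord]:
        return iter(self.records)


# ---------------------------------------------------------------------------
# gap repair


def _fill_gaps(values: np.ndarray, joint: str) -> np.ndarray:
    """Linearly interpolate NaN runs of length <= MAX_GAP_FRAMES per column."""
    out = values.copy()
    n = len(out)
    for col in range(out.shape[1]):
        v = out[:, col]
        isnan = np.isnan(v)
        if not isnan.any():
            continue
        # locate runs of NaN
        idx = np.flatnonzero(isnan)
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in splits:
            if len(run) > MAX_GAP_FRAMES:
                raise ValidationError(
                    f"joint {joint!r}: dropout of {len(run)} frames exceeds "
                    f"the {MAX_GAP_FRAMES}-frame interpolation limit"
                )
            lo, hi = run[0] - 1, run[-1] + 1
            if lo < 0 or hi >= n:
                raise ValidationError(
                    f"joint {joint!r}: dropout touches the clip boundary"
                )
        good = ~isnan
        v[isnan] = np.interp(np.flatnonzero(isnan), np.flatnonzero(good), v[good])
    return out


# ---------------------------------------------------------------------------
# CSV dialect


def _read_csv(path: Path) -> PoseSequence:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    if len(df) == 0:
        raise ValidationError(f"{path}: no data rows")
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing 'time_s' column")
    # a column pair <j>_x/<j>_y defines a joint; unpaired columns are ignored
    joints = [c[:-2] for c in df.columns if c.endswith("_x") and f"{c[:-2]}_y" in df.columns]
    for j in sorted(REQUIRED_JOINTS):
        if j not in joints:
            raise FormatError(f"{path}: missing required joint {j!r}")
    n = len(df)
    coords = np.empty((n, len(joints), 2))
    conf_cols = [f"{j}_conf" for j in joints]
    has_conf = all(c in df.columns for c in conf_cols)
    confidence = np.empty((n, len(joints))) if has_conf else None
    for k, j in enumerate(joints):
        block = df[[f"{j}_x", f"{j}_y"]].to_numpy(dtype=float)
        coords[:, k, :] = _fill_gaps(block, j)
        if has_conf:
            confidence[:, k] = df[f"{j}_conf"].to_numpy(dtype=float)
    times = df["time_s"].to_numpy(dtype=float)
    attrs = {}
    for key in ("fps", "units", "handedness", "clip_id", "player_id"):
        col = f"_{key}"
        if col in df.columns:
            attrs[key] = df[col].iloc[0]
    fps = float(attrs.get("fps", 0)) or _infer_fps(times)
    return PoseSequence(
        times=times,
        coords=coords,
        joints=tuple(joints),
        fps=fps,
        units=str(attrs.get("units", "pixels")),
        handedness=str(attrs.get("handedness", "right")),
        clip_id=str(attrs.get("clip_id", path.stem)),
        player_id=str(attrs.get("player_id", "")),
        confidence=confidence,
    )


def _infer_fps(times: np.ndarray) -> float:
    dt = np.diff(times)
    if len(dt) == 0 or np.any(dt <= 0):
        raise ValidationError("cannot infer fps: non-increasing timestamps")
    return float(round(1.0 / np.median(dt), 6))


def _write_csv(seq: PoseSequence, path: Path) -> None:
    data: dict[str, np.ndarray | list] = {
        "frame": np.arange(seq.n_frames),
        "time_s": seq.times,
    }
    for k, j in enumerate(seq.joints):
        data[f"{j}_x"] = seq.coords[:, k, 0]
        data[f"{j}_y"] = seq.coords[:, k, 1]
    if seq.confidence is not None:
        for k, j in enumerate(seq.joints):
            data[f"{j}_conf"] = seq.confidence[:, k]
    data["_fps"] = np.full(seq.n_frames, seq.fps)
    data["_units"] = [seq.units] * seq.n_frames
    data["_handedness"] = [seq.handedness] * seq.n_frames
    data["_clip_id"] = [seq.clip_id] * seq.n_frames
    data["_player_id"] = [seq.player_id] * seq.n_frames
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# landmark-record dialect (BlazePose order, image-normalized)


def _read_landmarks(path: Path) -> PoseSequence:
    text = path.read_text().strip()
    if not text:
        raise ValidationError(f"{path}: empty file")
    lines = text.splitlines()
    if not lines[0].startswith(_LANDMARK_HEADER):
        raise FormatError(f"{path}: missing {_LANDMARK_HEADER} header line")
    header = json.loads(lines[0][len(_LANDMARK_HEADER):])
    try:
        width, height = float(header["width"]), float(header["height"])
    except KeyError as exc:
        raise FormatError(f"{path}: header missing {exc}") from None
    times, rows, confs = [], [], []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        rec = json.loads(ln)
        lm = np.asarray(rec["lm"], dtype=float)
        if lm.shape[0] != len(BLAZEPOSE_LANDMARKS):
            raise FormatError(
                f"{path}: record with {lm.shape[0]} landmarks "
                f"(expected {len(BLAZEPOSE_LANDMARKS)})"
            )
        times.append(float(rec["t"]))
        rows.append(lm[:, :2] * np.array([width, height]))
        confs.append(lm[:, 2] if lm.shape[1] > 2 else np.ones(lm.shape[0]))
    if not rows:
        raise ValidationError(f"{path}: no landmark records")
    return PoseSequence(
        times=np.asarray(times),
        coords=np.stack(rows),
        joints=BLAZEPOSE_LANDMARKS,
        fps=float(header.get("fps", 0)) or _infer_fps(np.asarray(times)),
        units=str(header.get("units", "pixels")),
        handedness=str(header.get("handedness", "right")),
        clip_id=str(header.get("clip_id", path.stem)),
        player_id=str(header.get("player_id", "")),
        confidence=np.stack(confs),
        meta={"width": width, "height": height},
    )


def _write_landmarks(seq: PoseSequence, path: Path) -> None:
    missing = set(BLAZEPOSE_LANDMARKS) - set(seq.joints)
    if missing:
        raise FormatError(
            f"landmark-record dialect requires the full 33-landmark set; "
            f"missing {len(missing)} landmarks (e.g. {sorted(missing)[:3]})"
        )
    width = float(seq.meta.get("width", 960.0))
    height = float(seq.meta.get("height", 540.0))
    header = {
        "width": width,
        "height": height,
        "fps": seq.fps,
        "units": seq.units,
        "handedness": seq.handedness,
        "clip_id": seq.clip_id,
        "player_id": seq.player_id,
    }
    order = [seq.joint_index(j) for j in BLAZEPOSE_LANDMARKS]
    with open(path, "w") as fh:
        fh.write(_LANDMARK_HEADER + " " + json.dumps(header) + "\n")
        for i in range(seq.n_frames):
            lm = []
            for k in order:
                x, y = seq.coords[i, k] / np.array([width, height])
                c = 1.0 if seq.confidence is None else float(seq.confidence[i, k])
                lm.append([float(x), float(y), c])
            fh.write(json.dumps({"t": float(seq.times[i]), "lm": lm}) + "\n")


# ---------------------------------------------------------------------------
# public API


def read_pose_sequence(path: str | Path, format: str = "csv") -> PoseSequence:
    """Read a pose sequence from ``path`` in the given dialect.

    Parameters
    ----------
    path : file path
    format : ``"csv"`` or ``"landmark_records"``
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv(path)
    if format == "landmark_records":
        return _read_landmarks(path)
    raise ValueError(f"unknown format {format!r}")


def write_pose_sequence(seq: PoseSequence, path: str | Path, format: str = "csv") -> None:
    """Write ``seq`` to ``path``; round-trips coordinates within 1e-9 (csv)."""
    path = Path(path)
    if format == "csv":
        _write_csv(seq, path)
    elif format == "landmark_records":
        _write_landmarks(seq, path)
    else:
        raise ValueError(f"unknown format {format!r}")


_MANIFEST_COLUMNS = ["clip_id", "player_id", "path", "handedness", "fps", "level"]


def read_manifest(path: str | Path, check_paths: bool = True) -> ClipManifest:
    """Read a tab-separated clip manifest.

    Columns: clip_id, player_id, path, handedness, fps, level. Paths are
    resolved relative to the manifest's directory and checked for existence
    unless ``check_paths`` is false.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        clip_path = Path(row["path"])
        if not clip_path.is_absolute():
            clip_path = path.parent / clip_path
        if check_paths and not clip_path.exists():
            raise ValidationError(f"manifest path not resolvable: {clip_path}")
        records.append(
            ClipRecord(
                clip_id=row["clip_id"],
                player_id=row["player_id"],
                path=str(clip_path),
                handedness=row["handedness"],
                fps=float(row["fps"]),
                level=row["level"],
            )
        )
    return ClipManifest(records)


def write_manifest(manifest: ClipManifest | Sequence[ClipRecord], path: str | Path) -> None:
    records = list(manifest)
    df = pd.DataFrame(
        [
            {
                "clip_id": r.clip_id,
                "player_id": r.player_id,
                "path": r.path,
                "handedness": r.handedness,
                "fps": r.fps,
                "level": r.level,
            }
            for r in records
        ],
        columns=_MANIFEST_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
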