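"""Reading and writing keypoint trajectories and heel-strike annotations.

Everything downstream consumes a single in-memory carrier, :class:`PoseSequence`:
a ``frames x joints x D`` coordinate array (D=2 pixel coordinates from 2D pose
estimators, or D=3 with metric depth) plus per-frame/per-joint confidences and
a missing-data mask.  Two on-disk dialects are supported:

* the per-frame JSON files that 2D pose estimators emit (keypoints as flat
  ``[x1, y1, c1, x2, y2, c2, ...]`` arrays under a ``people`` list), and
* a long-format keypoint CSV (``frame,joint,x,y[,z],confidence``) which is the
  repository's canonical exchange format, also written by the simulator.

Conventions: frames are 0-based and the time of frame ``i`` is ``i / fps``
seconds; image x grows rightward, y downward, origin top-left; 3D input is
x lateral, y vertical, z depth (distance from the camera).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CORE_JOINTS",
    "JOINT_SCHEMES",
    "PoseSequence",
    "BoutMeta",
    "AnnotationSet",
    "read_pose_json_dir",
    "read_pose_csv",
    "write_pose_csv",
    "read_annotations",
    "write_annotations",
    "read_bouts_csv",
    "write_bouts_csv",
]

#: Joints the pipeline cannot run without.
CORE_JOINTS = ("left_ankle", "right_ankle", "left_hip", "right_hip")

# Neutral internal joint vocabulary with per-scheme alias tables so the
# 17-, 18- and 25-keypoint schemes of the common 2D libraries all load.
JOINT_SCHEMES: dict[str, tuple[str, ...]] = {
    # COCO order used by e.g. AlphaPose / Detectron keypoint heads.
    "coco17": (
        "nose", "left_eye", "right_eye", "left_ear", "right_ear",
        "left_shoulder", "right_shoulder", "left_elbow", "right_elbow",
        "left_wrist", "right_wrist", "left_hip", "right_hip",
        "left_knee", "right_knee", "left_ankle", "right_ankle",
    ),
    # OpenPose COCO-18 output order.
    "coco18": (
        "nose", "neck", "right_shoulder", "right_elbow", "right_wrist",
        "left_shoulder", "left_elbow", "left_wrist", "right_hip",
        "right_knee", "right_ankle", "left_hip", "left_knee", "left_ankle",
        "right_eye", "left_eye", "right_ear", "left_ear",
    ),
    # OpenPose BODY_25 output order.
    "body25": (
        "nose", "neck", "right_shoulder", "right_elbow", "right_wrist",
        "left_shoulder", "left_elbow", "left_wrist", "mid_hip", "right_hip",
        "right_knee", "right_ankle", "left_hip", "left_knee", "left_ankle",
        "right_eye", "left_eye", "right_ear", "left_ear", "left_big_toe",
        "left_small_toe", "left_heel", "right_big_toe", "right_small_toe",
        "right_heel",
    ),
    # Minimal scheme emitted by the synthetic walker.
    "synthetic4": ("left_hip", "right_hip", "left_ankle", "right_ankle"),
}


class PoseIOError(ValueError):
    """Raised on malformed pose / annotation inputs."""


@dataclass
class PoseSequence:
    """Time-indexed keypoint trajectories with confidences.

    Attributes
    ----------
    coords : ndarray, shape (frames, joints, D)
        D=2 (pixels) or D=3 (meters, x lateral / y vertical / z depth).
        NaN where missing.
    confidence : ndarray (frames, joints) in [0, 1], or None for 3D input
        without per-joint scores.
    joint_scheme : mapping joint name -> column index; must resolve the four
        core joints (both ankles and both hips).
    missing_mask : bool ndarray (frames, joints); True wherever the joint was
        absent from the source or was gated out by confidence.
    """

    coords: np.ndarray
    fps: float
    joint_scheme: dict[str, int]
    confidence: np.ndarray | None = None
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] not in (2, 3):
            raise PoseIOError("coords must be frames x joints x D with D in {2, 3}")
        if not self.fps > 0:
            raise PoseIOError("fps must be positive")
        for joint in CORE_JOINTS:
            if joint not in self.joint_scheme:
                raise PoseIOError(f"joint scheme missing required joint {joint!r}")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != self.coords.shape[:2]:
                raise PoseIOError("confidence and coords must share leading dimensions")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.coords).all(axis=2)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.coords.shape[:2]:
                raise PoseIOError("missing_mask and coords must share leading dimensions")
            self.missing_mask = self.missing_mask | ~np.isfinite(self.coords).all(axis=2)

    # -- basic geometry -----------------------------------------------------
    @property
    def frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_joints(self) -> int:
        return self.coords.shape[1]

    @property
    def ndim_coords(self) -> int:
        return self.coords.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time of each frame in seconds (frame i at i / fps)."""
        return np.arange(self.frames) / self.fps

    def joint_index(self, name: str) -> int:
        try:
            return self.joint_scheme[name]
        except KeyError:
            raise PoseIOError(f"unsupported joint scheme: no joint {name!r}") from None

    def joint_coords(self, name: str) -> np.ndarray:
        """(frames, D) trajectory of one joint; NaN where missing."""
        return self.coords[:, self.joint_index(name), :]

    def joint_valid(self, name: str) -> np.ndarray:
        return ~self.missing_mask[:, self.joint_index(name)]

    def copy(self) -> "PoseSequence":
        return replace(
            self,
            coords=self.coords.copy(),
            confidence=None if self.confidence is None else self.confidence.copy(),
            missing_mask=self.missing_mask.copy(),
        )


@dataclass
class BoutMeta:
    """One walking bout: a contiguous frame range with direction/state labels."""

    bout_id: str
    frame_start: int
    frame_end: int  # exclusive
    direction: str = "unknown"  # toward | away | unknown
    estimator: str = "unknown"
    treatment_state: str = "unknown"  # ON | OFF | unknown
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not self.frame_start < self.frame_end:
            raise PoseIOError(f"bout {self.bout_id}: frame_start must be < frame_end")
        if self.direction not in ("toward", "away", "unknown"):
            raise PoseIOError(f"bout {self.bout_id}: bad direction {self.direction!r}")
        if self.treatment_state not in ("ON", "OFF", "unknown"):
            raise PoseIOError(
                f"bout {self.bout_id}: bad treatment_state {self.treatment_state!r}"
            )


@dataclass
class AnnotationSet:
    """Manually annotated heel-strike frames for one bout."""

    bout_id: str
    events: list[tuple[int, str]] = field(default_factory=list)  # (frame, foot)

    def __post_init__(self) -> None:
        for frame, foot in self.events:
            if foot not in ("left", "right"):
                raise PoseIOError(
                    f"bout {self.bout_id}: annotation foot must be left/right, got {foot!r}"
                )
        self.events = sorted(self.events, key=lambda e: (e[0], e[1]))
        for foot in ("left", "right"):
            frames = [f for f, s in self.events if s == foot]
            if any(b <= a for a, b in zip(frames, frames[1:])):
                raise PoseIOError(
                    f"bout {self.bout_id}: duplicate {foot} annotation frames"
                )

    def __len__(self) -> int:
        return len(self.events)

    def frames_for(self, foot: str) -> list[int]:
        return [f for f, s in self.events if s == foot]


# ---------------------------------------------------------------------------
# per-frame JSON dialect
# ---------------------------------------------------------------------------

_FRAME_INDEX_RE = re.compile(r"(\d+)")


def _frame_index_from_name(path: Path) -> int:
    matches = _FRAME_INDEX_RE.findall(path.stem)
    if not matches:
        raise PoseIOError(f"cannot infer frame index from file name {path.name!r}")
    return int(matches[-1])


def _best_person(people: list[dict], n_joints: int) -> np.ndarray | None:
    """Pick the detection with the highest mean keypoint confidence."""
    best, best_conf = None, -np.inf
    for person in people:
        kps = person.get("pose_keypoints_2d") or person.get("pose_keypoints") or []
        arr = np.asarray(kps, dtype=float).reshape(-1, 3)
        if arr.shape[0] != n_joints:
            continue
        mean_conf = float(np.nanmean(arr[:, 2])) if arr.size else -np.inf
        if mean_conf > best_conf:
            best, best_conf = arr, mean_conf
    return best


def read_pose_json_dir(path: str | Path, joint_scheme_name: str, fps: float = 30.0) -> PoseSequence:
    """Load a directory of per-frame pose-estimator JSON files.

    Frames are ordered by the integer index embedded in the file name; index
    gaps are filled with all-missing frames (with a warning).  When several
    people are detected in a frame the one with the highest mean keypoint
    confidence is kept.  Absent joints get confidence 0 and are masked.
    """
    path = Path(path)
    if joint_scheme_name not in JOINT_SCHEMES:
        raise PoseIOError(f"unsupported joint scheme {joint_scheme_name!r}")
    names = JOINT_SCHEMES[joint_scheme_name]
    files = sorted(path.glob("*.json"), key=_frame_index_from_name)
    if not files:
        raise PoseIOError(f"no frames: no JSON files under {path}")

    indices = [_frame_index_from_name(f) for f in files]
    first, last = indices[0], indices[-1]
    n_frames = last - first + 1
    if n_frames != len(files):
        warnings.warn(
            f"frame-index gaps in {path}: {len(files)} files span indices "
            f"{first}..{last}; inserting all-missing frames",
            stacklevel=2,
        )

    n_joints = len(names)
    coords = np.full((n_frames, n_joints, 2), np.nan)
    conf = np.zeros((n_frames, n_joints))
    for file, idx in zip(files, indices):
        with open(file) as fh:
            payload = json.load(fh)
        person = _best_person(payload.get("people", []), n_joints)
        if person is None:
            continue  # person absent -> row stays fully missing
        row = idx - first
        coords[row] = person[:, :2]
        conf[row] = person[:, 2]
    # zero-confidence joints are treated as absent
    coords[conf <= 0] = np.nan

    scheme = {name: i for i, name in enumerate(names)}
    return PoseSequence(coords=coords, fps=fps, joint_scheme=scheme, confidence=conf)


# ---------------------------------------------------------------------------
# long-format CSV
# ---------------------------------------------------------------------------

def write_pose_csv(seq: PoseSequence, path: str | Path) -> None:
    """Write the canonical long-format keypoint CSV (lossless for finite values)."""
    names = sorted(seq.joint_scheme, key=seq.joint_scheme.get)
    frames = np.repeat(np.arange(seq.frames), seq.n_joints)
    joints = np.tile(names, seq.frames)
    flat = seq.coords.reshape(-1, seq.ndim_coords)
    data = {"frame": frames, "joint": joints, "x": flat[:, 0], "y": flat[:, 1]}
    if seq.ndim_coords == 3:
        data["z"] = flat[:, 2]
    if seq.confidence is not None:
        data["confidence"] = seq.confidence.reshape(-1)
    df = pd.DataFrame(data)
    # drop rows that carry no information (fully missing joints)
    missing = seq.missing_mask.reshape(-1)
    df = df[~missing]
    # pandas' default float formatting is the shortest round-trip repr,
    # keeping the CSV lossless for finite values
    df.to_csv(path, index=False)


def read_pose_csv(path: str | Path, fps: float = 30.0) -> PoseSequence:
    """Read the canonical long-format keypoint CSV.

    Output is invariant to row order: joints are indexed by sorted name and
    every frame in ``[0, max_frame]`` is represented exactly once, with rows
    absent from the file marked missing (confidence 0).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "joint", "x", "y"}
    if not required.issubset(df.columns):
        raise PoseIOError(f"pose CSV must have columns {sorted(required)}")
    for col in ("frame", "x", "y") + (("z",) if "z" in df.columns else ()):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise PoseIOError(f"non-numeric value in column {col!r} at CSV row {bad[0] + 2}")
        df[col] = coerced
    dupes = df.duplicated(subset=["frame", "joint"])
    if dupes.any():
        row = int(df.index[dupes][0])
        raise PoseIOError(f"duplicated (frame, joint) row at CSV row {row + 2}")

    df["frame"] = df["frame"].astype(int)
    names = sorted(df["joint"].unique())
    scheme = {name: i for i, name in enumerate(names)}
    n_frames = int(df["frame"].max()) + 1
    dims = 3 if "z" in df.columns else 2
    coords = np.full((n_frames, len(names), dims), np.nan)
    has_conf = "confidence" in df.columns
    conf = np.zeros((n_frames, len(names))) if has_conf else None

    rows = df["frame"].to_numpy()
    cols = df["joint"].map(scheme).to_numpy()
    coords[rows, cols, 0] = df["x"].to_numpy()
    coords[rows, cols, 1] = df["y"].to_numpy()
    if dims == 3:
        coords[rows, cols, 2] = df["z"].to_numpy()
    if has_conf:
        conf[rows, cols] = pd.to_numeric(df["confidence"], errors="coerce").fillna(0.0)

    return PoseSequence(coords=coords, fps=fps, joint_scheme=scheme, confidence=conf)


# ---------------------------------------------------------------------------
# annotations and bout metadata
# ---------------------------------------------------------------------------

def read_annotations(
    path: str | Path, bouts: dict[str, BoutMeta] | None = None
) -> dict[str, AnnotationSet]:
    """Read a heel-strike annotation CSV (columns bout_id, frame, foot).

    Returns one :class:`AnnotationSet` per bout, frames sorted ascending per
    foot.  When ``bouts`` is given, frames are validated against each bout's
    frame range.
    """
    df = pd.read_csv(path)
    required = {"bout_id", "frame", "foot"}
    if not required.issubset(df.columns):
        raise PoseIOError(f"annotation CSV must have columns {sorted(required)}")
    out: dict[str, AnnotationSet] = {}
    for bout_id, grp in df.groupby("bout_id", sort=True):
        events = []
        for _, row in grp.iterrows():
            foot = str(row["foot"]).strip().lower()
            if foot not in ("left", "right"):
                raise PoseIOError(f"bout {bout_id}: foot must be left/right, got {row['foot']!r}")
            frame = int(row["frame"])
            if bouts is not None and str(bout_id) in bouts:
                meta = bouts[str(bout_id)]
                if not (meta.frame_start <= frame < meta.frame_end):
                    raise PoseIOError(
                        f"bout {bout_id}: annotated frame {frame} outside range "
                        f"[{meta.frame_start}, {meta.frame_end})"
                    )
            events.append((frame, foot))
        out[str(bout_id)] = AnnotationSet(bout_id=str(bout_id), events=events)
    return out


def write_annotations(annotations: dict[str, AnnotationSet], path: str | Path) -> None:
    rows = [
        {"bout_id": ann.bout_id, "frame": frame, "foot": foot}
        for ann in annotations.values()
        for frame, foot in ann.events
    ]
    pd.DataFrame(rows, columns=["bout_id", "frame", "foot"]).to_csv(path, index=False)


_BOUT_COLS = [
    "bout_id", "frame_start", "frame_end", "direction",
    "estimator", "treatment_state", "subject_id",
]


def write_bouts_csv(bouts: dict[str, BoutMeta], path: str | Path) -> None:
    rows = [{c: getattr(b, c) for c in _BOUT_COLS} for b in bouts.values()]
    pd.DataFrame(rows, columns=_BOUT_COLS).to_csv(path, index=False)


def read_bouts_csv(path: str | Path) -> dict[str, BoutMeta]:
    df = pd.read_csv(path).fillna({"subject_id": ""})
    out = {}
    for _, row in df.iterrows():
        meta = BoutMeta(
            bout_id=str(row["bout_id"]),
            frame_start=int(row["frame_start"]),
            frame_end=int(row["frame_end"]),
            direction=str(row.get("direction", "unknown")),
            estimator=str(row.get("estimator", "unknown")),
            treatment_state=str(row.get("treatment_state", "unknown")),
            subject_id=str(row.get("subject_id", "")),
        )
        out[meta.bout_id] = meta
    return out
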