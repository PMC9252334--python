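"""Heel-strike detection from ankle trajectories via ST-DBSCAN.

During stance the ankle keypoint is effectively stationary on the ground, so
a foot's trajectory, viewed as points in (time, image position), contains one
dense spatiotemporal blob per stance separated by fast-moving swing samples.
ST-DBSCAN clusters points that are close in BOTH a spatial radius
(``eps_spatial``) and a temporal radius (``eps_temporal``); core/border/noise
expansion follows classical density clustering.  Each retained cluster is a
stance, and the heel strike is the first timestep of the stance.

Expansion visits points in time order and cluster ids are assigned in order
of discovery, so labels are fully deterministic.

Far from the camera, consecutive steps subtend only a few pixels and swing
samples become dense enough to bridge adjacent stances; clusters then merge
and steps are undercounted.  This resolvability limit is intrinsic to
clustering pixel trajectories and is the reason short, shuffling steps are
unreliable for the automatic method (the synthetic suite reproduces it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pose_io import AnnotationSet, BoutMeta, PoseSequence

__all__ = [
    "STDBSCANParams",
    "StanceCluster",
    "HeelStrikeEvent",
    "NoStanceDataError",
    "st_dbscan",
    "detect_stances",
    "heel_strikes_auto",
    "heel_strikes_manual",
    "merge_feet",
]


class NoStanceDataError(ValueError):
    """Ankle trajectory unusable for stance detection."""


@dataclass
class STDBSCANParams:
    """ST-DBSCAN parameters.

    ``eps_spatial`` is in coordinate units (pixels, or hip-width multiples
    when ``normalize_by_hip_width``).  When ``eps_spatial`` is None it is set
    to ``eps_hip_fraction`` times the bout's median hip width, which keeps the
    radius commensurate with apparent body scale at any camera distance.
    ``min_stance_s`` filters clusters shorter than a sustained ground contact;
    None means ``min_pts / fps``.  With ``censor_start`` (default), a stance
    already in ground contact at the first analyzed frame is discarded: one
    foot is always planted when a bout's window opens, and the first observed
    timestep of that censored stance is a segmentation edge, not a heel strike.
    """

    eps_spatial: float | None = None
    eps_hip_fraction: float = 0.12
    eps_temporal: float = 0.35  # seconds
    min_pts: int = 12
    normalize_by_hip_width: bool = False
    min_stance_s: float | None = None
    censor_start: bool = True

    def __post_init__(self) -> None:
        if self.eps_spatial is not None and self.eps_spatial <= 0:
            raise ValueError("eps_spatial must be positive")
        if self.eps_temporal <= 0:
            raise ValueError("eps_temporal must be positive")
        if self.min_pts < 2:
            raise ValueError("min_pts must be >= 2")


@dataclass
class StanceCluster:
    foot: str
    frame_first: int
    frame_last: int
    member_frames: np.ndarray
    position: np.ndarray  # cluster-median coordinates

    def duration_s(self, fps: float) -> float:
        return (self.frame_last - self.frame_first + 1) / fps


@dataclass
class HeelStrikeEvent:
    frame: int
    time_s: float
    foot: str
    position: np.ndarray
    source: str = "auto"  # auto | manual
    flagged: bool = False


def st_dbscan(
    times: np.ndarray,
    coords: np.ndarray,
    eps_spatial: float,
    eps_temporal: float,
    min_pts: int,
) -> np.ndarray:
    """Density-based clustering with a joint space-and-time neighborhood.

    A point's neighborhood is every point within ``eps_spatial`` (Euclidean,
    D in {1,2,3}) AND within ``eps_temporal`` seconds, itself included.  Core
    points have at least ``min_pts`` neighbors.  Returns integer labels with
    -1 for noise; points must be time-sorted and expansion is deterministic.
    """
    times = np.asarray(times, dtype=float)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.ndim == 2 and coords.shape[0] != times.size:
        coords = coords.reshape(times.size, -1)
    n = times.size
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    if np.any(np.diff(times) < 0):
        raise ValueError("points must be sorted by time")

    # O(n^2) neighborhoods; bouts are a few hundred points per foot.
    dt = np.abs(times[:, None] - times[None, :]) <= eps_temporal
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    adj = dt & (d2 <= eps_spatial**2)
    neighbor_counts = adj.sum(axis=1)
    is_core = neighbor_counts >= min_pts

    cluster_id = 0
    visited = np.zeros(n, dtype=bool)
    for i in range(n):  # time order
        if visited[i] or not is_core[i]:
            continue
        # grow a new cluster from this core point
        labels[i] = cluster_id
        visited[i] = True
        queue = list(np.flatnonzero(adj[i]))
        head = 0
        while head < len(queue):
            j = queue[head]
            head += 1
            if labels[j] == -1:
                labels[j] = cluster_id
            if not visited[j]:
                visited[j] = True
                if is_core[j]:
                    queue.extend(np.flatnonzero(adj[j]))
        cluster_id += 1
    return labels


def _refine_contact_run(member: np.ndarray, gap_tolerance: int = 2) -> np.ndarray:
    """Reduce a cluster's member frames to its longest near-contiguous run.

    Ground contact is contiguous in time, but the projected swing path can
    pass within the spatial radius of the upcoming stance position (most
    visibly when walking away from the camera, where rising foot clearance
    cancels the receding depth in the image), attaching short disconnected
    mid-swing fragments to the cluster.  Runs separated by gaps larger than
    ``gap_tolerance`` frames are split and the longest one (earliest on ties)
    is kept as the actual contact.
    """
    splits = np.flatnonzero(np.diff(member) > gap_tolerance + 1)
    runs = np.split(member, splits + 1)
    return max(runs, key=len)


def _trim_to_contact(member: np.ndarray, pts: np.ndarray, eps: float) -> np.ndarray:
    """Trim a stance run's edges to the frames consistent with the plateau.

    The clustering radius must tolerate measurement noise, so at far camera
    distances the slowly-landing foot contributes a few pre-contact frames to
    the cluster edge.  The plateau itself tells us the local noise scale: the
    run's interior frames scatter about the contact position by the residual
    noise.  Edge frames farther from the plateau median than
    ``max(eps/4, 3 x median interior deviation)`` are peeled off, so on clean
    trajectories the onset snaps to the true contact frame while on noisy ones
    the gate widens and nothing is trimmed.
    """
    n = member.size
    if n < 5:
        return member
    center = np.median(pts, axis=0)  # contact frames are the majority
    dist = np.linalg.norm(pts - center, axis=1)
    delta = max(eps / 4.0, 3.0 * float(np.median(dist)))
    inside = dist <= delta
    # longest contiguous run of in-gate frames = the actual contact; the
    # projected swing may cross the gate briefly (it passes through the
    # landing pixel), which a contiguity requirement rejects
    best_start, best_len, run_start = 0, 0, None
    for i, ok in enumerate(np.append(inside, False)):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = None
    if best_len == 0:
        return member
    return member[best_start : best_start + best_len]


def _resolve_eps_spatial(
    params: STDBSCANParams, hip_width: np.ndarray | None
) -> float:
    if params.eps_spatial is not None:
        return params.eps_spatial
    if hip_width is None:
        raise NoStanceDataError(
            "eps_spatial is None and no hip-width series available to derive it"
        )
    finite = hip_width[np.isfinite(hip_width)]
    if finite.size == 0 or np.median(finite) <= 0:
        raise NoStanceDataError("cannot derive eps_spatial: hip width degenerate")
    return params.eps_hip_fraction * float(np.median(finite))


def detect_stances(
    seq: PoseSequence,
    foot: str,
    params: STDBSCANParams | None = None,
    bout: BoutMeta | None = None,
    hip_width: np.ndarray | None = None,
) -> list[StanceCluster]:
    """Cluster one ankle's (t, x, y[, z]) samples into stances.

    Operates on preprocessed trajectories over the bout's frame range.
    Clusters shorter than the minimum stance duration are dropped, and
    overlapping same-foot clusters are merged.  Returned stances are ordered
    by first frame.
    """
    params = params or STDBSCANParams()
    joint = f"{foot}_ankle"
    start = bout.frame_start if bout else 0
    stop = bout.frame_end if bout else seq.frames

    traj = seq.joint_coords(joint)[start:stop]
    valid = seq.joint_valid(joint)[start:stop] & np.isfinite(traj).all(axis=1)
    frames = np.arange(start, stop)[valid]
    if frames.size == 0:
        raise NoStanceDataError(f"no stance data: {joint} has no valid samples in bout")
    pts_raw = traj[valid]
    pts = pts_raw
    times = frames / seq.fps

    hw = hip_width[start:stop][valid] if hip_width is not None else None
    if params.normalize_by_hip_width:
        if hw is None:
            raise NoStanceDataError("hip-width normalization requested but no series given")
        pts = pts / hw[:, None]
        eps = (
            params.eps_spatial
            if params.eps_spatial is not None
            else params.eps_hip_fraction
        )
    else:
        eps = _resolve_eps_spatial(params, hw if hw is not None else hip_width)

    labels = st_dbscan(times, pts, eps, params.eps_temporal, params.min_pts)

    min_stance = params.min_stance_s if params.min_stance_s is not None else params.min_pts / seq.fps
    frame_to_row = {int(f): i for i, f in enumerate(frames)}
    clusters: list[StanceCluster] = []
    for cid in range(labels.max() + 1):
        member = _refine_contact_run(frames[labels == cid])
        rows = [frame_to_row[int(f)] for f in member]
        member = _trim_to_contact(member, pts_raw[rows], eps)
        rows = [frame_to_row[int(f)] for f in member]
        cluster = StanceCluster(
            foot=foot,
            frame_first=int(member.min()),
            frame_last=int(member.max()),
            member_frames=member,
            position=np.median(pts_raw[rows], axis=0),
        )
        if cluster.duration_s(seq.fps) >= min_stance:
            clusters.append(cluster)
    clusters.sort(key=lambda c: c.frame_first)

    # merge overlapping same-foot clusters
    merged: list[StanceCluster] = []
    for c in clusters:
        if merged and c.frame_first <= merged[-1].frame_last:
            prev = merged[-1]
            member = np.union1d(prev.member_frames, c.member_frames)
            rows = [frame_to_row[int(f)] for f in member]
            merged[-1] = StanceCluster(
                foot=foot,
                frame_first=int(member.min()),
                frame_last=int(member.max()),
                member_frames=member,
                position=np.median(pts_raw[rows], axis=0),
            )
        else:
            merged.append(c)
    if params.censor_start and merged and merged[0].frame_first == int(frames[0]):
        merged = merged[1:]
    return merged


def heel_strikes_auto(stances: list[StanceCluster], fps: float) -> list[HeelStrikeEvent]:
    """One event per stance: the stance's first timestep."""
    return [
        HeelStrikeEvent(
            frame=stance.frame_first,
            time_s=stance.frame_first / fps,
            foot=stance.foot,
            position=stance.position,
            source="auto",
        )
        for stance in stances
    ]


def heel_strikes_manual(
    annotations: AnnotationSet, seq: PoseSequence
) -> list[HeelStrikeEvent]:
    """Events from manual annotation: timing from the label, position from the
    smoothed trajectory at that frame.

    Annotations falling where the joint trajectory has no spatial data (an
    untrackable gap) are dropped with a warning — without underlying
    trajectory data the annotation cannot be used.
    """
    events: list[HeelStrikeEvent] = []
    dropped = 0
    for frame, foot in annotations.events:
        joint = f"{foot}_ankle"
        if frame >= seq.frames or seq.missing_mask[frame, seq.joint_index(joint)]:
            dropped += 1
            continue
        pos = seq.joint_coords(joint)[frame]
        if not np.isfinite(pos).all():
            dropped += 1
            continue
        events.append(
            HeelStrikeEvent(
                frame=int(frame),
                time_s=frame / seq.fps,
                foot=foot,
                position=pos.copy(),
                source="manual",
            )
        )
    if dropped:
        warnings.warn(
            f"bout {annotations.bout_id}: {dropped} manual annotation(s) dropped "
            "(no spatial data at the annotated frame)",
            stacklevel=2,
        )
    return events


def merge_feet(
    left_events: list[HeelStrikeEvent], right_events: list[HeelStrikeEvent]
) -> tuple[list[HeelStrikeEvent], np.ndarray]:
    """Merge per-foot strike lists into one time-ordered sequence.

    Returns the merged list and a boolean array of length ``n - 1`` marking
    which inter-strike intervals are valid steps (consecutive opposite-foot
    strikes).  Consecutive same-foot strikes — a missed opposite-foot strike —
    invalidate the intervening step and flag the later event.  Simultaneous
    left+right strikes are ordered left-first and flagged.
    """
    merged = sorted(
        list(left_events) + list(right_events),
        key=lambda e: (e.frame, 0 if e.foot == "left" else 1),
    )
    n = len(merged)
    valid = np.zeros(max(n - 1, 0), dtype=bool)
    for i in range(n - 1):
        a, b = merged[i], merged[i + 1]
        if a.frame == b.frame:
            b.flagged = True
            continue
        if a.foot == b.foot:
            b.flagged = True
            continue
        valid[i] = True
    return merged, valid
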