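"""Synthetic 3D walker + pinhole camera: pose sequences with known ground truth.

A parametric walker advances along a 6 m walkway in front of a tripod camera
(30 Hz, 640x480 by default).  A heel-strike schedule is drawn from truncated
normal step time / length / width distributions with alternating feet; each
ankle is piecewise stationary at its strike position during stance (60% of
its step cycle by default) and swings to the next strike position with a
smoothstep forward profile and sinusoidal vertical clearance; the hips ride
at fixed lateral offsets on a pelvis that advances between the feet.  All
joints are projected to pixels through a pinhole model with a downward camera
pitch, then Gaussian pixel noise and confidence dropout are applied.  With
``depth_output`` the metric 3D joint positions are emitted instead of pixels.

The returned :class:`GroundTruth` carries the exact strike schedule and the
true feature values, playing the role of the instrumented-walkway reference
in validity experiments.

All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64), so a
fixed seed reproduces a bout bit-exactly on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .features import compute_features
from .heelstrike import HeelStrikeEvent, merge_feet
from .pose_io import (
    AnnotationSet,
    BoutMeta,
    PoseSequence,
    write_annotations,
    write_bouts_csv,
    write_pose_csv,
)

__all__ = [
    "CameraModel",
    "WalkSpec",
    "GroundTruth",
    "CohortData",
    "simulate_walk",
    "make_cohort",
    "true_features",
    "PRESETS",
    "TRUTH_COLUMNS",
]

JOINTS = ("left_hip", "right_hip", "left_ankle", "right_ankle")
SCHEME = {name: i for i, name in enumerate(JOINTS)}


@dataclass
class CameraModel:
    """Pinhole camera at the walkway end, looking down the walkway axis."""

    height_m: float = 1.2
    pitch_deg: float = 5.0  # downward
    focal_px: float = 600.0
    principal_point: tuple[float, float] = (320.0, 240.0)
    image_size: tuple[int, int] = (640, 480)  # width, height

    def project(self, points: np.ndarray) -> np.ndarray:
        """World (X lateral, Y up, Z depth from camera base) -> pixel (u, v).

        Image x grows rightward, y downward.  Raises if any point sits at or
        behind the camera plane.
        """
        pts = np.asarray(points, dtype=float)
        theta = math.radians(self.pitch_deg)
        x = pts[..., 0]
        y_rel = pts[..., 1] - self.height_m
        z = pts[..., 2]
        z_cam = -y_rel * math.sin(theta) + z * math.cos(theta)
        if np.any(z_cam <= 0.1):
            raise ValueError("walker behind (or at) the camera plane")
        y_cam = -y_rel * math.cos(theta) - z * math.sin(theta)
        u = self.principal_point[0] + self.focal_px * x / z_cam
        v = self.principal_point[1] + self.focal_px * y_cam / z_cam
        return np.stack([u, v], axis=-1)


@dataclass
class WalkSpec:
    """One simulated walking bout.

    ``step_length``, ``step_time`` and ``step_width`` are (mean, sd) pairs in
    meters / seconds; draws are truncated normals (rejection at +-3 sd and
    positivity, or the explicit ``step_length_range`` when given, e.g. the
    shuffling regime).  ``camera_offset_m`` is the distance from the camera to
    the near end of the walkway; the 2.5 m default keeps ankle keypoints
    inside the default image for the whole walk.
    """

    walkway_length_m: float = 6.0
    camera_offset_m: float = 2.5
    fps: float = 30.0
    direction: str = "away"  # toward | away
    step_length: tuple[float, float] = (0.55, 0.04)
    step_time: tuple[float, float] = (0.55, 0.03)
    step_width: tuple[float, float] = (0.10, 0.02)
    step_length_range: tuple[float, float] | None = None
    hip_width_m: float = 0.30
    hip_height_m: float = 0.90
    ankle_height_m: float = 0.08
    clearance_m: float = 0.12  # peak additional ankle height mid-swing
    stance_fraction: float = 0.6  # fraction of a foot's step cycle on the ground
    lead_in_s: float = 0.25  # bout time before the first recorded strike lands
    camera: CameraModel = field(default_factory=CameraModel)
    noise_px_sd: float = 0.0
    confidence_base: float = 0.9
    dropout_prob: float = 0.0
    depth_output: bool = False
    noise_m_sd: float = 0.0
    tail_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("step_length", "step_time", "step_width"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{name}: mean must be > 0 and sd >= 0")
        if self.fps <= 0 or self.walkway_length_m <= 0:
            raise ValueError("fps and walkway_length_m must be positive")
        if self.direction not in ("toward", "away"):
            raise ValueError("direction must be 'toward' or 'away'")
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Simulator-side truth: the strike schedule and the true joint motion."""

    strikes: pd.DataFrame  # time_s, frame, foot, lateral_m, forward_m, depth_m
    hip_width_m: float
    fps: float
    world_coords: np.ndarray  # frames x joints x 3 (true, noise-free, metric)

    def annotation_set(self, bout_id: str) -> AnnotationSet:
        """The manual-annotation oracle: the true strike frames and feet."""
        events = [
            (int(row.frame), str(row.foot)) for row in self.strikes.itertuples()
        ]
        return AnnotationSet(bout_id=bout_id, events=events)


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float | None = None,
    hi: float | None = None,
    size: int = 1,
) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    lower = max(lo if lo is not None else 0.0, mean - 3 * sd, 1e-6)
    upper = min(hi if hi is not None else math.inf, mean + 3 * sd)
    out = np.empty(size)
    for i in range(size):
        for _ in range(1000):
            draw = rng.normal(mean, sd)
            if lower <= draw <= upper:
                out[i] = draw
                break
        else:
            out[i] = min(max(mean, lower), upper)
    return out


def _draw_schedule(spec: WalkSpec, rng: np.random.Generator):
    """Strike schedule: times, feet, lateral and forward positions (walk frame).

    The first recorded strike (left foot, forward position 0) lands
    ``lead_in_s`` after the bout starts — the walker enters the bout mid-gait —
    and the walker keeps stepping until a strike lands at or beyond the
    walkway length, so the last strike position is >= walkway_length_m.
    """
    times = [spec.lead_in_s]
    feet = ["left"]
    forward = [0.0]
    widths = [float(_truncated_normal(rng, *spec.step_width)[0])]
    lateral = [-widths[0] / 2.0]
    lo, hi = spec.step_length_range or (None, None)
    while forward[-1] < spec.walkway_length_m:
        step_len = float(_truncated_normal(rng, *spec.step_length, lo=lo, hi=hi)[0])
        step_t = float(_truncated_normal(rng, *spec.step_time)[0])
        width = float(_truncated_normal(rng, *spec.step_width)[0])
        foot = "right" if feet[-1] == "left" else "left"
        times.append(times[-1] + step_t)
        feet.append(foot)
        forward.append(forward[-1] + step_len)
        widths.append(width)
        lateral.append((width / 2.0) * (1 if foot == "right" else -1))
    return (
        np.array(times),
        feet,
        np.array(lateral),
        np.array(forward),
    )


def _smoothstep(tau: np.ndarray) -> np.ndarray:
    return tau * tau * (3.0 - 2.0 * tau)


def _ankle_track(
    frame_times: np.ndarray,
    strike_times: np.ndarray,
    strike_fwd: np.ndarray,
    strike_lat: np.ndarray,
    spec: WalkSpec,
) -> np.ndarray:
    """One foot's (lateral, height, forward) trajectory in the walk frame.

    The strike arrays include a leading *virtual* pre-bout strike (time <= 0),
    so the walker enters the bout mid-gait: the foot's phase at frame 0 falls
    somewhere inside the virtual strike's stance or its swing into the first
    in-bout strike.  The last stance holds to the end of the sequence.
    """
    n = frame_times.size
    out = np.empty((n, 3))
    swing_frac = 1.0 - spec.stance_fraction
    n_strikes = strike_times.size

    def position(t: float) -> tuple[float, float, float]:
        j = int(np.searchsorted(strike_times, t, side="right")) - 1  # >= 0
        if j == n_strikes - 1:
            return strike_lat[j], spec.ankle_height_m, strike_fwd[j]
        cycle = strike_times[j + 1] - strike_times[j]
        swing_start = strike_times[j + 1] - swing_frac * cycle
        if t <= swing_start:
            return strike_lat[j], spec.ankle_height_m, strike_fwd[j]
        tau = (t - swing_start) / (strike_times[j + 1] - swing_start)
        s = float(_smoothstep(np.array(tau)))
        fwd = strike_fwd[j] + (strike_fwd[j + 1] - strike_fwd[j]) * s
        lat = strike_lat[j] + (strike_lat[j + 1] - strike_lat[j]) * s
        h = spec.ankle_height_m + spec.clearance_m * math.sin(math.pi * tau)
        return lat, h, fwd

    for i, t in enumerate(frame_times):
        lat, h, fwd = position(float(t))
        out[i] = (lat, h, fwd)
    return out


def simulate_walk(spec: WalkSpec) -> tuple[PoseSequence, GroundTruth, BoutMeta]:
    """Simulate one bout; identical spec (including seed) gives identical output."""
    rng = np.random.default_rng(spec.seed)
    times_s, feet, lateral, forward = _draw_schedule(spec, rng)

    duration = times_s[-1] + spec.tail_s
    n_frames = int(round(duration * spec.fps)) + 1
    frame_times = np.arange(n_frames) / spec.fps

    # Per-foot strike subsets, each prefixed with a virtual pre-bout strike one
    # foot-cycle (two mean steps) before its first in-bout strike.  With the
    # default lead-in both virtual strikes fall before t=0, so at frame 0 one
    # foot is finishing a pre-bout stance and the other is mid-swing.
    mean_len, mean_time = spec.step_length[0], spec.step_time[0]

    def foot_track(foot: str) -> np.ndarray:
        idx = [i for i, f in enumerate(feet) if f == foot]
        t = np.concatenate([[times_s[idx[0]] - 2 * mean_time], times_s[idx]])
        fwd = np.concatenate([[forward[idx[0]] - 2 * mean_len], forward[idx]])
        lat = np.concatenate([[lateral[idx[0]]], lateral[idx]])
        if t[0] > 0:
            raise ValueError("lead_in_s too long: virtual strike falls inside the bout")
        return _ankle_track(frame_times, t, fwd, lat, spec)

    left = foot_track("left")
    right = foot_track("right")

    # Pelvis advances between the feet: at strike k it sits midway between the
    # striking foot and the previous one.  A virtual pre-bout anchor keeps it
    # moving through the lead-in, so the walker's apparent size changes
    # strictly monotonically for the whole bout.
    midpoints = (forward + np.concatenate([[0.0], forward[:-1]])) / 2.0
    anchor_t = times_s[0] - 2 * mean_time
    anchor_p = midpoints[0] - mean_len
    pelvis_fwd = np.interp(
        frame_times,
        np.concatenate([[anchor_t], times_s]),
        np.concatenate([[anchor_p], midpoints]),
    )

    # world frame: X lateral, Y up, Z depth from camera
    def to_depth(fwd: np.ndarray) -> np.ndarray:
        if spec.direction == "away":
            return spec.camera_offset_m + fwd
        return spec.camera_offset_m + (forward[-1] - fwd)

    world = np.empty((n_frames, len(JOINTS), 3))
    world[:, SCHEME["left_hip"]] = np.column_stack(
        [np.full(n_frames, -spec.hip_width_m / 2), np.full(n_frames, spec.hip_height_m), to_depth(pelvis_fwd)]
    )
    world[:, SCHEME["right_hip"]] = np.column_stack(
        [np.full(n_frames, spec.hip_width_m / 2), np.full(n_frames, spec.hip_height_m), to_depth(pelvis_fwd)]
    )
    world[:, SCHEME["left_ankle"]] = np.column_stack(
        [left[:, 0], left[:, 1], to_depth(left[:, 2])]
    )
    world[:, SCHEME["right_ankle"]] = np.column_stack(
        [right[:, 0], right[:, 1], to_depth(right[:, 2])]
    )

    if spec.depth_output:
        coords = world + rng.normal(0.0, spec.noise_m_sd, world.shape)
        corrupt_sd = 0.3
    else:
        coords = spec.camera.project(world)
        coords = coords + rng.normal(0.0, spec.noise_px_sd, coords.shape)
        corrupt_sd = 30.0

    conf = np.clip(
        rng.normal(spec.confidence_base, 0.03, (n_frames, len(JOINTS))), 0.0, 1.0
    )
    if spec.dropout_prob > 0:
        drop = rng.random((n_frames, len(JOINTS))) < spec.dropout_prob
        conf[drop] = rng.uniform(0.0, 0.4, int(drop.sum()))
        coords[drop] += rng.normal(0.0, corrupt_sd, (int(drop.sum()), coords.shape[2]))

    # joints projecting outside the image are unusable detections
    if not spec.depth_output:
        w, h = spec.camera.image_size
        outside = (
            (coords[..., 0] < 0) | (coords[..., 0] >= w)
            | (coords[..., 1] < 0) | (coords[..., 1] >= h)
        )
        conf[outside] = 0.0

    seq = PoseSequence(coords=coords, fps=spec.fps, joint_scheme=dict(SCHEME), confidence=conf)

    strike_frames = np.ceil(times_s * spec.fps - 1e-9).astype(int)
    strikes = pd.DataFrame(
        {
            "time_s": times_s,
            "frame": strike_frames,
            "foot": feet,
            "lateral_m": lateral,
            "forward_m": forward,
            "depth_m": to_depth(forward),
        }
    )
    gt = GroundTruth(
        strikes=strikes, hip_width_m=spec.hip_width_m, fps=spec.fps, world_coords=world
    )
    meta = BoutMeta(
        bout_id="sim",
        frame_start=0,
        frame_end=n_frames,
        direction=spec.direction,
        estimator="synthetic",
    )
    return seq, gt, meta


def true_features(gt: GroundTruth) -> dict:
    """Reference-modality features from the exact strike schedule.

    Uses the same formulas as :func:`vidgait.features.compute_features`, in
    metric units; widths are reported both raw (meters) and normalized by the
    (constant) hip width, mirroring a walkway's foot-length normalization —
    rank correlations are invariant to this monotone scaling.
    """
    df = gt.strikes
    if len(df) < 3:
        raise ValueError("insufficient steps in schedule")
    events = [
        HeelStrikeEvent(
            frame=int(row.frame),
            time_s=float(row.time_s),
            foot=str(row.foot),
            position=np.array([row.lateral_m, 0.0, row.forward_m]),
            source="manual",
        )
        for row in df.itertuples()
    ]
    left = [e for e in events if e.foot == "left"]
    right = [e for e in events if e.foot == "right"]
    merged, valid = merge_feet(left, right)
    max_frame = max(e.frame for e in merged)
    hipw = np.full(max_frame + 1, gt.hip_width_m)
    feats = compute_features(merged, valid, hipw, gt.fps, annotation_method="truth")

    # swing time = (1 - stance fraction) x a foot's cycle; the CV equals the
    # CV of the same-foot inter-strike intervals
    cycles = []
    for foot in ("left", "right"):
        t = df.loc[df["foot"] == foot, "time_s"].to_numpy()
        cycles.extend(np.diff(t).tolist())
    cycles = np.asarray(cycles)
    swing_cv = (
        100.0 * float(np.std(cycles, ddof=1) / np.mean(cycles))
        if cycles.size >= 2
        else math.nan
    )
    return {
        "n_steps": feats.n_steps,
        "cadence": feats.cadence,
        "step_time_cv": feats.step_time_cv,
        "step_width_mean_norm": feats.step_width_mean,
        "step_width_mean_m": feats.step_width_mean * gt.hip_width_m,
        "step_width_cv": feats.step_width_cv,
        "step_length_mean": feats.step_length_mean,
        "speed": feats.speed,
        "swing_time_cv": swing_cv,
    }


TRUTH_COLUMNS = [
    "bout_id", "subject_id", "direction", "treatment_state", "n_steps", "cadence",
    "step_time_cv", "step_width_mean_norm", "step_width_mean_m", "step_width_cv",
    "step_length_mean", "speed", "swing_time_cv",
]

# Cohort presets.  "Between" sds perturb each bout's mean (between-bout,
# subject-level variability); the (mean, sd) pairs inside WalkSpec are the
# within-bout step-to-step variability.  The shuffling preset encodes the
# short-step regime (step length 10.8 +- 5.4 cm, truncated to 4.8-19.2 cm)
# in which clustering-based detection undercounts steps.
PRESETS: dict[str, dict] = {
    "normal": {
        "step_length": (0.55, 0.04),
        "step_time": (0.55, 0.03),
        "step_width": (0.10, 0.02),
        "step_length_range": None,
        "clearance_m": 0.12,
        "between_sd": {"step_length": 0.07, "step_time": 0.07, "step_width": 0.02},
    },
    # Shuffling (festinating) gait: very short steps with the clinically
    # characteristic reduced foot lift.
    "shuffling": {
        "step_length": (0.108, 0.054),
        "step_time": (0.45, 0.03),
        "step_width": (0.10, 0.02),
        "step_length_range": (0.048, 0.192),
        "clearance_m": 0.03,
        "between_sd": {"step_length": 0.01, "step_time": 0.04, "step_width": 0.02},
    },
    "off_state": {
        "step_length": (0.45, 0.04),
        "step_time": (0.60, 0.03),
        "step_width": (0.10, 0.02),
        "step_length_range": None,
        "clearance_m": 0.08,
        "between_sd": {"step_length": 0.06, "step_time": 0.06, "step_width": 0.02},
    },
}


@dataclass
class CohortData:
    sequences: dict[str, PoseSequence]
    ground_truths: dict[str, GroundTruth]
    bouts: dict[str, BoutMeta]
    annotations: dict[str, AnnotationSet]
    truth: pd.DataFrame


def _bout_spec(
    preset: dict, rng: np.random.Generator, direction: str, base: WalkSpec
) -> WalkSpec:
    """Draw one bout's WalkSpec around the preset means."""
    between = preset["between_sd"]
    fields = {}
    for name in ("step_length", "step_time", "step_width"):
        mean, within_sd = preset[name]
        lo, hi = preset.get("step_length_range") or (None, None)
        if name != "step_length":
            lo, hi = None, None
        bout_mean = float(
            _truncated_normal(rng, mean, between[name], lo=lo, hi=hi)[0]
        )
        fields[name] = (bout_mean, within_sd)
    return replace(
        base,
        direction=direction,
        step_length=fields["step_length"],
        step_time=fields["step_time"],
        step_width=fields["step_width"],
        step_length_range=preset.get("step_length_range"),
        clearance_m=preset.get("clearance_m", base.clearance_m),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_cohort(
    n_bouts: int,
    preset: str = "normal",
    seed: int = 0,
    out_dir: str | Path | None = None,
    treatment_effect: tuple[float, float] = (0.10, -0.05),
    base_spec: WalkSpec | None = None,
    **spec_overrides,
) -> CohortData:
    """Generate a cohort of simulated bouts with ground truth.

    Presets: ``normal``, ``shuffling``, ``mixed`` (alternating normal and
    shuffling bouts), ``on_off_paired`` (two bouts per synthetic subject, OFF
    and ON, with an additive treatment effect on step length / step time).
    Bouts alternate toward/away directions.  When ``out_dir`` is given the
    canonical CSVs (per-bout keypoints, bout metadata, annotations, ground
    truth) are written there.
    """
    if preset not in ("normal", "shuffling", "mixed", "on_off_paired"):
        raise ValueError(f"unknown preset {preset!r}")
    rng = np.random.default_rng(seed)
    base = base_spec or WalkSpec()
    if spec_overrides:
        base = replace(base, **spec_overrides)

    sequences: dict[str, PoseSequence] = {}
    ground_truths: dict[str, GroundTruth] = {}
    bouts: dict[str, BoutMeta] = {}
    annotations: dict[str, AnnotationSet] = {}
    truth_rows: list[dict] = []

    def add_bout(bout_id, subject_id, preset_dict, direction, state,
                 effect=(0.0, 0.0), base_bout_spec=None):
        spec = base_bout_spec or _bout_spec(preset_dict, rng, direction, base)
        spec = replace(
            spec,
            direction=direction,
            step_length=(max(spec.step_length[0] + effect[0], 0.02), spec.step_length[1]),
            step_time=(max(spec.step_time[0] + effect[1], 0.1), spec.step_time[1]),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        seq, gt, meta = simulate_walk(spec)
        meta = replace(
            meta, bout_id=bout_id, subject_id=subject_id, treatment_state=state
        )
        sequences[bout_id] = seq
        ground_truths[bout_id] = gt
        bouts[bout_id] = meta
        annotations[bout_id] = gt.annotation_set(bout_id)
        row = {
            "bout_id": bout_id,
            "subject_id": subject_id,
            "direction": direction,
            "treatment_state": state,
            **true_features(gt),
        }
        truth_rows.append(row)

    if preset == "on_off_paired":
        # subject-level gait parameters are drawn once and shared by the OFF
        # and ON bouts; the treatment shifts the subject's own baseline
        n_subjects = n_bouts // 2
        for s in range(n_subjects):
            direction = "toward" if s % 2 == 0 else "away"
            subject_spec = _bout_spec(PRESETS["off_state"], rng, direction, base)
            add_bout(f"b{2 * s:04d}", f"s{s:03d}", PRESETS["off_state"], direction,
                     "OFF", base_bout_spec=subject_spec)
            add_bout(
                f"b{2 * s + 1:04d}", f"s{s:03d}", PRESETS["off_state"], direction, "ON",
                effect=treatment_effect, base_bout_spec=subject_spec,
            )
    else:
        for i in range(n_bouts):
            direction = "toward" if i % 2 == 0 else "away"
            if preset == "mixed":
                # first half normal, second half shuffling, so each preset
                # sees both walking directions
                preset_dict = PRESETS["normal" if i < n_bouts // 2 else "shuffling"]
            else:
                preset_dict = PRESETS[preset]
            add_bout(f"b{i:04d}", f"s{i:03d}", preset_dict, direction, "unknown")

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)

    cohort = CohortData(
        sequences=sequences,
        ground_truths=ground_truths,
        bouts=bouts,
        annotations=annotations,
        truth=truth,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for bout_id, seq in sequences.items():
            write_pose_csv(seq, out / f"{bout_id}.csv")
        write_bouts_csv(bouts, out / "bouts.csv")
        write_annotations(annotations, out / "annotations.csv")
        truth.to_csv(out / "truth.csv", index=False)
    return cohort
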