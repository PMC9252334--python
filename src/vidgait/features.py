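"""Per-bout spatiotemporal gait features from heel-strike events.

Five features are computed from 2D trajectories: number of steps, cadence,
mean and coefficient of variation (CV) of step width, and CV of step time.
Pixel distances carry no real-world units, so spatial measures are divided by
the apparent hip width in the relevant frame, cancelling perspective scale;
video step widths are therefore unitless.  With metric 3D input two more
features become available: gait speed and mean step length, both along the
depth axis.

Definitions (sample SD, ddof=1, for all CVs; n >= 3 strikes required):

* ``n_steps``          — number of heel strikes in the bout.
* ``cadence``          — 60 * (n_strikes - 1) / (t_last - t_first), steps/min.
* ``step_time_i``      — interval between consecutive opposite-foot strikes.
* ``step_width_i``     — |lateral position difference of consecutive
  opposite-foot strikes| / hip width at the later strike's frame (the moment
  both feet are grounded).
* ``step_length_i``    — |depth difference of consecutive opposite-foot
  strikes| (3D, meters).
* ``speed``            — depth displacement between first and last strike
  over the elapsed time (3D, m/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .heelstrike import HeelStrikeEvent
from .pose_io import PoseSequence

__all__ = [
    "GaitFeatures",
    "InsufficientStepsError",
    "CannotNormalizeError",
    "hip_width",
    "compute_features",
    "filter_bouts",
    "infer_direction",
]


class InsufficientStepsError(ValueError):
    """Fewer than the minimum number of detected steps."""


class CannotNormalizeError(ValueError):
    """Hip-width series unusable for normalization."""


@dataclass
class GaitFeatures:
    n_steps: int
    cadence: float
    step_width_mean: float  # hip-width-normalized (video) or meters (metric truth)
    step_width_cv: float  # percent
    step_time_cv: float  # percent
    speed: float = math.nan  # m/s, 3D only
    step_length_mean: float = math.nan  # meters, 3D only
    annotation_method: str = "auto"
    direction: str = "unknown"

    def to_dict(self) -> dict:
        return asdict(self)


def hip_width(seq: PoseSequence) -> np.ndarray:
    """Per-frame Euclidean distance between the hip keypoints.

    NaN where either hip is missing.  Raises :class:`CannotNormalizeError`
    when no frame has both hips tracked.
    """
    left = seq.joint_coords("left_hip")
    right = seq.joint_coords("right_hip")
    width = np.linalg.norm(left - right, axis=1)
    both = seq.joint_valid("left_hip") & seq.joint_valid("right_hip")
    width = np.where(both, width, np.nan)
    if not np.isfinite(width).any():
        raise CannotNormalizeError("cannot normalize: hips untracked in every frame")
    return width


def _cv_percent(values: np.ndarray, ddof: int = 1) -> float:
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.mean(values) == 0:
        return math.nan
    return 100.0 * float(np.std(values, ddof=ddof) / np.mean(values))


def compute_features(
    strikes: list[HeelStrikeEvent],
    valid_steps: np.ndarray,
    hipw: np.ndarray,
    fps: float,
    *,
    annotation_method: str = "auto",
    direction: str = "unknown",
    ddof: int = 1,
    min_strikes: int = 3,
) -> GaitFeatures:
    """Gait features from a merged, time-ordered strike list.

    ``valid_steps[i]`` marks whether the interval between strikes i and i+1
    is a usable opposite-foot step (see :func:`vidgait.heelstrike.merge_feet`).
    ``hipw`` is the per-frame hip-width series used to normalize widths; pass
    a constant array (the metric hip width) for metric ground truth.  Depth
    features are produced only for 3D strike positions.
    """
    n = len(strikes)
    if n < min_strikes:
        raise InsufficientStepsError(f"insufficient steps: {n} < {min_strikes}")
    times = np.array([e.time_s for e in strikes])
    span = times[-1] - times[0]
    if span <= 0:
        raise InsufficientStepsError("strikes span zero time")
    cadence = 60.0 * (n - 1) / span

    is_3d = strikes[0].position.size == 3
    step_times, widths, lengths = [], [], []
    for i in range(n - 1):
        if not valid_steps[i]:
            continue
        a, b = strikes[i], strikes[i + 1]
        step_times.append(b.time_s - a.time_s)
        hw = hipw[b.frame] if b.frame < hipw.size else np.nan
        if np.isfinite(hw) and hw > 0:
            widths.append(abs(b.position[0] - a.position[0]) / hw)
        if is_3d:
            lengths.append(abs(b.position[2] - a.position[2]))

    step_times = np.asarray(step_times)
    widths = np.asarray(widths)
    width_mean = float(np.mean(widths)) if widths.size else math.nan
    width_cv = _cv_percent(widths, ddof) if widths.size >= 2 else math.nan
    time_cv = _cv_percent(step_times, ddof) if step_times.size >= 2 else math.nan

    speed = step_length_mean = math.nan
    if is_3d:
        speed = float(abs(strikes[-1].position[2] - strikes[0].position[2]) / span)
        if lengths:
            step_length_mean = float(np.mean(lengths))

    return GaitFeatures(
        n_steps=n,
        cadence=cadence,
        step_width_mean=width_mean,
        step_width_cv=width_cv,
        step_time_cv=time_cv,
        speed=speed,
        step_length_mean=step_length_mean,
        annotation_method=annotation_method,
        direction=direction,
    )


def filter_bouts(df, min_steps: int = 3, max_steps: int = 20, ref_col: str = "ref_n_steps"):
    """Apply the bout inclusion rules to a features table.

    Rows whose reference (ground-truth / walkway) step count exceeds
    ``max_steps`` are dropped — the regime in which clustering-based
    detection is known to undercount — as are rows with fewer than
    ``min_steps`` detected strikes.  Returns ``(retained, exclusions)``
    DataFrames; exclusions carry a ``reason`` column.
    """
    import pandas as pd

    reasons = pd.Series("", index=df.index, dtype=object)
    too_many = df[ref_col] > max_steps
    too_few = df["n_steps"] < min_steps
    reasons[too_many] = f"reference steps > {max_steps}"
    reasons[too_few] = f"detected steps < {min_steps}"
    reasons[too_many & too_few] = (
        f"reference steps > {max_steps}; detected steps < {min_steps}"
    )
    excluded = df[too_many | too_few].copy()
    excluded["reason"] = reasons[too_many | too_few]
    return df[~(too_many | too_few)].copy(), excluded


def infer_direction(
    hipw: np.ndarray, fps: float, rel_noise_floor: float = 0.05
) -> str:
    """Walking direction from the apparent-size trend of the hip width.

    A walker approaching the camera grows in the image, so a positive robust
    (Theil–Sen) trend of hip width over the bout means "toward", a negative
    one "away".  If the total relative change implied by the trend is below
    ``rel_noise_floor``, the direction is "unknown" and a manual label is
    required (a manual label in the bout metadata always takes precedence).
    """
    finite = np.isfinite(hipw)
    if finite.sum() < int(fps):  # need at least ~1 s of signal
        return "unknown"
    t = np.flatnonzero(finite) / fps
    w = hipw[finite]
    slope = stats.theilslopes(w, t)[0]
    rel_change = slope * (t[-1] - t[0]) / np.median(w)
    if abs(rel_change) < rel_noise_floor:
        return "unknown"
    return "toward" if slope > 0 else "away"
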