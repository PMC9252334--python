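"""Trajectory conditioning: confidence gating, gap interpolation, smoothing.

Raw keypoint tracks from pose estimators carry low-confidence detections and
frame-to-frame jitter.  The pipeline (1) masks joints whose confidence falls
below an estimator-specific threshold, (2) fills interior gaps by linear
interpolation between adjacent valid timesteps, never extrapolating past the
first/last valid sample, and (3) smooths every coordinate with a zero-phase
second-order low-pass Butterworth filter (8 Hz cut-off at 30 Hz sampling),
applied forward and backward so gait-event timing is not delayed.

Confidence scores of the common estimators are not mutually calibrated, so
the gating threshold is keyed by estimator tag; the shipped defaults are the
values tuned so that on the order of <10% of timesteps need interpolation:
0.50 (AlphaPose), 0.15 (Detectron), 0.65 (OpenPose).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .pose_io import CORE_JOINTS, PoseSequence

__all__ = [
    "PreprocessConfig",
    "PreprocessReport",
    "UntrackableJointError",
    "BoutTooShortError",
    "mask_low_confidence",
    "interpolate_gaps",
    "smooth",
    "preprocess_sequence",
    "DEFAULT_CONFIDENCE_THRESHOLDS",
]

DEFAULT_CONFIDENCE_THRESHOLDS = {
    "alphapose": 0.50,
    "detectron": 0.15,
    "openpose": 0.65,
    "synthetic": 0.50,
}


class UntrackableJointError(ValueError):
    """A joint needed downstream has fewer than 2 valid samples."""


class BoutTooShortError(ValueError):
    """The valid segment is too short for zero-phase filtering."""


@dataclass
class PreprocessConfig:
    confidence_threshold: float | None = None  # None -> resolve from estimator tag
    estimator: str = "synthetic"
    filter_order: int = 2
    cutoff_hz: float = 8.0
    max_gap_frames: int = 15  # 0.5 s at 30 Hz before a track break is declared

    def __post_init__(self) -> None:
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.confidence_threshold is not None and not 0 <= self.confidence_threshold <= 1:
            raise ValueError("confidence_threshold must lie in [0, 1]")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")

    def resolve_threshold(self) -> float:
        if self.confidence_threshold is not None:
            return self.confidence_threshold
        return DEFAULT_CONFIDENCE_THRESHOLDS.get(self.estimator.lower(), 0.5)


@dataclass
class PreprocessReport:
    """Per-joint bookkeeping emitted by the preprocessing stages."""

    masked_fraction: dict[str, float] = field(default_factory=dict)
    interpolated_fraction: dict[str, float] = field(default_factory=dict)
    usable_range: dict[str, tuple[int, int]] = field(default_factory=dict)  # inclusive
    breaks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    untrackable: list[str] = field(default_factory=list)


def _joint_names(seq: PoseSequence) -> list[str]:
    return sorted(seq.joint_scheme, key=seq.joint_scheme.get)


def mask_low_confidence(
    seq: PoseSequence, cfg: PreprocessConfig, report: PreprocessReport | None = None
) -> tuple[PoseSequence, PreprocessReport]:
    """Mark joints with confidence below the threshold as missing.

    3D input without confidence scores passes through unchanged.  The report
    records, per joint, the fraction of frames newly masked.
    """
    report = report or PreprocessReport()
    out = seq.copy()
    if seq.confidence is None:
        report.masked_fraction = {name: 0.0 for name in _joint_names(seq)}
        return out, report
    threshold = cfg.resolve_threshold()
    low = out.confidence < threshold
    out.missing_mask |= low
    out.coords[out.missing_mask] = np.nan
    for name, j in out.joint_scheme.items():
        report.masked_fraction[name] = float(np.mean(low[:, j]))
    return out, report


def interpolate_gaps(
    seq: PoseSequence, cfg: PreprocessConfig, report: PreprocessReport | None = None
) -> tuple[PoseSequence, PreprocessReport]:
    """Fill interior gaps by linear interpolation between adjacent timesteps.

    Leading/trailing missing frames are never extrapolated; they stay missing
    and the usable range is recorded per joint.  Interior gaps longer than
    ``max_gap_frames`` are left missing and reported as track breaks.  A core
    joint with fewer than 2 valid samples raises :class:`UntrackableJointError`;
    non-core joints are only recorded in the report.
    """
    report = report or PreprocessReport()
    out = seq.copy()
    for name, j in out.joint_scheme.items():
        valid = ~out.missing_mask[:, j]
        idx = np.flatnonzero(valid)
        if idx.size < 2:
            report.untrackable.append(name)
            if name in CORE_JOINTS:
                raise UntrackableJointError(f"untrackable joint {name!r} (<2 valid samples)")
            continue
        first, last = int(idx[0]), int(idx[-1])
        report.usable_range[name] = (first, last)
        breaks: list[tuple[int, int]] = []
        filled = 0
        for a, b in zip(idx[:-1], idx[1:]):
            gap = b - a - 1
            if gap == 0:
                continue
            if gap > cfg.max_gap_frames:
                breaks.append((int(a) + 1, int(b) - 1))
                continue
            span = np.arange(a + 1, b)
            for d in range(out.ndim_coords):
                out.coords[span, j, d] = np.interp(
                    span, [a, b], [out.coords[a, j, d], out.coords[b, j, d]]
                )
            out.missing_mask[span, j] = False
            filled += gap
        report.breaks[name] = breaks
        report.interpolated_fraction[name] = filled / max(last - first + 1, 1)
    return out, report


def _pad_len(cfg: PreprocessConfig) -> int:
    # filtfilt's default pad length for an order-N Butterworth (len(a) = N+1)
    return 3 * (cfg.filter_order + 1)


def _valid_segments(valid: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as inclusive (start, stop) index pairs."""
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], splits + 1])
    stops = np.concatenate([splits, [idx.size - 1]])
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, stops)]


def smooth(
    seq: PoseSequence, cfg: PreprocessConfig, report: PreprocessReport | None = None
) -> tuple[PoseSequence, PreprocessReport]:
    """Zero-phase low-pass Butterworth smoothing of every joint coordinate.

    The filter runs forward and backward (``filtfilt``) over each contiguous
    valid segment, with odd signal-reflection padding at the segment ends.
    A core joint whose longest segment does not exceed three pad lengths
    raises :class:`BoutTooShortError`; shorter non-core segments are left
    unfiltered.
    """
    report = report or PreprocessReport()
    if not cfg.cutoff_hz < seq.fps / 2:
        raise ValueError("cutoff_hz must be below the Nyquist frequency")
    out = seq.copy()
    b, a = butter(cfg.filter_order, cfg.cutoff_hz, fs=seq.fps, btype="low")
    min_len = 3 * _pad_len(cfg) + 1
    for name, j in out.joint_scheme.items():
        segments = _valid_segments(~out.missing_mask[:, j])
        long_enough = [s for s in segments if s[1] - s[0] + 1 >= min_len]
        if name in CORE_JOINTS and segments and not long_enough:
            raise BoutTooShortError(
                f"bout too short to filter: joint {name!r} longest segment "
                f"< {min_len} frames"
            )
        for start, stop in long_enough:
            chunk = out.coords[start : stop + 1, j, :]
            out.coords[start : stop + 1, j, :] = filtfilt(b, a, chunk, axis=0)
    return out, report


def preprocess_sequence(
    seq: PoseSequence, cfg: PreprocessConfig | None = None
) -> tuple[PoseSequence, PreprocessReport]:
    """mask -> interpolate -> smooth, accumulating one report."""
    cfg = cfg or PreprocessConfig()
    report = PreprocessReport()
    seq, report = mask_low_confidence(seq, cfg, report)
    seq, report = interpolate_gaps(seq, cfg, report)
    seq, report = smooth(seq, cfg, report)
    return seq, report
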