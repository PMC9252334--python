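"""Pipeline orchestration: simulate -> preprocess -> detect -> features -> validity.

Runs are configured by a single mapping (optionally loaded from YAML) with
per-stage blocks; every bout that enters extraction leaves it either as a
features row or as an exclusion row with a reason, and reruns under the same
configuration and seed are byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import validity_stats as vs
from .features import (
    CannotNormalizeError,
    InsufficientStepsError,
    compute_features,
    filter_bouts,
    hip_width,
)
from .heelstrike import (
    NoStanceDataError,
    STDBSCANParams,
    detect_stances,
    heel_strikes_auto,
    heel_strikes_manual,
    merge_feet,
)
from .pose_io import (
    AnnotationSet,
    BoutMeta,
    PoseSequence,
    read_annotations,
    read_bouts_csv,
    read_pose_csv,
)
from .preprocess import (
    BoutTooShortError,
    PreprocessConfig,
    UntrackableJointError,
    preprocess_sequence,
)
from .synthetic_gait import CohortData

__all__ = ["RunConfig", "run_extract", "run_validity", "load_cohort_dir"]

FEATURE_COLUMNS = [
    "bout_id", "annotation_method", "estimator", "direction", "treatment_state",
    "subject_id", "n_steps", "cadence", "step_width_mean", "step_width_cv",
    "step_time_cv", "speed", "step_length_mean",
]

EVENT_COLUMNS = ["bout_id", "frame", "time_s", "foot", "x", "y", "z", "source"]


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    heelstrike: STDBSCANParams = field(default_factory=STDBSCANParams)
    min_steps: int = 3
    max_steps: int = 20
    bonferroni_factor_2d: float = 18.0
    bonferroni_factor_3d: float = 6.0
    cutoff_grid: tuple[int, ...] = tuple(range(8, 41, 2))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        errors = []
        pre_kwargs = raw.get("preprocess", {})
        hs_kwargs = raw.get("heelstrike", {})
        try:
            pre = PreprocessConfig(**pre_kwargs)
        except (TypeError, ValueError) as exc:
            errors.append(f"preprocess: {exc}")
            pre = PreprocessConfig()
        try:
            hs = STDBSCANParams(**hs_kwargs)
        except (TypeError, ValueError) as exc:
            errors.append(f"heelstrike: {exc}")
            hs = STDBSCANParams()
        known = {"preprocess", "heelstrike", "min_steps", "max_steps",
                 "bonferroni_factor_2d", "bonferroni_factor_3d", "cutoff_grid", "seed"}
        for key in raw:
            if key not in known:
                errors.append(f"unknown config key {key!r}")
        if errors:
            raise ValueError("config schema violations: " + "; ".join(errors))
        scalars = {k: raw[k] for k in known - {"preprocess", "heelstrike"} if k in raw}
        if "cutoff_grid" in scalars:
            scalars["cutoff_grid"] = tuple(scalars["cutoff_grid"])
        return cls(preprocess=pre, heelstrike=hs, **scalars)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "preprocess": asdict(self.preprocess),
            "heelstrike": asdict(self.heelstrike),
            "min_steps": self.min_steps,
            "max_steps": self.max_steps,
            "bonferroni_factor_2d": self.bonferroni_factor_2d,
            "bonferroni_factor_3d": self.bonferroni_factor_3d,
            "cutoff_grid": list(self.cutoff_grid),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def load_cohort_dir(path: str | Path) -> CohortData:
    """Load a cohort directory written by :func:`vidgait.synthetic_gait.make_cohort`."""
    path = Path(path)
    bouts = read_bouts_csv(path / "bouts.csv")
    annotations = (
        read_annotations(path / "annotations.csv", bouts)
        if (path / "annotations.csv").exists()
        else {}
    )
    sequences = {
        bout_id: read_pose_csv(path / f"{bout_id}.csv") for bout_id in bouts
    }
    truth = (
        pd.read_csv(path / "truth.csv") if (path / "truth.csv").exists() else pd.DataFrame()
    )
    return CohortData(
        sequences=sequences,
        ground_truths={},
        bouts=bouts,
        annotations=annotations,
        truth=truth,
    )


def _extract_one(
    seq: PoseSequence,
    meta: BoutMeta,
    annotations: AnnotationSet | None,
    config: RunConfig,
):
    """Features + events for one bout, for the auto and (if annotated) manual
    heel-strike methods.  Raises the stage-specific error on failure."""
    pre, report = preprocess_sequence(seq, config.preprocess)
    hipw = hip_width(pre)

    rows, event_rows = [], []

    def events_to_rows(events, method):
        for e in events:
            pos = list(e.position) + [np.nan] * (3 - e.position.size)
            event_rows.append(
                {
                    "bout_id": meta.bout_id, "frame": e.frame, "time_s": e.time_s,
                    "foot": e.foot, "x": pos[0], "y": pos[1], "z": pos[2],
                    "source": method,
                }
            )

    def features_from(events_left, events_right, method):
        merged, valid = merge_feet(events_left, events_right)
        feats = compute_features(
            merged, valid, hipw, pre.fps,
            annotation_method=method,
            direction=meta.direction,
            min_strikes=config.min_steps,
        )
        events_to_rows(merged, method)
        rows.append(
            {
                "bout_id": meta.bout_id,
                "annotation_method": method,
                "estimator": meta.estimator,
                "direction": meta.direction,
                "treatment_state": meta.treatment_state,
                "subject_id": meta.subject_id,
                **{
                    k: v
                    for k, v in feats.to_dict().items()
                    if k not in ("annotation_method", "direction")
                },
            }
        )

    errors = {}
    # automated: ST-DBSCAN stances per foot
    try:
        strikes = {}
        for foot in ("left", "right"):
            stances = detect_stances(
                pre, foot, config.heelstrike, bout=meta, hip_width=hipw
            )
            strikes[foot] = heel_strikes_auto(stances, pre.fps)
        features_from(strikes["left"], strikes["right"], "auto")
    except (InsufficientStepsError, NoStanceDataError) as exc:
        errors["auto"] = str(exc)

    # manual: annotated frames, positions from the smoothed trajectory
    if annotations is not None and len(annotations):
        try:
            manual = heel_strikes_manual(annotations, pre)
            left = [e for e in manual if e.foot == "left"]
            right = [e for e in manual if e.foot == "right"]
            features_from(left, right, "manual")
        except InsufficientStepsError as exc:
            errors["manual"] = str(exc)

    return rows, event_rows, errors, report


def run_extract(
    cohort: CohortData, config: RunConfig | None = None, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Extract gait features for every bout of a cohort.

    Returns ``(features, events, exclusions)``.  Every (bout, method) pair
    appears either in the features table or in the exclusion report with a
    reason; the run is deterministic given the config.
    """
    config = config or RunConfig()
    feature_rows, event_rows, exclusion_rows = [], [], []
    for bout_id in sorted(cohort.bouts):
        seq = cohort.sequences[bout_id]
        meta = cohort.bouts[bout_id]
        ann = cohort.annotations.get(bout_id)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows, events, errors, _ = _extract_one(seq, meta, ann, config)
        except (UntrackableJointError, BoutTooShortError, CannotNormalizeError) as exc:
            for method in ("auto",) + (("manual",) if ann else ()):
                exclusion_rows.append(
                    {"bout_id": bout_id, "annotation_method": method, "reason": str(exc)}
                )
            continue
        feature_rows.extend(rows)
        event_rows.extend(events)
        for method, reason in errors.items():
            exclusion_rows.append(
                {"bout_id": bout_id, "annotation_method": method, "reason": reason}
            )

    features = pd.DataFrame(feature_rows, columns=FEATURE_COLUMNS)
    events = pd.DataFrame(event_rows, columns=EVENT_COLUMNS)
    exclusions = pd.DataFrame(
        exclusion_rows, columns=["bout_id", "annotation_method", "reason"]
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        features.to_csv(out / "features.csv", index=False, float_format="%.17g")
        events.to_csv(out / "events.csv", index=False, float_format="%.17g")
        exclusions.to_csv(out / "exclusions.csv", index=False)
        config.to_yaml(out / "config_resolved.yaml")
    return features, events, exclusions


def run_validity(
    features: pd.DataFrame,
    truth: pd.DataFrame,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    make_plots: bool = False,
) -> dict[str, pd.DataFrame]:
    """The full validity battery against the reference (ground-truth) table.

    Emits the all-bouts correlation analysis, the analysis restricted to bouts
    with at most ``max_steps`` reference steps, the cutoff sweep, difference
    metrics for the unit-comparable features, and — when paired ON/OFF states
    are present — Wilcoxon signed-rank comparisons per feature.
    """
    config = config or RunConfig()
    is_3d = features["speed"].notna().any() if "speed" in features.columns else False
    pairs = vs.FEATURE_PAIRS_3D if is_3d else vs.FEATURE_PAIRS_2D
    factor = config.bonferroni_factor_3d if is_3d else config.bonferroni_factor_2d

    out: dict[str, pd.DataFrame] = {}
    out["correlations_full"] = vs.validity_report(features, truth, pairs, factor)

    merged = features.merge(
        truth[["bout_id", "n_steps"]].rename(columns={"n_steps": "ref_n_steps"}),
        on="bout_id",
    )
    retained, excluded = filter_bouts(
        merged, min_steps=config.min_steps, max_steps=config.max_steps
    )
    out["capped_exclusions"] = excluded
    out["correlations_capped"] = vs.validity_report(
        retained.drop(columns=["ref_n_steps"]), truth, pairs, factor
    )

    # step-count cutoff sweep over the automated method
    sweeps = []
    for (method, direction), grp in merged.groupby(["annotation_method", "direction"]):
        sweep = vs.cutoff_sweep(
            grp["n_steps"], grp["ref_n_steps"], config.cutoff_grid
        )
        sweep.insert(0, "annotation_method", method)
        sweep.insert(1, "direction", direction)
        sweeps.append(sweep)
    out["cutoff_sweep"] = (
        pd.concat(sweeps, ignore_index=True) if sweeps else pd.DataFrame()
    )

    # direct difference metrics for unit-comparable features
    diff_rows = []
    comparable = [("n_steps", "n_steps"), ("cadence", "cadence"),
                  ("step_time_cv", "step_time_cv")]
    joined = features.merge(truth, on="bout_id", suffixes=("", "_ref"))
    for method, grp in joined.groupby("annotation_method"):
        for vcol, rcol in comparable:
            rcol_m = rcol if f"{rcol}_ref" not in grp.columns else f"{rcol}_ref"
            metrics = vs.difference_metrics(grp[vcol], grp[rcol_m])
            diff_rows.append({"annotation_method": method, "feature": vcol, **metrics})
    out["differences"] = pd.DataFrame(diff_rows)

    # paired treatment-state comparison
    states = set(features.get("treatment_state", pd.Series(dtype=str)).unique())
    if {"ON", "OFF"} <= states:
        wil_rows = []
        for method, grp in features.groupby("annotation_method"):
            on = grp[grp["treatment_state"] == "ON"].set_index("subject_id")
            off = grp[grp["treatment_state"] == "OFF"].set_index("subject_id")
            common = on.index.intersection(off.index)
            for col in ("cadence", "n_steps", "step_width_mean", "step_time_cv"):
                a = on.loc[common, col].to_numpy(dtype=float)
                b = off.loc[common, col].to_numpy(dtype=float)
                ok = np.isfinite(a) & np.isfinite(b)
                if ok.sum() < 5:
                    continue
                try:
                    w, p = vs.wilcoxon_signed_rank(a[ok], b[ok])
                except vs.DegenerateSampleError:
                    continue
                wil_rows.append(
                    {"annotation_method": method, "feature": col, "n": int(ok.sum()),
                     "W": w, "p": p}
                )
        out["wilcoxon"] = pd.DataFrame(wil_rows)

    if out_dir is not None:
        path = Path(out_dir)
        path.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            df.to_csv(path / f"{name}.csv", index=False, float_format="%.17g")
        if make_plots:
            _plots(merged, out["cutoff_sweep"], path)
    return out


def _plots(merged: pd.DataFrame, sweep: pd.DataFrame, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for method, grp in merged.groupby("annotation_method"):
        axes[0].scatter(grp["ref_n_steps"], grp["n_steps"], s=12, label=method, alpha=0.6)
    lim = merged[["ref_n_steps", "n_steps"]].max().max() * 1.05
    axes[0].plot([0, lim], [0, lim], "k--", lw=0.8)
    axes[0].set_xlabel("reference step count")
    axes[0].set_ylabel("video step count")
    axes[0].legend()
    ok = sweep[sweep["note"] == ""]
    for (method, direction), grp in ok.groupby(["annotation_method", "direction"]):
        axes[1].plot(grp["cutoff"], grp["r2"], marker="o", ms=3,
                     label=f"{method}/{direction}")
    axes[1].set_xlabel("max reference steps admitted")
    axes[1].set_ylabel(r"$R^2$")
    axes[1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_dir / "validity_plots.png", dpi=120)
    plt.close(fig)
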