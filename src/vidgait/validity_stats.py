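"""Concurrent-validity statistics between video and reference gait features.

The analysis battery: a D'Agostino-Pearson normality check on each feature
vector (reported, but the correlation method is not switched on it — rank
correlation is always used, matching the final analysis path for these
typically non-normal clinical features), Spearman's rank correlation with a
right-tailed test of positive association, Bonferroni adjustment over the
comparisons sharing a reference feature (factor 18 for the 2D battery, 6 for
the 3D one), a Wilcoxon signed-rank test for paired ON/OFF treatment states,
a step-count cutoff sweep (OLS R^2 / slope as a function of the maximum
reference step count admitted), and direct difference metrics for the
unit-comparable features.

Small samples get exact p-values: full permutation enumeration for Spearman
at n <= 8 and full sign-pattern enumeration for Wilcoxon at n <= 12 (average
ranks for ties in both); the asymptotic branches (t-approximation, normal
approximation with continuity and tie correction) are used above.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "DegenerateSampleError",
    "UndefinedCorrelationError",
    "dagostino_pearson",
    "spearman_right",
    "bonferroni",
    "wilcoxon_signed_rank",
    "cutoff_sweep",
    "difference_metrics",
    "validity_report",
    "FEATURE_PAIRS_2D",
    "FEATURE_PAIRS_3D",
]


class DegenerateSampleError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


@dataclass
class CorrelationResult:
    pair: str
    rho: float
    p_right: float
    p_adj: float
    n: int
    normality_p_video: float
    normality_p_reference: float


def dagostino_pearson(sample) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus normality test.

    K2 = z_skew^2 + z_kurt^2 using the published skewness/kurtosis normalizing
    transforms; p from chi-square with 2 df.  The test's validity floor is
    n >= 20; smaller samples produce a warning rather than an error.
    """
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 8:
        raise DegenerateSampleError("degenerate sample: n < 8")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("degenerate sample: zero variance")
    if x.size < 20:
        warnings.warn(
            f"normality test below its validity floor (n={x.size} < 20)", stacklevel=2
        )
    k2, p = stats.normaltest(x)
    return float(k2), float(p)


def _ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    sx, sy = np.std(rx), np.std(ry)
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("undefined correlation: constant vector")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_right(x, y, exact_n: int = 8) -> tuple[float, float]:
    """Spearman rho with a right-tailed p-value (H1: rho > 0).

    Ties get average ranks; rho is the Pearson correlation of the ranks.  For
    n <= ``exact_n`` the p-value is exact, by enumerating all n! permutations
    of one rank vector; above, the t-approximation
    t = rho * sqrt((n-2) / (1-rho^2)) with n-2 df is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise UndefinedCorrelationError("need n >= 4 pairs")
    rx, ry = _ranks(x), _ranks(y)
    rho = _rho_from_ranks(rx, ry)

    if n <= exact_n:
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if _rho_from_ranks(rx, np.asarray(perm)) >= rho - 1e-12:
                count += 1
        return rho, count / total
    if 1 - rho**2 < 1e-15:
        return rho, 0.0 if rho > 0 else 1.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    return rho, float(stats.t.sf(t, df=n - 2))


def bonferroni(p: float, factor: float) -> float:
    """min(1, factor * p)."""
    if factor < 1:
        raise ValueError("Bonferroni factor must be >= 1")
    return min(1.0, factor * p)


def wilcoxon_signed_rank(on_values, off_values, exact_n: int = 12) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; tied absolute differences get average ranks.
    W is the sum of ranks of positive differences.  For effective n <=
    ``exact_n`` the two-sided p is exact by enumerating all 2^n sign patterns;
    above, a normal approximation with continuity and tie corrections is used.
    """
    on = np.asarray(on_values, dtype=float)
    off = np.asarray(off_values, dtype=float)
    if on.shape != off.shape:
        raise ValueError("paired vectors must have equal length")
    d = on - off
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateSampleError("degenerate pairs: all differences zero")
    ranks = _ranks(np.abs(d))
    w = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0

    if n <= exact_n:
        # all 2^n assignments of signs to the observed |d| ranks
        signs = np.array(
            [[(k >> i) & 1 for i in range(n)] for k in range(2**n)], dtype=float
        )
        w_all = signs @ ranks
        obs_dev = abs(w - mean_w)
        p = float(np.mean(np.abs(w_all - mean_w) >= obs_dev - 1e-12))
        return w, p

    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var_w <= 0:
        raise DegenerateSampleError("degenerate pairs: zero variance of W")
    dev = w - mean_w
    z = (dev - 0.5 * np.sign(dev)) / math.sqrt(var_w)  # continuity correction
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return w, p


def cutoff_sweep(video_counts, reference_counts, cutoffs) -> pd.DataFrame:
    """OLS of video step counts on reference counts, per maximum-count cutoff.

    For each cutoff c, bouts with reference count <= c are retained and video
    counts are regressed on reference counts; R^2, slope, intercept and n are
    reported.  Cutoffs retaining fewer than 3 bouts are skipped with a note.
    """
    v = np.asarray(video_counts, dtype=float)
    r = np.asarray(reference_counts, dtype=float)
    rows = []
    for c in sorted(cutoffs):
        keep = r <= c
        n = int(keep.sum())
        if n < 3 or np.ptp(r[keep]) == 0:
            rows.append(
                {"cutoff": c, "n": n, "r2": np.nan, "slope": np.nan,
                 "intercept": np.nan, "note": "skipped: <3 bouts or degenerate"}
            )
            continue
        res = stats.linregress(r[keep], v[keep])
        rows.append(
            {"cutoff": c, "n": n, "r2": res.rvalue**2, "slope": res.slope,
             "intercept": res.intercept, "note": ""}
        )
    return pd.DataFrame(rows)


def difference_metrics(video_values, reference_values) -> dict:
    """Mean, mean absolute, and percent difference for unit-comparable features.

    percent difference = 100 * mean(|v - r| / r) over pairs with r > 0; the
    count of pairs excluded from the percent term is reported.
    """
    v = np.asarray(video_values, dtype=float)
    r = np.asarray(reference_values, dtype=float)
    ok = np.isfinite(v) & np.isfinite(r)
    v, r = v[ok], r[ok]
    pos = r > 0
    return {
        "mean_diff": float(np.mean(v - r)),
        "mean_abs_diff": float(np.mean(np.abs(v - r))),
        "percent_diff": float(100.0 * np.mean(np.abs(v[pos] - r[pos]) / r[pos]))
        if pos.any()
        else math.nan,
        "n": int(v.size),
        "n_percent_excluded": int((~pos).sum()),
    }


# video feature column -> reference (ground-truth) feature column
FEATURE_PAIRS_2D: tuple[tuple[str, str], ...] = (
    ("n_steps", "n_steps"),
    ("cadence", "cadence"),
    ("step_width_mean", "step_width_mean_norm"),
    ("step_width_cv", "step_width_cv"),
    ("step_time_cv", "step_time_cv"),
    ("step_time_cv", "swing_time_cv"),
)
FEATURE_PAIRS_3D: tuple[tuple[str, str], ...] = FEATURE_PAIRS_2D + (
    ("speed", "speed"),
    ("step_length_mean", "step_length_mean"),
)


def validity_report(
    features: pd.DataFrame,
    truth: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] = FEATURE_PAIRS_2D,
    factor: float = 18.0,
    strata_cols: tuple[str, ...] = ("annotation_method", "direction"),
    min_n: int = 4,
) -> pd.DataFrame:
    """One correlation row per (feature pair, stratum).

    ``features`` and ``truth`` are joined on ``bout_id``; bouts missing from
    either side are excluded (pairwise, per feature).  Each row carries
    Spearman rho, the right-tailed p, its Bonferroni adjustment by ``factor``,
    the n used, and the normality-test p-values of both vectors.
    """
    merged = features.merge(truth, on="bout_id", suffixes=("", "_ref"))
    rows = []
    strata_cols = [c for c in strata_cols if c in merged.columns]
    groups = merged.groupby(list(strata_cols)) if strata_cols else [((), merged)]
    for key, grp in groups:
        if not isinstance(key, tuple):
            key = (key,)
        stratum = dict(zip(strata_cols, key))
        for vcol, rcol in pairs:
            # reference columns sharing a video column's name carry the merge
            # suffix; prefer it so video is never correlated with itself
            rcol_m = f"{rcol}_ref" if f"{rcol}_ref" in grp.columns else rcol
            if vcol not in grp.columns or rcol_m not in grp.columns:
                continue
            v = grp[vcol].to_numpy(dtype=float)
            r = grp[rcol_m].to_numpy(dtype=float)
            ok = np.isfinite(v) & np.isfinite(r)
            if ok.sum() < min_n:
                continue
            try:
                rho, p = spearman_right(v[ok], r[ok])
            except UndefinedCorrelationError:
                continue
            def _norm_p(vec):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        return dagostino_pearson(vec)[1]
                except DegenerateSampleError:
                    return math.nan
            rows.append(
                {
                    **stratum,
                    "pair": f"{vcol}<->{rcol}",
                    "n": int(ok.sum()),
                    "rho": rho,
                    "p_right": p,
                    "p_adj": bonferroni(p, factor),
                    "normality_p_video": _norm_p(v[ok]),
                    "normality_p_reference": _norm_p(r[ok]),
                }
            )
    return pd.DataFrame(rows)
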