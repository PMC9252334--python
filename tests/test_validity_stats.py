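import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vidgait.validity_stats import (
    DegenerateSampleError,
    UndefinedCorrelationError,
    bonferroni,
    cutoff_sweep,
    dagostino_pearson,
    difference_metrics,
    spearman_right,
    validity_report,
    wilcoxon_signed_rank,
    FEATURE_PAIRS_2D,
)


def dagostino_oracle(x):
    """Step-by-step recomputation of the published skewness (D'Agostino) and
    kurtosis (Anscombe-Glynn) normalizing transforms."""
    x = np.asarray(x, dtype=float)
    n = x.size
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    m3 = ((x - m) ** 3).mean()
    m4 = ((x - m) ** 4).mean()
    g1 = m3 / m2**1.5
    y = g1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = 3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / (
        (n - 2) * (n + 5) * (n + 7) * (n + 9)
    )
    w2 = -1 + math.sqrt(2 * (beta2 - 1))
    delta = 1 / math.sqrt(0.5 * math.log(w2))
    alpha = math.sqrt(2.0 / (w2 - 1))
    z1 = delta * math.log(y / alpha + math.sqrt((y / alpha) ** 2 + 1))

    g2 = m4 / m2**2
    e = 3.0 * (n - 1) / (n + 1)
    var = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xk = (g2 - e) / math.sqrt(var)
    beta1 = (
        6.0 * (n**2 - 5 * n + 2) / ((n + 7) * (n + 9))
        * math.sqrt(6.0 * (n + 3) * (n + 5) / (n * (n - 2) * (n - 3)))
    )
    a = 6.0 + 8.0 / beta1 * (2.0 / beta1 + math.sqrt(1 + 4.0 / beta1**2))
    z2 = (
        (1 - 2.0 / (9 * a))
        - ((1 - 2.0 / a) / (1 + xk * math.sqrt(2.0 / (a - 4)))) ** (1.0 / 3)
    ) / math.sqrt(2.0 / (9 * a))
    k2 = z1**2 + z2**2
    return k2, stats.chi2.sf(k2, 2)


def spearman_permutation_oracle(x, y):
    """Exact right-tailed p by full enumeration over permutations of y."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    count = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if np.corrcoef(rx, np.asarray(perm))[0, 1] >= rho_obs - 1e-12:
            count += 1
    return rho_obs, count / total


def wilcoxon_enumeration_oracle(d):
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    n = d.size
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4.0
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return w_obs, count / 2**n


class TestDagostinoPearson:
    def test_matches_formula_oracle_on_fixed_sample(self, rng):
        x = rng.normal(10, 2, 60) ** 2  # skewed fixed sample
        k2, p = dagostino_pearson(x)
        k2o, po = dagostino_oracle(x)
        assert k2 == pytest.approx(k2o, rel=1e-10)
        assert p == pytest.approx(po, rel=1e-10)

    def test_power_on_exponential(self, rng):
        rejections = sum(
            dagostino_pearson(rng.exponential(1.0, 500))[1] < 0.001 for _ in range(100)
        )
        assert rejections >= 99

    def test_degenerate_sample(self):
        with pytest.raises(DegenerateSampleError):
            dagostino_pearson(np.full(50, 3.0))

    def test_small_n_warns(self, rng):
        with pytest.warns(UserWarning, match="validity floor"):
            dagostino_pearson(rng.normal(0, 1, 12))


class TestSpearman:
    def test_perfect_positive(self):
        rho, p = spearman_right([1, 2, 3, 4], [2, 4, 6, 8])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 24)

    def test_perfect_negative(self):
        # all 24 permutations have rho >= -1, so the inclusive right-tailed
        # permutation p-value is exactly 1
        rho, p = spearman_right([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(1.0)

    def test_ties_match_average_rank_bruteforce(self):
        x = [1, 2, 2, 4]
        y = [3, 1, 4, 5]
        rho, _ = spearman_right(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1])

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_exact_p_matches_enumeration(self, n, rng):
        for _ in range(3):
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            rho, p = spearman_right(x, y)
            rho_o, p_o = spearman_permutation_oracle(x, y)
            assert rho == pytest.approx(rho_o)
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        rho1, p1 = spearman_right(x, y)
        rho2, p2 = spearman_right(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)

    def test_exact_and_asymptotic_agree_at_crossover(self, rng):
        for _ in range(10):
            x = rng.normal(size=8)
            y = 0.8 * x + rng.normal(size=8)
            _, p_exact = spearman_right(x, y, exact_n=8)
            _, p_t = spearman_right(x, y, exact_n=0)
            assert abs(p_exact - p_t) < 0.05

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_right([1, 1, 1, 1], [1, 2, 3, 4])


class TestBonferroni:
    def test_factor_18(self):
        assert bonferroni(0.001, 18) == pytest.approx(0.018)

    def test_capped_at_one(self):
        assert bonferroni(0.2, 18) == 1.0

    def test_identity_factor(self):
        assert bonferroni(0.37, 1) == pytest.approx(0.37)


class TestWilcoxon:
    def test_all_positive_five_pairs(self):
        w, p = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])
        assert w == 15
        assert p == pytest.approx(0.0625)

    def test_antisymmetric_differences_central(self):
        on = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        off = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]  # differences -1,+1,-1,+1,-1,+1
        _, p = wilcoxon_signed_rank(on, off)
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration(self, rng):
        for _ in range(10):
            d = rng.normal(0.3, 1.0, 8)
            w, p = wilcoxon_signed_rank(d, np.zeros(8))
            w_o, p_o = wilcoxon_enumeration_oracle(d)
            assert w == pytest.approx(w_o)
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_matches_scipy_without_ties(self, rng):
        d = rng.normal(0.5, 1.0, 25)
        w, p = wilcoxon_signed_rank(d, np.zeros(25))
        res = stats.wilcoxon(d, correction=True, mode="approx")
        assert p == pytest.approx(res.pvalue, abs=1e-8)

    def test_exact_and_approx_agree_at_crossover(self, rng):
        for _ in range(10):
            d = rng.normal(0.4, 1.0, 12)
            _, p_exact = wilcoxon_signed_rank(d, np.zeros(12), exact_n=12)
            _, p_approx = wilcoxon_signed_rank(d, np.zeros(12), exact_n=0)
            assert abs(p_exact - p_approx) < 0.01 + 0.1 * p_exact

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestCutoffSweep:
    def test_identity_mapping(self):
        r = np.arange(5, 30)
        out = cutoff_sweep(r, r, [10, 20, 30])
        ok = out[out["note"] == ""]
        np.testing.assert_allclose(ok["r2"], 1.0)
        np.testing.assert_allclose(ok["slope"], 1.0)

    def test_exact_linear_half_slope(self):
        r = np.arange(5, 30, dtype=float)
        out = cutoff_sweep(0.5 * r, r, [30])
        assert out["slope"].iloc[0] == pytest.approx(0.5)
        assert out["r2"].iloc[0] == pytest.approx(1.0)

    def test_sparse_cutoff_skipped(self):
        out = cutoff_sweep([1, 2, 30], [1, 2, 30], [2, 100])
        assert "skipped" in out.loc[out["cutoff"] == 2, "note"].iloc[0]


class TestDifferenceMetrics:
    def test_stated_example(self):
        m = difference_metrics([10, 12], [10, 10])
        assert m["mean_diff"] == pytest.approx(1.0)
        assert m["mean_abs_diff"] == pytest.approx(1.0)
        assert m["percent_diff"] == pytest.approx(10.0)

    def test_identical_inputs_zero(self):
        m = difference_metrics([3.0, 4.0], [3.0, 4.0])
        assert m["mean_diff"] == 0 and m["mean_abs_diff"] == 0 and m["percent_diff"] == 0

    def test_random_tables_match_elementwise_recomputation(self, rng):
        v = rng.normal(10, 3, 50)
        r = rng.normal(10, 3, 50)
        r[r <= 0] = 0.1
        m = difference_metrics(v, r)
        assert m["mean_diff"] == pytest.approx(np.mean(v - r))
        assert m["mean_abs_diff"] == pytest.approx(np.mean(np.abs(v - r)))
        assert m["percent_diff"] == pytest.approx(100 * np.mean(np.abs(v - r) / r))

    def test_nonpositive_reference_excluded_and_counted(self):
        m = difference_metrics([1.0, 2.0, 3.0], [1.0, 0.0, 3.0])
        assert m["n_percent_excluded"] == 1


class TestValidityReport:
    def _tables(self, rho_noise, rng, n=30):
        truth = pd.DataFrame(
            {
                "bout_id": [f"b{i}" for i in range(n)],
                # distinct counts so vanishing noise cannot re-break ties
                "n_steps": rng.permutation(np.arange(8, 8 + n)),
                "cadence": rng.normal(110, 10, n),
                "step_time_cv": rng.uniform(2, 8, n),
                "step_width_mean_norm": rng.uniform(0.2, 0.5, n),
                "step_width_cv": rng.uniform(5, 25, n),
                "swing_time_cv": rng.uniform(2, 8, n),
            }
        )
        feats = truth.rename(columns={"step_width_mean_norm": "step_width_mean"}).copy()
        for col in ("n_steps", "cadence", "step_time_cv", "step_width_mean", "step_width_cv"):
            feats[col] = feats[col] + rng.normal(0, rho_noise, n)
        feats["annotation_method"] = "auto"
        feats["direction"] = ["toward", "away"] * (n // 2)
        return feats, truth

    def test_row_count_is_pairs_by_strata(self, rng):
        feats, truth = self._tables(0.01, rng)
        report = validity_report(feats, truth, FEATURE_PAIRS_2D, factor=18)
        assert len(report) == len(FEATURE_PAIRS_2D) * 2  # 2 directions, 1 method

    def test_near_noiseless_gives_rho_near_one(self, rng):
        feats, truth = self._tables(1e-9, rng)
        report = validity_report(feats, truth, FEATURE_PAIRS_2D, factor=18)
        direct = report[report["pair"].str.split("<->").str[0]
                        == report["pair"].str.split("<->").str[1]]
        assert (direct["rho"] > 0.999).all()

    def test_permuted_video_column_kills_correlation(self, rng):
        feats, truth = self._tables(0.01, rng, n=60)
        feats["cadence"] = rng.permutation(feats["cadence"].to_numpy())
        report = validity_report(feats, truth, FEATURE_PAIRS_2D, factor=18)
        row = report[report["pair"] == "cadence<->cadence"]
        assert (row["p_adj"] > 0.5).all()
        assert (row["rho"].abs() < 0.5).all()

    def test_padj_consistency(self, rng):
        feats, truth = self._tables(0.5, rng)
        report = validity_report(feats, truth, FEATURE_PAIRS_2D, factor=18)
        np.testing.assert_allclose(
            report["p_adj"], np.minimum(1.0, 18 * report["p_right"])
        )
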