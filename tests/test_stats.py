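"""Cohort statistics: rank tests, multiplicity control, trends."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from t1rho import (InsufficientDataError, InvalidParameterError,
                   age_trend_test, bh_adjust, bonferroni_threshold,
                   mann_whitney, merge_weeks, run_group_comparisons,
                   validate_measurement_table)
from t1rho.pipeline import derive_metrics


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def mwu_exact_oracle(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of rank
    assignments (tie-free data)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    mu = n1 * (len(pooled) - n1) / 2
    dev = abs(u_obs - mu)
    count = sum(abs(u_of(idx) - mu) >= dev - 1e-9
                for idx in combinations(range(len(pooled)), n1))
    return count / comb(len(pooled), n1)


def bh_oracle(p, fdr):
    """Literal step-up definition of Benjamini-Hochberg."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, bool)
    kmax = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * fdr / m:
            kmax = k
    reject[order[:kmax]] = True
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        adj[order[i]] = running
    return reject, adj


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestMergeWeeks:
    def test_pooled_counts_on_default_cohort(self, truth_cohort):
        pooled = merge_weeks(truth_cohort.truth_table)
        sub = pooled[(pooled.metric == "t1rho") & (pooled.fsl == 500.0)]
        got = {(g, r): ((sub.group == g) & (sub.roi == r)).sum()
               for g in (1, 2, 3) for r in ("tumour", "brain")}
        assert got[(1, "tumour")] == 0 and got[(1, "brain")] == 15
        assert got[(2, "tumour")] == 9 and got[(2, "brain")] == 14
        assert got[(3, "tumour")] == 7 and got[(3, "brain")] == 12

    def test_empty_and_idempotent(self, truth_cohort):
        t = truth_cohort.truth_table
        assert merge_weeks(t, weeks=[99]).empty
        one_week = t[t.week == 2]
        pd.testing.assert_frame_equal(
            merge_weeks(one_week, weeks=[2]).reset_index(drop=True),
            one_week.reset_index(drop=True))
        # input unmodified
        assert (t.week == 1).any()


class TestMannWhitney:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = mann_whitney(x, x)
        assert out.u_statistic == pytest.approx(len(x) ** 2 / 2)
        assert out.p_value >= 0.99
        assert out.mode == "asymptotic"  # ties force the approximation

    def test_small_sample_exact_enumeration(self):
        out = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert out.mode == "exact"
        assert out.p_value == pytest.approx(2 / 6)  # 2 extreme of C(4,2)

    def test_complete_separation_at_study_n(self):
        x = list(range(1, 8))
        y = [v + 100 for v in x]
        out = mann_whitney(x, y)
        assert out.mode == "exact"
        assert out.p_value == pytest.approx(2 / comb(14, 7), rel=1e-12)

    def test_exact_matches_enumeration_all_small_sizes(self):
        """Exhaustive check of the exact p-value against full enumeration
        for every sample-size pair up to 8."""
        rng = np.random.default_rng(2)
        for n1 in range(1, 9):
            for n2 in range(1, 9):
                x = rng.permutation(np.arange(1.0, n1 + n2 + 1))[:n1]
                y = np.setdiff1d(np.arange(1.0, n1 + n2 + 1), x)
                out = mann_whitney(x, y)
                assert out.mode == "exact"
                assert out.p_value == pytest.approx(mwu_exact_oracle(x, y),
                                                    rel=1e-12)

    def test_large_or_tied_samples_use_asymptotic(self):
        rng = np.random.default_rng(0)
        out = mann_whitney(rng.normal(size=12), rng.normal(size=12))
        assert out.mode == "asymptotic"
        out2 = mann_whitney([1, 1, 2], [3, 4, 5], mode="auto")
        assert out2.mode == "asymptotic"

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            mann_whitney([], [1.0])


class TestBHAdjust:
    def test_single_p(self):
        for p, expect in ((0.04, True), (0.06, False)):
            reject, adj = bh_adjust([p], fdr=0.05)
            assert reject[0] == expect
            assert adj[0] == pytest.approx(p)

    def test_step_up_example(self):
        # 0.04 > 3 * 0.05 / 4, so the step-up stops after the second p
        reject, adj = bh_adjust([0.01, 0.02, 0.04, 0.20], fdr=0.05)
        assert list(reject) == [True, True, False, False]
        assert adj[2] == pytest.approx(4 * 0.04 / 3)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            m = rng.integers(1, 11)
            p = rng.uniform(size=m)
            reject, adj = bh_adjust(p, fdr=0.05)
            oracle_rej, oracle_adj = bh_oracle(p, 0.05)
            np.testing.assert_array_equal(reject, oracle_rej)
            np.testing.assert_allclose(adj, oracle_adj, rtol=1e-12)

    def test_monotone_in_p(self):
        p = [0.012, 0.03, 0.2, 0.6]
        base, _ = bh_adjust(p, fdr=0.05)
        lowered = list(p)
        lowered[2] = 0.001
        new, _ = bh_adjust(lowered, fdr=0.05)
        assert set(np.flatnonzero(base)) <= set(np.flatnonzero(new))

    def test_invalid_p_rejected(self):
        with pytest.raises(InvalidParameterError):
            bh_adjust([0.1, 1.2])


class TestBonferroni:
    def test_six_way_threshold(self):
        thr = bonferroni_threshold(0.05, 6)
        assert thr == pytest.approx(0.05 / 6)
        assert f"{thr:.4f}" == "0.0083"

    def test_identity_and_monotone(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert (bonferroni_threshold(0.05, 2) > bonferroni_threshold(0.05, 3)
                > bonferroni_threshold(0.05, 6))

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(InvalidParameterError):
            bonferroni_threshold(1.5, 4)


class TestAgeTrend:
    def test_constant_values(self):
        out = age_trend_test([1, 2, 3, 4], [100.0] * 4)
        assert out.slope_ms_per_week == 0.0 and out.slope_p == 1.0

    def test_matches_closed_form_slope(self):
        rng = np.random.default_rng(4)
        w = np.arange(1.0, 7.0)
        v = 120 + 2.0 * w + rng.normal(0, 3, w.size)
        out = age_trend_test(w, v)
        slope = np.sum((w - w.mean()) * (v - v.mean())) / np.sum(
            (w - w.mean()) ** 2)
        assert out.slope_ms_per_week == pytest.approx(slope, rel=1e-12)

    def test_perfectly_collinear(self):
        out = age_trend_test([1, 2, 3], [10.0, 20.0, 30.0])
        assert out.slope_ms_per_week > 0 and out.slope_p == 0.0

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            age_trend_test([1, 2], [1.0, 2.0])


@pytest.fixture(scope="module")
def pooled(truth_cohort):
    metrics = derive_metrics(truth_cohort.truth_table)
    return merge_weeks(validate_measurement_table(metrics))


class TestRunGroupComparisons:

    def test_family_sizes(self, pooled):
        res = run_group_comparisons(pooled)
        td = res["t1rho_delta"]
        assert set(td.groupby("family").size()) == {4}
        assert td.family.nunique() == 7
        assert len(res["dispersion"]) == 6
        assert res["dispersion"]["threshold"].iloc[0] == pytest.approx(0.05 / 6)

    def test_permutation_invariance(self, pooled):
        res_a = run_group_comparisons(pooled)
        shuffled = pooled.sample(frac=1.0, random_state=1)
        res_b = run_group_comparisons(shuffled)
        for key in ("t1rho_delta", "dispersion"):
            pd.testing.assert_frame_equal(res_a[key], res_b[key])

    def test_only_naive_group_yields_absent_comparisons(self, pooled):
        g1 = pooled[pooled.group == 1]
        res = run_group_comparisons(g1)
        td = res["t1rho_delta"]
        assert (td.note == "no comparison possible").all()
        assert not td.significant.any()

    def test_validation_catches_duplicates_and_g1_tumours(self, pooled):
        dup = pd.concat([pooled, pooled.iloc[[0]]])
        with pytest.raises(InvalidParameterError):
            validate_measurement_table(dup)
        bad = pooled.copy()
        bad.loc[bad.index[0], ["group", "roi"]] = [1, "tumour"]
        with pytest.raises(InvalidParameterError):
            validate_measurement_table(bad)
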