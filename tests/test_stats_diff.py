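import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, pearsonr, spearmanr

from tmijoint.stats_diff import (
    bh_fdr,
    benchmark_metrics,
    differential_table,
    mann_whitney_u,
)


def _brute_force_exact_p(a, b):
    """Enumerate every assignment of pooled ranks to group A (oracle)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a, n_b = len(a), len(b)
    t_a_obs = ranks[:n_a].sum()
    u_a_obs = n_a * n_b + n_a * (n_a + 1) / 2 - t_a_obs
    u_b_obs = n_a * n_b - u_a_obs
    u_obs = min(u_a_obs, u_b_obs)
    count = total = 0
    for combo in itertools.combinations(range(n_a + n_b), n_a):
        t_a = ranks[list(combo)].sum()
        u_a = n_a * n_b + n_a * (n_a + 1) / 2 - t_a
        u = min(u_a, n_a * n_b - u_a)
        total += 1
        if u <= u_obs + 1e-9:
            count += 1
    # two-sided: P(min(U_A, U_B) <= u_obs) counts both tails already
    return min(1.0, count / total)


class TestMannWhitney:
    def test_worked_example(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.T_A == 6 and res.U_A == 9 and res.U_B == 0 and res.U == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_full_ties_symmetry(self):
        res = mann_whitney_u([1, 1], [1, 1], mode="normal")
        assert res.U_A == res.U_B == 2
        assert res.p_value == 1.0

    def test_sum_identity_random(self, rng):
        for _ in range(1000):
            n_a, n_b = rng.integers(1, 30, size=2)
            a = rng.integers(0, 10, size=n_a).astype(float)
            b = rng.integers(0, 10, size=n_b).astype(float)
            res = mann_whitney_u(a, b, mode="normal")
            assert res.U_A + res.U_B == pytest.approx(n_a * n_b)
            assert res.U == min(res.U_A, res.U_B)
            assert 0.0 <= res.p_value <= 1.0

    def test_exact_matches_enumeration_oracle_no_ties(self, rng):
        for n_a in range(2, 8):
            for n_b in range(2, 8):
                vals = rng.permutation(100)[: n_a + n_b].astype(float)
                a, b = vals[:n_a], vals[n_a:]
                res = mann_whitney_u(a, b, mode="exact")
                assert res.p_value == pytest.approx(_brute_force_exact_p(a, b), abs=1e-12)

    def test_exact_matches_scipy(self, rng):
        for _ in range(30):
            n_a, n_b = rng.integers(2, 10, size=2)
            vals = rng.permutation(1000)[: n_a + n_b].astype(float)
            a, b = vals[:n_a], vals[n_a:]
            res = mann_whitney_u(a, b, mode="exact")
            ref = mannwhitneyu(a, b, method="exact")
            assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_normal_with_ties_matches_scipy(self, rng):
        for _ in range(30):
            n_a, n_b = rng.integers(5, 25, size=2)
            a = rng.integers(0, 6, size=n_a).astype(float)
            b = rng.integers(0, 6, size=n_b).astype(float)
            if np.unique(np.concatenate([a, b])).size == 1:
                continue
            res = mann_whitney_u(a, b, mode="normal")
            ref = mannwhitneyu(a, b, method="asymptotic", use_continuity=True)
            assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-10)

    def test_normal_converges_to_exact(self, rng):
        vals = rng.permutation(10_000)[:30].astype(float)
        a, b = vals[:15], vals[15:]
        exact = mann_whitney_u(a, b, mode="exact").p_value
        approx = mann_whitney_u(a, b, mode="normal").p_value
        assert abs(exact - approx) < 0.01

    def test_exact_with_ties_small_matches_oracle(self, rng):
        for _ in range(20):
            n_a, n_b = rng.integers(2, 7, size=2)
            a = rng.integers(0, 4, size=n_a).astype(float)
            b = rng.integers(0, 4, size=n_b).astype(float)
            res = mann_whitney_u(a, b, mode="exact")
            assert res.p_value == pytest.approx(_brute_force_exact_p(a, b), abs=1e-12)

    def test_exact_with_ties_large_rejected(self):
        a = [1.0, 1.0] + list(range(20))
        b = [1.0, 2.0] + list(range(30, 48))
        with pytest.raises(ValueError, match="too large"):
            mann_whitney_u(a, b, mode="exact")

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_auto_switches_to_normal_for_large_n(self, rng):
        a = rng.normal(size=25)
        b = rng.normal(size=5)
        assert mann_whitney_u(a, b).method == "normal_approx"


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.005, 0.05]), [0.01, 0.05])

    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(1000):
            p = rng.random(size=int(rng.integers(1, 40)))
            mine = bh_fdr(p)
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.random(size=50)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_monotone_rejections_when_p_shrinks(self, rng):
        p = rng.random(size=30)
        q = bh_fdr(p)
        shrunk = p.copy()
        shrunk[rng.integers(0, 30)] *= 0.1
        q2 = bh_fdr(shrunk)
        assert (q2 < 0.05).sum() >= (q < 0.05).sum()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])


def _two_groups(rng, n_feat=6, n_a=20, n_b=20, shift=None):
    a = pd.DataFrame(
        rng.lognormal(0, 0.4, size=(n_a, n_feat)),
        columns=[f"f{i}" for i in range(n_feat)],
    )
    b = pd.DataFrame(
        rng.lognormal(0, 0.4, size=(n_b, n_feat)),
        columns=[f"f{i}" for i in range(n_feat)],
    )
    if shift:
        for feat, fold in shift.items():
            b[feat] *= fold
    return a, b


class TestDifferentialTable:
    def test_planted_shift_detected(self, rng):
        a, b = _two_groups(rng, n_a=49, n_b=49, shift={"f0": 2.0})
        table = differential_table(a, b)
        assert table.loc["f0", "q"] < 0.05
        assert table.loc["f0", "direction"] == "up"
        assert table.loc["f0", "pct_diff"] > 0

    def test_null_type_one_error_rate(self, rng):
        # 200 null cohorts: per-feature rejection rate should be ~ alpha at most
        rejections = 0
        tests = 0
        for _ in range(200):
            a, b = _two_groups(rng, n_feat=5, n_a=15, n_b=15)
            table = differential_table(a, b)
            rejections += int((table["p"] < 0.05).sum())
            tests += len(table)
        rate = rejections / tests
        assert rate < 0.05 + 0.02

    def test_permutation_within_groups_invariant(self, rng):
        a, b = _two_groups(rng)
        table1 = differential_table(a, b)
        table2 = differential_table(
            a.sample(frac=1, random_state=3), b.sample(frac=1, random_state=4)
        )
        pd.testing.assert_frame_equal(table1, table2)

    def test_constant_feature_flagged(self, rng):
        a, b = _two_groups(rng, n_feat=3)
        a["f0"] = 1.0
        b["f0"] = 1.0
        table = differential_table(a, b)
        assert table.loc["f0", "p"] == 1.0 and bool(table.loc["f0", "constant"])

    def test_pct_diff_can_exceed_100(self):
        a = pd.DataFrame({"f": [1.0, 1.1, 0.9, 1.0]})
        b = pd.DataFrame({"f": [4.0, 4.4, 3.6, 4.0]})
        table = differential_table(a, b)
        assert table.loc["f", "pct_diff"] > 100.0

    def test_requires_two_samples_per_group(self):
        a = pd.DataFrame({"f": [1.0]})
        b = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ValueError):
            differential_table(a, b)


class TestBenchmarkMetrics:
    def test_perfect_estimate(self):
        m = benchmark_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m == {"rmse": 0.0, "pearson_r": 1.0, "spearman_rs": 1.0}

    def test_rmse_hand_computed(self):
        with pytest.warns(UserWarning):  # constant estimate: correlations NaN
            m = benchmark_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert m["rmse"] == pytest.approx(math.sqrt(2.0 / 3.0))

    def test_monotone_nonlinear(self):
        m = benchmark_metrics([1.0, 2.0, 3.0], [1.0, 4.0, 9.0])
        assert m["spearman_rs"] == pytest.approx(1.0)
        assert m["pearson_r"] < 1.0

    def test_matches_scipy(self, rng):
        t = rng.normal(size=50)
        e = t + rng.normal(scale=0.5, size=50)
        m = benchmark_metrics(t, e)
        assert m["pearson_r"] == pytest.approx(float(pearsonr(t, e).statistic))
        assert m["spearman_rs"] == pytest.approx(float(spearmanr(t, e).statistic))

    def test_constant_vector_nan_with_warning(self):
        with pytest.warns(UserWarning):
            m = benchmark_metrics([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert math.isnan(m["pearson_r"])

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            benchmark_metrics([1.0], [1.0])


@given(
    st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60),
)
@settings(max_examples=50, deadline=None)
def test_bh_properties(p):
    q = bh_fdr(p)
    assert np.all((q >= np.asarray(p) - 1e-12) & (q <= 1.0))
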