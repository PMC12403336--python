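"""SAM statistic, permutation FDR and the signed fold-change convention."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lacrimark.diffabund import (
    DAParams,
    permutation_fdr,
    sam_statistic,
    signed_fold_change,
    volcano_table,
)


class TestSamStatistic:
    def test_equal_means_give_zero(self):
        assert sam_statistic([1, 2, 3], [3, 2, 1], s0=0.7) == pytest.approx(0.0)

    def test_reduces_to_pooled_t_at_s0_zero(self, rng):
        for _ in range(200):
            x1 = rng.normal(size=rng.integers(3, 12))
            x0 = rng.normal(size=rng.integers(3, 12))
            t_ref = stats.ttest_ind(x1, x0, equal_var=True).statistic
            assert sam_statistic(x1, x0, s0=0.0) == pytest.approx(t_ref, abs=1e-10)

    def test_hand_computed_example(self):
        # groups {1,2,3} vs {2,3,4}: pooled SE = sqrt(1*(1/3+1/3)) = 0.8165
        d = sam_statistic([1, 2, 3], [2, 3, 4], s0=0.1)
        assert d == pytest.approx(-1 / (math.sqrt(2 / 3) + 0.1), abs=1e-9)
        assert d == pytest.approx(-1.091, abs=5e-4)

    def test_antisymmetric_under_group_swap(self, rng):
        x1, x0 = rng.normal(size=6), rng.normal(size=8)
        assert sam_statistic(x1, x0, 0.3) == pytest.approx(-sam_statistic(x0, x1, 0.3))

    def test_large_s0_shrinks_towards_zero(self, rng):
        x1, x0 = rng.normal(1, 1, 10), rng.normal(0, 1, 10)
        assert abs(sam_statistic(x1, x0, s0=1e6)) < 1e-4

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            sam_statistic([1.0], [1.0, 2.0], 0.1)


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "log2fc, expected",
        [(-0.41, -1.33), (-0.46, -1.38), (0.31, 1.24), (-0.34, -1.27), (0.0, 1.00)],
    )
    def test_reporting_convention(self, log2fc, expected):
        assert round(signed_fold_change(log2fc), 2) == expected

    @given(l=st.floats(-8, 8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_magnitude_always_at_least_one(self, l):
        fc = signed_fold_change(l)
        assert abs(fc) >= 1.0
        assert (fc >= 0) == (l >= 0)


def _fdr_oracle(values: np.ndarray, case: np.ndarray, s0: float) -> np.ndarray:
    """Naive exhaustive-enumeration permutation FDR (independent of the
    implementation: plain loops, no shared code paths)."""

    def sam(v, c):
        x1, x0 = v[c], v[~c]
        n1, n0 = len(x1), len(x0)
        sp2 = ((n1 - 1) * np.var(x1, ddof=1) + (n0 - 1) * np.var(x0, ddof=1)) / (n1 + n0 - 2)
        return (np.mean(x1) - np.mean(x0)) / (math.sqrt(sp2 * (1 / n1 + 1 / n0)) + s0)

    n = values.shape[1]
    n_case = int(case.sum())
    d_obs = np.array([sam(values[i], case) for i in range(values.shape[0])])
    perm_stats = []
    for idx in combinations(range(n), n_case):
        c = np.zeros(n, dtype=bool)
        c[list(idx)] = True
        perm_stats.append([abs(sam(values[i], c)) for i in range(values.shape[0])])
    perm_stats = np.array(perm_stats)  # B x p
    B = perm_stats.shape[0]

    def raw_fdr(t):
        r = sum(abs(d) >= t for d in d_obs)
        v = sum((perm_stats >= t).sum(axis=1)) / B
        return min(1.0, v / r)

    thresholds = sorted(set(abs(d) for d in d_obs))
    fdr = np.empty_like(d_obs)
    for i, d in enumerate(d_obs):
        candidates = [raw_fdr(t) for t in thresholds if t <= abs(d) + 1e-15]
        fdr[i] = min(candidates)
    return fdr


class TestPermutationFdr:
    def test_matches_exhaustive_enumeration_3v3(self, rng):
        values = rng.normal(size=(8, 6))
        df = pd.DataFrame(values, index=[f"P{i}" for i in range(8)],
                          columns=[f"S{j}" for j in range(6)])
        groups = pd.Series(["ALS"] * 3 + ["control"] * 3, index=df.columns)
        res = permutation_fdr(df, groups, DAParams(n_permutations=20, seed=0))
        expected = _fdr_oracle(values, np.array([True] * 3 + [False] * 3), 0.1)
        assert np.allclose(res["fdr"].to_numpy(), expected, atol=1e-12)

    def test_null_data_yields_no_significant_calls(self, rng):
        values = rng.normal(size=(500, 20))
        df = pd.DataFrame(values, index=[f"P{i}" for i in range(500)],
                          columns=[f"S{j}" for j in range(20)])
        groups = pd.Series(["ALS"] * 10 + ["control"] * 10, index=df.columns)
        res = permutation_fdr(df, groups, DAParams(n_permutations=100, seed=1))
        assert res["significant"].mean() <= 0.01

    def test_fdr_bounded_and_monotone_in_statistic(self, rng):
        values = rng.normal(size=(60, 12))
        values[:5, :6] += 2.0  # plant some signal
        df = pd.DataFrame(values, index=[f"P{i}" for i in range(60)],
                          columns=[f"S{j}" for j in range(12)])
        groups = pd.Series(["ALS"] * 6 + ["control"] * 6, index=df.columns)
        res = permutation_fdr(df, groups, DAParams(n_permutations=50, seed=2))
        assert res["fdr"].between(0, 1).all()
        ordered = res.sort_values("sam_stat", key=lambda s: s.abs())
        assert (ordered["fdr"].diff().dropna() <= 1e-12).all()

    def test_deterministic_given_seed(self, rng):
        values = rng.normal(size=(30, 16))
        df = pd.DataFrame(values, index=[f"P{i}" for i in range(30)],
                          columns=[f"S{j}" for j in range(16)])
        groups = pd.Series(["ALS"] * 8 + ["control"] * 8, index=df.columns)
        p = DAParams(n_permutations=40, seed=9)
        a = permutation_fdr(df, groups, p)
        b = permutation_fdr(df, groups, p)
        assert a.equals(b)

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["P0"], columns=["S0", "S1"])
        groups = pd.Series(["ALS", "control"], index=df.columns)
        with pytest.raises(ValueError):
            permutation_fdr(df, groups)


class TestVolcanoTable:
    def test_all_null_reports_zero_significant(self, rng):
        values = rng.normal(size=(40, 12))
        df = pd.DataFrame(values, index=[f"P{i}" for i in range(40)],
                          columns=[f"S{j}" for j in range(12)])
        groups = pd.Series(["ALS"] * 6 + ["control"] * 6, index=df.columns)
        res = permutation_fdr(df, groups, DAParams(n_permutations=50, seed=3))
        _, counts = volcano_table(res)
        assert counts["n_significant"] <= 1

    def test_planted_direction_split_recovered(self, rng):
        values = rng.normal(size=(200, 40)) * 0.3
        values[:10, :20] -= 2.0  # 10 down in cases
        values[10:12, :20] += 2.0  # 2 up in cases
        df = pd.DataFrame(values, index=[f"P{i}" for i in range(200)],
                          columns=[f"S{j}" for j in range(40)])
        groups = pd.Series(["ALS"] * 20 + ["control"] * 20, index=df.columns)
        res = permutation_fdr(df, groups, DAParams(n_permutations=100, seed=4))
        table, counts = volcano_table(res)
        assert counts["n_down"] == 10
        assert counts["n_up"] == 2
        assert {"neg_log10_fdr", "log2fc", "fc_signed"} <= set(table.columns)
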