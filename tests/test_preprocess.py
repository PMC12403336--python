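"""Presence filtering, log2 transform, down-shifted imputation, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lacrimark.preprocess import (
    AbundanceMatrix,
    FilterParams,
    ImputeParams,
    filter_by_presence,
    impute_mnar_downshift,
    log2_transform,
    minmax_scale,
    preprocess,
)


def _matrix(values, mask=None, state="raw"):
    df = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"P{i}" for i in range(len(values))],
        columns=[f"S{j}" for j in range(len(values[0]))],
    )
    if mask is not None:
        df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))
    return AbundanceMatrix.from_dataframe(df, state=state)


class TestFilterByPresence:
    def test_complete_matrix_keeps_everything(self):
        m = _matrix(np.ones((4, 6)))
        groups = pd.Series(["ALS"] * 3 + ["control"] * 3, index=m.samples)
        assert filter_by_presence(m, groups).shape == (4, 6)

    def test_protein_below_threshold_in_one_group_removed(self):
        # 70% presence in controls but 50% in cases at threshold 2/3 -> out
        values = np.ones((1, 20))
        mask = np.zeros((1, 20), dtype=bool)
        mask[0, 10:15] = True  # 5 of 10 case samples missing
        mask[0, 0:3] = True  # 3 of 10 control samples missing
        m = _matrix(values, mask)
        groups = pd.Series(["control"] * 10 + ["ALS"] * 10, index=m.samples)
        out = filter_by_presence(m, groups)
        assert out.shape[0] == 0

    def test_matches_brute_force_counting(self, rng):
        values = np.abs(rng.normal(10, 2, size=(50, 20))) + 1
        mask = rng.random((50, 20)) < 0.4
        m = _matrix(values, mask)
        groups = pd.Series(["control"] * 11 + ["ALS"] * 9, index=m.samples)
        thr = 2.0 / 3.0
        out = filter_by_presence(m, groups, FilterParams(thr))
        expected = []
        for i, pid in enumerate(m.proteins):
            ok = True
            for g in ("control", "ALS"):
                cols = [j for j, s in enumerate(m.samples) if groups[s] == g]
                frac = sum(not mask[i, j] for j in cols) / len(cols)
                ok &= frac >= thr - 1e-12
            if ok:
                expected.append(pid)
        assert list(out.proteins) == expected

    @given(thr_lo=st.floats(0.1, 0.5), delta=st.floats(0.0, 0.5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, thr_lo, delta):
        rng = np.random.default_rng(7)
        values = np.ones((30, 12))
        mask = rng.random((30, 12)) < 0.45
        m = _matrix(values, mask)
        groups = pd.Series(["control"] * 6 + ["ALS"] * 6, index=m.samples)
        lo = set(filter_by_presence(m, groups, FilterParams(thr_lo)).proteins)
        hi = set(
            filter_by_presence(m, groups, FilterParams(min(1.0, thr_lo + delta))).proteins
        )
        assert hi <= lo

    def test_empty_group_rejected(self, small_matrix):
        groups = pd.Series(["ALS"] * 10, index=small_matrix.samples)
        # a group present in metadata but with zero samples cannot arise via
        # groupby; missing labels are the error surface instead
        with pytest.raises(ValueError):
            filter_by_presence(small_matrix, groups.iloc[:5])


class TestLog2Transform:
    def test_known_values(self):
        m = _matrix([[8.0, 1.0]])
        out = log2_transform(m)
        assert out.values.iloc[0, 0] == 3.0
        assert out.values.iloc[0, 1] == 0.0
        assert out.state == "log2"

    def test_zero_value_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            log2_transform(_matrix([[4.0, 0.0]]))

    def test_mask_unchanged(self, small_matrix):
        out = log2_transform(small_matrix)
        assert out.mask.equals(small_matrix.mask)


class TestImputeDownshift:
    def test_no_missing_is_identity(self):
        m = _matrix([[1.0, 2.0, 3.0]], state="raw")
        logged = log2_transform(m)
        out = impute_mnar_downshift(logged, ImputeParams(seed=1))
        assert np.allclose(out.values, logged.values)

    def test_imputed_distribution_matches_downshifted_normal(self):
        # column with observed mean 20, sd 2: imputed draws ~ N(16.4, 0.6^2)
        rng = np.random.default_rng(5)
        n_obs, n_miss = 2000, 30000
        obs = rng.normal(20.0, 2.0, size=n_obs)
        col = np.concatenate([obs, np.full(n_miss, np.nan)])
        df = pd.DataFrame({"S0": col}, index=[f"P{i}" for i in range(col.size)])
        m = AbundanceMatrix.from_dataframe(df, state="log2")
        out = impute_mnar_downshift(m, ImputeParams(seed=2))
        imputed = out.values.to_numpy()[n_obs:, 0]
        mu, sd = obs.mean(), obs.std(ddof=1)
        assert abs(imputed.mean() - (mu - 1.8 * sd)) < 0.02
        assert abs(imputed.std(ddof=1) - 0.3 * sd) < 0.01

    def test_only_masked_cells_touched(self, small_matrix):
        logged = log2_transform(small_matrix)
        out = impute_mnar_downshift(logged, ImputeParams(seed=3))
        obs = ~small_matrix.mask.to_numpy()
        assert np.array_equal(
            out.values.to_numpy()[obs], logged.values.to_numpy()[obs]
        )
        assert not out.mask.to_numpy().any()
        assert out.state == "imputed"

    def test_deterministic_given_seed(self, small_matrix):
        logged = log2_transform(small_matrix)
        a = impute_mnar_downshift(logged, ImputeParams(seed=11))
        b = impute_mnar_downshift(logged, ImputeParams(seed=11))
        c = impute_mnar_downshift(logged, ImputeParams(seed=12))
        assert a.values.equals(b.values)
        assert not a.values.equals(c.values)

    def test_column_with_single_observation_rejected(self):
        df = pd.DataFrame({"S0": [5.0, np.nan, np.nan]}, index=["P0", "P1", "P2"])
        m = AbundanceMatrix.from_dataframe(df, state="log2")
        with pytest.raises(ValueError, match="S0"):
            impute_mnar_downshift(m, ImputeParams(seed=0))


class TestMinMaxScale:
    def test_known_row(self):
        m = _matrix([[2.0, 4.0, 6.0]], state="raw")
        m.state = "imputed"
        out = minmax_scale(m)
        assert np.allclose(out.values.to_numpy(), [[0.0, 0.5, 1.0]])
        assert out.state == "scaled"

    def test_constant_row_maps_to_zero(self):
        m = _matrix([[3.0, 3.0, 3.0]], state="raw")
        m.state = "imputed"
        assert (minmax_scale(m).values.to_numpy() == 0).all()

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        m = _matrix(rng.normal(size=(8, 6)))
        m.state = "imputed"
        v = minmax_scale(m).values.to_numpy()
        assert v.min() >= 0.0 and v.max() <= 1.0


def test_full_preprocess_deterministic(small_matrix, small_groups):
    a_imp, a_sc = preprocess(small_matrix, small_groups, seed=42)
    b_imp, b_sc = preprocess(small_matrix, small_groups, seed=42)
    assert a_imp.values.equals(b_imp.values)
    assert a_sc.values.equals(b_sc.values)


def test_state_transitions_enforced(small_matrix):
    with pytest.raises(ValueError):
        minmax_scale(small_matrix)  # raw -> scaled is not a legal jump
    with pytest.raises(ValueError):
        impute_mnar_downshift(small_matrix)  # raw -> imputed skips log2
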