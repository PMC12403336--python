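"""Densitometry normalization, mindet imputation, group tests, in-silico ML."""

import numpy as np
import pandas as pd
import pytest

from lacrimark.ml import ModelSpec, ResampleParams
from lacrimark.wb import (
    group_test_bonferroni,
    lasso_selection_profile,
    mindet_impute,
    normalize_band,
    normalize_panel,
    validation_ml,
)

FAST_LASSO = ModelSpec("lasso_logistic", grid=tuple({"lam": l} for l in (0.1, 0.3, 1.0)))


class TestNormalizeBand:
    def test_band_equal_to_standard_unit_protein(self):
        assert normalize_band(1000.0, 1000.0, 1.0) == pytest.approx(0.0)

    def test_worked_arithmetic(self):
        # 2000 / 1000 standard / 30 ug -> log10(2/30)
        assert normalize_band(2000.0, 1000.0, 30.0) == pytest.approx(-1.176, abs=5e-4)

    def test_membrane_scale_equivariance(self, rng):
        band, std, total = 1500.0, 900.0, 25.0
        for c in (0.1, 3.0, 42.0):
            assert normalize_band(band * c, std * c, total) == pytest.approx(
                normalize_band(band, std, total)
            )

    def test_missing_band_stays_missing(self):
        out = normalize_band(np.array([np.nan, 100.0]), np.array([50.0, 50.0]),
                             np.array([2.0, 2.0]))
        assert np.isnan(out[0]) and np.isfinite(out[1])

    def test_non_positive_band_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            normalize_band(np.array([0.0]), np.array([1.0]), np.array([1.0]))


class TestMindetImpute:
    def test_no_missing_is_identity(self, rng):
        panel = pd.DataFrame(rng.normal(size=(3, 6)))
        assert mindet_impute(panel).equals(panel)

    def test_missing_gets_protein_minimum(self):
        panel = pd.DataFrame([[-1.0, 0.2, np.nan]], index=["P1"], columns=list("abc"))
        out = mindet_impute(panel)
        assert out.loc["P1", "c"] == -1.0

    def test_never_below_observed_minimum(self, rng):
        v = rng.normal(size=(5, 20))
        v[rng.random((5, 20)) < 0.2] = np.nan
        panel = pd.DataFrame(v)
        out = mindet_impute(panel)
        for i in panel.index:
            assert out.loc[i].min() >= np.nanmin(panel.loc[i].to_numpy())

    def test_all_missing_protein_rejected(self):
        panel = pd.DataFrame([[np.nan, np.nan]], index=["P1"])
        with pytest.raises(ValueError, match="P1"):
            mindet_impute(panel)


class TestGroupTestBonferroni:
    def _labels(self, n1, n0):
        idx = [f"S{i}" for i in range(n1 + n0)]
        return pd.Series(["ALS"] * n1 + ["control"] * n0, index=idx), idx

    def test_identical_groups_give_p_one(self):
        labels, idx = self._labels(5, 5)
        panel = pd.DataFrame([list(range(5)) * 2], index=["P1"], columns=idx, dtype=float)
        out = group_test_bonferroni(panel, labels, m=6)
        assert out.loc["P1", "t_stat"] == pytest.approx(0.0)
        assert out.loc["P1", "p_raw"] == pytest.approx(1.0)
        assert out.loc["P1", "p_adj"] == pytest.approx(1.0)

    def test_bonferroni_arithmetic(self, rng):
        labels, idx = self._labels(10, 10)
        panel = pd.DataFrame(rng.normal(size=(1, 20)), index=["P1"], columns=idx)
        out = group_test_bonferroni(panel, labels, m=6)
        assert out.loc["P1", "p_adj"] == pytest.approx(min(1.0, 6 * out.loc["P1", "p_raw"]))

    def test_adjusted_never_below_raw_and_capped(self, rng):
        labels, idx = self._labels(8, 9)
        panel = pd.DataFrame(rng.normal(size=(6, 17)),
                             index=[f"P{i}" for i in range(6)], columns=idx)
        out = group_test_bonferroni(panel, labels)
        assert (out["p_adj"] >= out["p_raw"] - 1e-15).all()
        assert (out["p_adj"] <= 1.0).all()
        assert (out["m"] == 6).all()

    def test_planted_shift_detected_with_high_power(self):
        # 1 pooled-SD shift at 50/50 survives a Bonferroni over 6 proteins
        detected = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            labels, idx = self._labels(50, 50)
            v = rng.normal(size=(1, 100))
            v[0, :50] += 1.0
            panel = pd.DataFrame(v, index=["P1"], columns=idx)
            out = group_test_bonferroni(panel, labels, m=6)
            detected += out.loc["P1", "p_adj"] < 0.05
        assert detected / n_seeds >= 0.90


class TestNormalizePanel:
    def test_round_trip_wide_shape(self, rng):
        records = pd.DataFrame(
            {
                "protein": ["A", "A", "B", "B"],
                "sample": ["s1", "s2", "s1", "s2"],
                "membrane": ["M1", "M1", "M1", "M1"],
                "band": [100.0, 200.0, np.nan, 50.0],
                "standard": [100.0] * 4,
                "total_protein": [10.0, 20.0, 10.0, 20.0],
            }
        )
        wide = normalize_panel(records)
        assert wide.shape == (2, 2)
        assert np.isnan(wide.loc["B", "s1"])
        assert wide.loc["A", "s1"] == pytest.approx(np.log10((100 / 100) / 10))

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="lacks columns"):
            normalize_panel(pd.DataFrame({"protein": [], "sample": []}))


class TestValidationMl:
    def _panel(self, seed, signal=(0.0, 0.0), n=60):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(2, n))
        v[0, : n // 2] += signal[0]
        v[1, : n // 2] += signal[1]
        panel = pd.DataFrame(v, index=["HP", "SERPINC1"],
                             columns=[f"S{i}" for i in range(n)])
        labels = pd.Series(["ALS"] * (n // 2) + ["control"] * (n // 2), index=panel.columns)
        return panel, labels

    def test_uninformative_feature_scores_at_chance(self):
        aucs = []
        for seed in range(25):
            panel, labels = self._panel(seed)
            res, _ = validation_ml(panel, labels, {"hp": ["HP"]},
                                   ResampleParams(n_bootstrap=4, inner_folds=3, seed=seed),
                                   models=[FAST_LASSO])
            aucs.append(res["auroc_mean"].iloc[0])
        assert abs(np.mean(aucs) - 0.5) < 0.07

    def test_combining_two_signals_does_not_hurt(self):
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            panel, labels = self._panel(seed, signal=(0.9, 0.9))
            res, _ = validation_ml(
                panel, labels,
                {"hp": ["HP"], "serpinc1": ["SERPINC1"], "both": ["HP", "SERPINC1"]},
                ResampleParams(n_bootstrap=12, inner_folds=3, seed=seed),
                models=[FAST_LASSO],
            )
            by_set = res.set_index("feature_set")["auroc_mean"]
            wins += by_set["both"] >= max(by_set["hp"], by_set["serpinc1"]) - 0.02
        assert wins >= 8

    def test_selection_profile_ranks_informative_protein_first(self):
        panel, labels = self._panel(3, signal=(1.5, 0.0))
        profile = lasso_selection_profile(panel, labels, outer_folds=5, inner_folds=3, seed=3)
        assert profile.index[0] == "HP"
        assert profile.iloc[0] >= profile.iloc[1]

    def test_empty_feature_set_rejected(self):
        panel, labels = self._panel(0)
        with pytest.raises(ValueError, match="empty"):
            validation_ml(panel, labels, {"none": []})
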