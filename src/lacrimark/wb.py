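"""Densitometry (Western blot) validation stage.

Band intensities are normalised to a pooled tear-fluid standard loaded on
every membrane (removing inter-membrane variability) and then to the total
protein amount of the sample (removing collection-volume differences), and
reported on the log10 scale:

    value = log10( (band / pooled_standard) / total_protein_ug )

Missing bands are imputed with the minimum detected value of the protein
(mindet), group differences are tested with equal-variance t-tests under a
Bonferroni correction, and the small validated panel is re-evaluated with
the same classifier bench used in discovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ml import MODEL_KINDS, ModelSpec, ResampleParams, bootstrap_bench, nested_cv_train

REQUIRED_COLUMNS = ("protein", "sample", "membrane", "band", "standard", "total_protein")


def normalize_band(band, standard, total_protein_ug):
    """log10 normalised abundance of one band (vectorised).

    Missing bands (NaN) stay missing; non-positive recorded intensities are
    rejected.
    """
    scalar = np.isscalar(band) or np.ndim(band) == 0
    band, standard, total = np.broadcast_arrays(
        np.asarray(band, dtype=float),
        np.asarray(standard, dtype=float),
        np.asarray(total_protein_ug, dtype=float),
    )
    if np.any(standard <= 0) or np.any(total <= 0):
        raise ValueError("pooled standard and total protein must be positive")
    observed = ~np.isnan(band)
    if np.any(band[observed] <= 0):
        raise ValueError("non-positive band intensity present")
    out = np.full(band.shape, np.nan)
    out[observed] = np.log10((band[observed] / standard[observed]) / total[observed])
    return float(out) if scalar else out


def normalize_panel(records: pd.DataFrame) -> pd.DataFrame:
    """Long densitometry table -> wide protein x sample log10 matrix.

    ``records`` needs columns protein, sample, membrane, band, standard,
    total_protein; technical replicates are expected to be averaged upstream.
    """
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"densitometry table lacks columns: {sorted(missing)}")
    vals = normalize_band(
        records["band"].to_numpy(dtype=float),
        records["standard"].to_numpy(dtype=float),
        records["total_protein"].to_numpy(dtype=float),
    )
    long = records[["protein", "sample"]].copy()
    long["value"] = vals
    wide = long.pivot(index="protein", columns="sample", values="value")
    return wide


def mindet_impute(panel: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing value with the protein's minimum observed value."""
    out = panel.copy()
    for protein, row in out.iterrows():
        if row.isna().all():
            raise ValueError(f"protein {protein!r} has no observed values")
        out.loc[protein] = row.fillna(row.min())
    return out


def group_test_bonferroni(
    panel: pd.DataFrame,
    groups: pd.Series,
    m: int | None = None,
    case_label: str = "ALS",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Equal-variance two-sample t-test per protein with Bonferroni correction.

    Reports group medians and IQR (Q1, Q3) on the log10 scale and the outcome
    of the D'Agostino-Pearson and Shapiro-Wilk normality tests per group;
    the t-test is applied regardless, with a warning when normality is
    rejected at alpha = 0.05 in either group.
    """
    groups = pd.Series(groups).reindex(panel.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    case_cols = groups[groups == case_label].index
    ctrl_cols = groups[groups != case_label].index
    if len(case_cols) < 3 or len(ctrl_cols) < 3:
        raise ValueError("need at least 3 samples per group")
    m = m if m is not None else len(panel.index)
    rows = []
    for protein, row in panel.iterrows():
        x1 = row[case_cols].dropna().to_numpy(dtype=float)
        x0 = row[ctrl_cols].dropna().to_numpy(dtype=float)
        if x1.std(ddof=1) == 0 and x0.std(ddof=1) == 0:
            if x1.mean() == x0.mean():
                t, p = 0.0, 1.0
            else:
                raise ValueError(f"degenerate variance in both groups for {protein!r}")
        else:
            t, p = stats.ttest_ind(x1, x0, equal_var=equal_var)
        normal_flags = {}
        for name, x in (("case", x1), ("control", x0)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    dp_p = float(stats.normaltest(x).pvalue)
                except ValueError:
                    dp_p = np.nan
                sw_p = float(stats.shapiro(x).pvalue)
            normal_flags[f"dagostino_p_{name}"] = dp_p
            normal_flags[f"shapiro_p_{name}"] = sw_p
        rejected = any(
            p_ < 0.05 for p_ in normal_flags.values() if not np.isnan(p_)
        )
        if rejected:
            warnings.warn(f"normality rejected for {protein!r}; t-test applied regardless")
        q = lambda x: np.percentile(x, [25, 50, 75])
        q1c, medc, q3c = q(x1)
        q1k, medk, q3k = q(x0)
        rows.append(
            {
                "protein": protein,
                "median_case": medc, "q1_case": q1c, "q3_case": q3c,
                "median_control": medk, "q1_control": q1k, "q3_control": q3k,
                "t_stat": float(t), "p_raw": float(p),
                "p_adj": float(min(1.0, m * p)), "m": m,
                "normality_rejected": bool(rejected),
                **normal_flags,
            }
        )
    return pd.DataFrame(rows).set_index("protein")


def lasso_selection_profile(
    panel: pd.DataFrame,
    groups: pd.Series,
    outer_folds: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
    lasso: ModelSpec | None = None,
    case_label: str = "ALS",
) -> pd.Series:
    """Selection counts of each protein across nested-CV lasso iterations.

    For each outer fold, a lasso is tuned by inner CV on the training part;
    a protein counts as selected when its refit coefficient is nonzero.
    Sorted most-consistently-selected first.
    """
    from sklearn.model_selection import StratifiedKFold

    lasso = lasso or ModelSpec(
        "lasso_logistic",
        grid=tuple({"lam": float(l)} for l in (0.0, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)),
    )
    groups = pd.Series(groups).reindex(panel.columns)
    X = panel.to_numpy(dtype=float).T
    y = (groups == case_label).to_numpy().astype(int)
    k = min(outer_folds, int(np.unique(y, return_counts=True)[1].min()))
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    counts = np.zeros(panel.shape[0], dtype=int)
    for tr, _ in cv.split(X, y):
        est, _, _ = nested_cv_train(lasso, X[tr], y[tr], inner_folds, seed)
        counts += (np.asarray(est.coef_).ravel() != 0).astype(int)
    return pd.Series(counts, index=panel.index).sort_values(ascending=False)


def validation_ml(
    panel: pd.DataFrame,
    groups: pd.Series,
    feature_sets: dict[str, list[str]],
    params: ResampleParams | None = None,
    models: list[ModelSpec] | None = None,
    case_label: str = "ALS",
) -> tuple[pd.DataFrame, pd.Series]:
    """Classifier bench on small densitometry feature sets.

    Returns (AUROC summary per model x feature set, lasso selection profile
    over the full panel).
    """
    params = params or ResampleParams(n_bootstrap=50)
    models = models or [ModelSpec(k) for k in MODEL_KINDS]
    rows = []
    for name, features in feature_sets.items():
        if not features:
            raise ValueError(f"feature set {name!r} is empty")
        missing = set(features) - set(panel.index)
        if missing:
            raise ValueError(f"feature set {name!r} has unknown proteins: {sorted(missing)}")
        bench = bootstrap_bench(panel.loc[features], groups, models, params, case_label)
        summ = bench.summary()
        for model, row in summ.iterrows():
            rows.append(
                {"feature_set": name, "model": model,
                 "auroc_mean": row["auroc_mean"], "auroc_sd": row["auroc_std"]}
            )
    profile = lasso_selection_profile(
        panel, groups, params.inner_folds, params.inner_folds, params.seed,
        case_label=case_label,
    )
    return pd.DataFrame(rows), profile
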