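"""Clinical derivations and the cohort-comparison statistical battery.

Disease progression is summarised by the ALSFRS-R decline rate (dFRS):
points lost per month between symptom onset (assumed full score, 48) and the
first recorded ALSFRS-R, with fast (> 1.11), intermediate (0.47-1.11,
boundaries inclusive) and slow (< 0.47) progressor classes.

Cohort tables report median (IQR: Q1, Q3) for quantitative variables and
counts (%) for categorical ones. The test battery follows standard clinical
practice: Fisher's exact test for 2x2 categorical contrasts, chi-square
(no continuity correction) for r x c contrasts, a normality gate
(D'Agostino-Pearson AND Shapiro-Wilk, alpha = 0.05) deciding between the
unpaired t-test and the Mann-Whitney test for two-group quantitative
variables, and Kruskal-Wallis for multi-group quantitative comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FULL_ALSFRS = 48.0
FAST_CUTOFF = 1.11  # points/month; dFRS above this is "fast"
SLOW_CUTOFF = 0.47  # dFRS below this is "slow"


@dataclass(frozen=True)
class ProgressionClass:
    delta_frs: float
    label: str  # fast | intermediate | slow


def delta_frs(first_recorded_score: float, months_between: float,
              baseline_score: float = FULL_ALSFRS) -> float:
    """ALSFRS-R decline rate in points/month.

    ``baseline_score`` defaults to the full score of 48 assumed at symptom
    onset.
    """
    if months_between <= 0:
        raise ValueError("months_between must be positive")
    for s in (first_recorded_score, baseline_score):
        if not (0.0 <= s <= 48.0):
            raise ValueError("ALSFRS-R scores must lie in [0, 48]")
    return (baseline_score - first_recorded_score) / months_between


def classify_progression(dfrs: float) -> ProgressionClass:
    """Map a dFRS value to fast / intermediate / slow (boundaries intermediate)."""
    if not np.isfinite(dfrs):
        raise ValueError("delta FRS must be finite")
    if dfrs > FAST_CUTOFF:
        label = "fast"
    elif dfrs < SLOW_CUTOFF:
        label = "slow"
    else:
        label = "intermediate"
    return ProgressionClass(delta_frs=float(dfrs), label=label)


def disease_duration_months(onset_date, collection_date) -> float:
    """Months between symptom onset and tear-fluid collection."""
    delta = pd.Timestamp(collection_date) - pd.Timestamp(onset_date)
    if delta.days < 0:
        raise ValueError("collection before onset")
    return delta.days / 30.4375  # mean Gregorian month


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (sum of hypergeometric
    probabilities not exceeding the observed table's)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin")
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    """Conservative gate: both D'Agostino-Pearson and Shapiro-Wilk must not
    reject. D'Agostino needs n >= 8; below that only Shapiro decides."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sw = stats.shapiro(x).pvalue
        try:
            dp = stats.normaltest(x).pvalue
        except ValueError:
            dp = 1.0
    return bool(sw >= alpha and dp >= alpha)


def _quant_summary(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}, {q3:.1f})"


def cohort_table(
    records: pd.DataFrame,
    group_col: str,
    variables: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cohort-comparison table over declared variables.

    ``variables`` maps column name -> kind in {"continuous", "binary",
    "categorical"}. Two groups: Fisher (binary), chi-square (categorical),
    t-test vs Mann-Whitney gated on normality (continuous). More than two
    groups: chi-square for categorical kinds, Kruskal-Wallis for continuous.
    """
    groups = records[group_col]
    levels = sorted(groups.dropna().unique().tolist(), key=str)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for var, kind in variables.items():
        if kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown variable kind {kind!r} for {var!r}")
        col = records[var]
        if col.isna().all():
            rows.append({"variable": var, "kind": kind, "test": "none",
                         "p_value": np.nan, "note": "all values missing"})
            continue
        per_group = [col[groups == g].dropna() for g in levels]
        summary = {}
        if kind == "continuous":
            for g, x in zip(levels, per_group):
                summary[str(g)] = _quant_summary(x.to_numpy(dtype=float))
            if len(levels) == 2:
                x0, x1 = (x.to_numpy(dtype=float) for x in per_group)
                if _is_normal(x0, alpha) and _is_normal(x1, alpha):
                    test, p = "t-test", stats.ttest_ind(x0, x1, equal_var=True).pvalue
                else:
                    test, p = "mann-whitney", stats.mannwhitneyu(
                        x0, x1, alternative="two-sided").pvalue
            else:
                test = "kruskal-wallis"
                p = stats.kruskal(*[x.to_numpy(dtype=float) for x in per_group]).pvalue
        else:
            ct = pd.crosstab(groups, col)
            for g in levels:
                if g not in ct.index:
                    summary[str(g)] = "n/a"
                    continue
                n = ct.loc[g]
                summary[str(g)] = " / ".join(
                    f"{cat}: {int(c)} ({100 * c / n.sum():.1f}%)" for cat, c in n.items()
                )
            if len(ct.index) < 2 or len(ct.columns) < 2:
                rows.append({"variable": var, "kind": kind, "test": "none",
                             "p_value": np.nan, "note": "observed in a single stratum",
                             **summary})
                continue
            if kind == "binary" and len(levels) == 2 and ct.shape == (2, 2):
                test, p = "fisher", fisher_exact_2x2(ct.to_numpy())
            else:
                test = "chi-square"
                p = stats.chi2_contingency(ct.to_numpy(), correction=False).pvalue
        rows.append({"variable": var, "kind": kind, "test": test,
                     "p_value": round(float(p), 3), **summary})
    return pd.DataFrame(rows)
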