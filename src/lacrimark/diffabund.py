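"""Two-sample differential abundance with a SAM-style statistic and
permutation-based FDR.

The test statistic is d = (mean_case - mean_control) / (se_pooled + s0),
where se_pooled is the classical pooled-variance two-sample standard error
and s0 is a small positive "fudge" constant that stabilises proteins with
tiny variance. Significance is controlled by permuting group labels: at a
cutoff |d*| the FDR estimate is the mean permutation count of statistics
exceeding |d*| divided by the observed count, clipped to [0, 1] and made
monotone so that more stringent cutoffs never report a larger FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .preprocess import as_values_frame


@dataclass(frozen=True)
class DAParams:
    s0: float = 0.1
    fdr_threshold: float = 0.1
    n_permutations: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def sam_statistic(x_case, x_control, s0: float = 0.1) -> float:
    """SAM-style two-sample statistic for a single protein.

    Equals the pooled two-sample t statistic when ``s0 == 0``.
    """
    x1 = np.asarray(x_case, dtype=float)
    x0 = np.asarray(x_control, dtype=float)
    if x1.size < 2 or x0.size < 2:
        raise ValueError("need at least 2 observations per group")
    n1, n0 = x1.size, x0.size
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n0 - 1) * x0.var(ddof=1)) / (n1 + n0 - 2)
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    return float((x1.mean() - x0.mean()) / (se + s0))


def _sam_all(values: np.ndarray, case: np.ndarray, s0: float) -> np.ndarray:
    """Vectorised SAM statistic across all proteins (rows of ``values``)."""
    n1 = int(case.sum())
    n0 = case.size - n1
    x1 = values[:, case]
    x0 = values[:, ~case]
    m1 = x1.mean(axis=1)
    m0 = x0.mean(axis=1)
    sp2 = ((n1 - 1) * x1.var(axis=1, ddof=1) + (n0 - 1) * x0.var(axis=1, ddof=1)) / (n1 + n0 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    return (m1 - m0) / (se + s0)


def signed_fold_change(log2fc: float) -> float:
    """Signed fold-change reporting convention.

    FC = 2**L for L >= 0 and FC = -(2**|L|) for L < 0, i.e. a halving is
    reported as -2 rather than 0.5. Rounding happens only at presentation.
    """
    if not np.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    return float(2.0 ** log2fc) if log2fc >= 0 else float(-(2.0 ** (-log2fc)))


def _case_index_sets(n: int, n_case: int, n_permutations: int, rng: np.random.Generator):
    """Distinct case-label assignments: exhaustive when feasible, otherwise
    sampled without replacement."""
    total = math.comb(n, n_case)
    if total <= 1:
        raise ValueError("too few samples to permute group labels")
    if total <= n_permutations:
        return [np.array(c) for c in combinations(range(n), n_case)]
    seen: set[tuple[int, ...]] = set()
    out = []
    while len(out) < n_permutations:
        c = tuple(sorted(rng.choice(n, size=n_case, replace=False).tolist()))
        if c in seen:
            continue
        seen.add(c)
        out.append(np.array(c))
    return out


def permutation_fdr(
    matrix, groups: pd.Series, params: DAParams | None = None, case_label: str = "ALS"
) -> pd.DataFrame:
    """Per-protein SAM statistics with permutation-based FDR.

    Parameters
    ----------
    matrix : AbundanceMatrix or DataFrame
        Imputed (complete) protein x sample matrix on the log2 scale.
    groups : Series
        Sample id -> group label; ``case_label`` marks the case group.

    Returns
    -------
    DataFrame indexed by protein with columns ``log2fc``, ``fc_signed``,
    ``sam_stat``, ``fdr``, ``neg_log10_fdr``, ``significant``, ``direction``.
    """
    params = params or DAParams()
    values_df = as_values_frame(matrix)
    groups = pd.Series(groups).reindex(values_df.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    case = (groups == case_label).to_numpy()
    if case.sum() < 2 or (~case).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    values = values_df.to_numpy(dtype=float)

    d_obs = _sam_all(values, case, params.s0)
    abs_obs = np.abs(d_obs)

    rng = np.random.default_rng(params.seed)
    assignments = _case_index_sets(values.shape[1], int(case.sum()), params.n_permutations, rng)
    n_perm = len(assignments)
    perm_abs = np.empty(n_perm * values.shape[0])
    for b, idx in enumerate(assignments):
        perm_case = np.zeros(values.shape[1], dtype=bool)
        perm_case[idx] = True
        perm_abs[b * values.shape[0] : (b + 1) * values.shape[0]] = np.abs(
            _sam_all(values, perm_case, params.s0)
        )
    perm_abs.sort()
    abs_sorted = np.sort(abs_obs)

    # raw FDR at each observed |d| as candidate cutoff, then running minimum
    # over less stringent cutoffs so FDR is non-increasing in |d*|
    thresholds = np.unique(abs_obs)
    n_exceed_perm = perm_abs.size - np.searchsorted(perm_abs, thresholds, side="left")
    n_exceed_obs = abs_sorted.size - np.searchsorted(abs_sorted, thresholds, side="left")
    raw = np.clip((n_exceed_perm / n_perm) / n_exceed_obs, 0.0, 1.0)
    monotone = np.minimum.accumulate(raw)  # thresholds ascending -> running min
    fdr = monotone[np.searchsorted(thresholds, abs_obs)]

    log2fc = values[:, case].mean(axis=1) - values[:, ~case].mean(axis=1)
    with np.errstate(divide="ignore"):
        neg_log10 = np.where(fdr > 0, -np.log10(np.where(fdr > 0, fdr, 1.0)), np.inf)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fc_signed": [signed_fold_change(v) for v in log2fc],
            "sam_stat": d_obs,
            "fdr": fdr,
            "neg_log10_fdr": neg_log10,
            "significant": fdr < params.fdr_threshold,
            "direction": np.where(log2fc >= 0, "up", "down"),
        },
        index=values_df.index,
    )
    return out


def volcano_table(results: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Sort DA results for reporting and count significant proteins by direction.

    Returns the table sorted by FDR then |log2fc| (descending) and a dict with
    ``n_significant``, ``n_up`` and ``n_down``.
    """
    tab = results.copy()
    tab["_abs_fc"] = tab["log2fc"].abs()
    tab = tab.sort_values(["fdr", "_abs_fc"], ascending=[True, False]).drop(columns="_abs_fc")
    sig = tab[tab["significant"]]
    counts = {
        "n_significant": int(len(sig)),
        "n_up": int((sig["direction"] == "up").sum()),
        "n_down": int((sig["direction"] == "down").sum()),
    }
    return tab, counts
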