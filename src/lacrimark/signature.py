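"""Stability-based signature selection.

Candidates are proteins that the lasso selects reproducibly across bootstrap
runs (tier list), intersected with differential-abundance significance;
the final panel is chosen by a forward curve: rank candidates by mean
absolute lasso weight, fit nested-CV lasso models on the top-k candidates for
growing k under the same resampling protocol, and take the smallest panel
attaining the maximal mean test AUROC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ml import BootstrapBench, ModelSpec, ResampleParams, auroc, decision_scores, \
    nested_cv_train, stratified_split
from .preprocess import as_values_frame


@dataclass(frozen=True)
class TierParams:
    min_selection_fraction: float = 0.20
    stability_rule: str = "sd_below_mean"  # or "sd_below_mean_selected_only"
    require_da_significant: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.min_selection_fraction <= 1.0):
            raise ValueError("min_selection_fraction must be in (0, 1]")
        if self.stability_rule not in ("sd_below_mean", "sd_below_mean_selected_only"):
            raise ValueError(f"unknown stability_rule {self.stability_rule!r}")


@dataclass
class SignatureCurve:
    """Forward-addition AUROC curve over ranked candidates."""

    curve: pd.DataFrame  # columns: k, protein_added, auroc
    ranked: list[str]

    @property
    def optimal_k(self) -> int:
        best = self.curve["auroc"].max()
        return int(self.curve.loc[self.curve["auroc"] >= best - 1e-12, "k"].min())

    @property
    def optimal_panel(self) -> list[str]:
        return self.ranked[: self.optimal_k]


def tier_list(
    bench: BootstrapBench, da: pd.DataFrame | None = None, params: TierParams | None = None
) -> pd.DataFrame:
    """Bootstrap-stability candidate table.

    A protein is a candidate iff its lasso selection fraction is at least
    ``min_selection_fraction``, the SD of its bootstrap weights is below the
    absolute mean weight, and (optionally) it is significant in the
    differential abundance results. Weights include zeros from runs that did
    not select the protein under the default rule; the alternative rule takes
    moments over selected runs only.

    Returns the full per-protein table with a ``candidate`` flag, sorted by
    ``|mean_weight|`` descending (the validation-priority ranking).
    """
    params = params or TierParams()
    if bench.selected.shape[1] == 0:
        raise ValueError("bench contains no lasso runs")
    w = bench.weights["lasso_logistic"]
    sel = bench.selected
    frac = sel.mean(axis=1)
    if params.stability_rule == "sd_below_mean":
        mean_w = w.mean(axis=1)
        sd_w = w.std(axis=1, ddof=1)
    else:
        masked = w.where(sel)
        mean_w = masked.mean(axis=1).fillna(0.0)
        sd_w = masked.std(axis=1, ddof=1).fillna(np.inf)
    stable = sd_w < mean_w.abs()
    out = pd.DataFrame(
        {
            "selection_fraction": frac,
            "mean_weight": mean_w,
            "sd_weight": sd_w,
            "stable": stable,
        }
    )
    out["candidate"] = (frac >= params.min_selection_fraction - 1e-12) & stable
    if params.require_da_significant:
        if da is None:
            raise ValueError("require_da_significant=True needs DA results")
        sig = da["significant"].reindex(out.index).fillna(False).astype(bool)
        out["da_fdr"] = da["fdr"].reindex(out.index)
        out["candidate"] &= sig
    return out.sort_values("mean_weight", key=lambda s: s.abs(), ascending=False)


def _panel_mean_auroc(
    X: np.ndarray, y: np.ndarray, lasso: ModelSpec, params: ResampleParams
) -> float:
    """Mean held-out AUROC of nested-CV lasso over repeated stratified splits."""
    ss = np.random.SeedSequence(params.seed)
    seeds = ss.generate_state(params.n_bootstrap)
    aucs = []
    for s in seeds:
        s = int(s % (2**31 - 1))
        tr, te = stratified_split(y, params.train_fraction, s)
        est, _, _ = nested_cv_train(lasso, X[tr], y[tr], params.inner_folds, s)
        aucs.append(auroc(decision_scores(est, X[te]), y[te]))
    return float(np.mean(aucs))


def forward_auroc_curve(
    matrix,
    groups: pd.Series,
    candidates: list[str],
    params: ResampleParams | None = None,
    lasso: ModelSpec | None = None,
    case_label: str = "ALS",
) -> SignatureCurve:
    """Cumulative top-k panel AUROCs for candidates ranked by importance.

    ``candidates`` must already be ranked (typically by ``|mean_weight|``
    descending from :func:`tier_list`). Panels are strictly nested.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    params = params or ResampleParams(n_bootstrap=50)
    lasso = lasso or ModelSpec("lasso_logistic",
                               grid=tuple({"lam": float(l)} for l in
                                          (0.0, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)))
    values_df = as_values_frame(matrix)
    groups = pd.Series(groups).reindex(values_df.columns)
    y = (groups == case_label).to_numpy().astype(int)
    rows = []
    for k in range(1, len(candidates) + 1):
        X = values_df.loc[candidates[:k]].to_numpy(dtype=float).T
        rows.append(
            {"k": k, "protein_added": candidates[k - 1],
             "auroc": _panel_mean_auroc(X, y, lasso, params)}
        )
    return SignatureCurve(curve=pd.DataFrame(rows), ranked=list(candidates))


def select_signature(curve: SignatureCurve) -> dict:
    """Optimal panel: smallest k attaining the maximal curve AUROC."""
    if curve.curve.empty:
        raise ValueError("empty signature curve")
    k = curve.optimal_k
    return {
        "panel": curve.optimal_panel,
        "k": k,
        "auroc": float(curve.curve.loc[curve.curve["k"] == k, "auroc"].iloc[0]),
        "curve": curve.curve,
    }
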