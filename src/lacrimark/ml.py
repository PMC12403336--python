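"""Bootstrapped, nested-CV benchmarking of classifiers on feature tables.

Four model families are benchmarked: L1-penalised ("lasso") logistic
regression, linear- and radial-kernel SVMs, and random forests. Each
bootstrap run draws a stratified 80/20 train/test split, tunes
hyperparameters by inner stratified k-fold cross-validation maximising
AUROC, refits on the full training portion and scores the held-out test
samples. Per-run weights are stored for the linear models; a protein counts
as "selected" in a run when its lasso coefficient is nonzero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import as_values_frame
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

MODEL_KINDS = ("lasso_logistic", "svm_linear", "svm_rbf", "random_forest")

#: default hyperparameter grids; the lasso lambda grid 0..100 step 0.1 is
#: kept literal and may be thinned for speed via ModelSpec(grid=...)
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "lasso_logistic": [{"lam": float(l)} for l in np.round(np.arange(0.0, 100.0001, 0.1), 1)],
    "svm_linear": [{"C": c} for c in (0.01, 0.1, 1.0, 10.0, 100.0)],
    "svm_rbf": [
        {"C": c, "gamma": g} for c in (0.1, 1.0, 10.0) for g in ("scale", 0.01, 0.1, 1.0)
    ],
    "random_forest": [{"max_features": m} for m in (1, 2, 3, 4, 5)],
}


@dataclass(frozen=True)
class ModelSpec:
    kind: str
    grid: tuple = ()  # hyperparameter dicts; empty -> DEFAULT_GRIDS[kind]
    n_trees: int = 500

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def effective_grid(self) -> list[dict]:
        grid = list(self.grid) if self.grid else list(DEFAULT_GRIDS[self.kind])
        if not grid:
            raise ValueError("empty hyperparameter grid")
        return grid


@dataclass(frozen=True)
class ResampleParams:
    train_fraction: float = 0.8
    n_bootstrap: int = 500
    inner_folds: int = 10
    stratified: bool = True
    mode: str = "resplit"  # "resplit" (repeated stratified 80/20) or "resample"
    prob_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.mode not in ("resplit", "resample"):
            raise ValueError("mode must be 'resplit' or 'resample'")


@dataclass
class BootstrapBench:
    """Per-run metrics and per-protein weights from the bootstrap bench."""

    runs: pd.DataFrame  # columns: run, model, auroc, sensitivity, specificity
    weights: dict[str, pd.DataFrame]  # model -> protein x run weight matrix
    selected: pd.DataFrame  # protein x run, lasso nonzero-coefficient flags
    n_failures: int = 0

    def summary(self) -> pd.DataFrame:
        """Mean +- SD of AUROC/sensitivity/specificity per model."""
        g = self.runs.groupby("model")[["auroc", "sensitivity", "specificity"]]
        out = g.agg(["mean", "std"])
        out.columns = ["_".join(c) for c in out.columns]
        return out


def make_estimator(kind: str, hp: dict, seed: int = 0, n_trees: int = 500):
    """Instantiate a scikit-learn estimator for one grid point."""
    if kind == "lasso_logistic":
        lam = hp["lam"]
        c = 1e10 if lam == 0 else 1.0 / lam
        return LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear", max_iter=2000,
                                  random_state=seed)
    if kind == "svm_linear":
        return SVC(kernel="linear", C=hp["C"], random_state=seed)
    if kind == "svm_rbf":
        return SVC(kernel="rbf", C=hp["C"], gamma=hp["gamma"], random_state=seed)
    if kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=n_trees,
            max_features=min(hp["max_features"], 10**9),
            random_state=seed,
            n_jobs=1,
        )
    raise ValueError(f"unknown model kind {kind!r}")


def decision_scores(est, X: np.ndarray) -> np.ndarray:
    """Continuous class-1 scores: decision_function if present, else P(y=1)."""
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=float)
    return np.asarray(est.predict_proba(X)[:, 1], dtype=float)


def auroc(scores, labels) -> float:
    """Area under the ROC curve; ties contribute 1/2 (Mann-Whitney estimate)."""
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain exactly two classes")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def stratified_split(labels, train_fraction: float = 0.8, seed: int = 0):
    """Disjoint, exhaustive train/test split preserving class proportions.

    Returns positional index arrays (train, test).
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)  # keep both sides non-empty
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def nested_cv_train(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
                    inner_folds: int = 10, seed: int = 0):
    """Inner stratified k-fold CV over the grid, refit at the best point.

    Returns ``(fitted_estimator, chosen_hyperparameters, inner_auroc)``. The
    grid point maximising mean inner AUROC wins; ties go to the earliest grid
    point. The fold count is capped by the minority class size so every fold
    contains both classes.
    """
    y = np.asarray(y)
    n_min = int(np.unique(y, return_counts=True)[1].min())
    k = min(inner_folds, n_min)
    if k < 2:
        raise ValueError("minority class too small for cross-validation")
    if k < inner_folds:
        warnings.warn(f"inner folds reduced to {k} to keep both classes in every fold")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    grid = spec.effective_grid
    best_score, best_hp = -np.inf, grid[0]
    for hp in grid:
        scores = []
        for tr, va in folds:
            est = make_estimator(spec.kind, hp, seed=seed, n_trees=spec.n_trees)
            est.fit(X[tr], y[tr])
            scores.append(auroc(decision_scores(est, X[va]), y[va]))
        mean_score = float(np.mean(scores))
        if mean_score > best_score:
            best_score, best_hp = mean_score, hp
    final = make_estimator(spec.kind, best_hp, seed=seed, n_trees=spec.n_trees)
    final.fit(X, y)
    return final, best_hp, best_score


def _model_weights(spec: ModelSpec, est, n_features: int) -> np.ndarray | None:
    if spec.kind in ("lasso_logistic", "svm_linear"):
        return np.asarray(est.coef_, dtype=float).ravel()
    if spec.kind == "random_forest":
        return np.asarray(est.feature_importances_, dtype=float)
    return None


def bootstrap_bench(
    matrix,
    groups: pd.Series,
    models: list[ModelSpec] | None = None,
    params: ResampleParams | None = None,
    case_label: str = "ALS",
) -> BootstrapBench:
    """Repeated split -> nested-CV train -> held-out test, per model.

    ``matrix`` is an AbundanceMatrix or protein x sample DataFrame (features
    in rows); it is transposed internally to samples x features. Deterministic
    for a fixed ``params.seed``. A failed run is skipped and counted.
    """
    params = params or ResampleParams()
    models = models or [ModelSpec(k) for k in MODEL_KINDS]
    values_df = as_values_frame(matrix)
    groups = pd.Series(groups).reindex(values_df.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    X_all = values_df.to_numpy(dtype=float).T
    y_all = (groups == case_label).to_numpy().astype(int)
    proteins = values_df.index

    rows = []
    weights: dict[str, list[np.ndarray]] = {
        m.kind: [] for m in models if m.kind in ("lasso_logistic", "svm_linear", "random_forest")
    }
    selected_runs: list[np.ndarray] = []
    n_failures = 0
    ss = np.random.SeedSequence(params.seed)
    run_seeds = ss.generate_state(params.n_bootstrap)
    for run, run_seed in enumerate(run_seeds):
        run_seed = int(run_seed % (2**31 - 1))
        if params.mode == "resample":
            rng = np.random.default_rng(run_seed)
            boot = rng.choice(len(y_all), size=len(y_all), replace=True)
            oob = np.setdiff1d(np.arange(len(y_all)), boot)
            if len(np.unique(y_all[boot])) < 2 or len(np.unique(y_all[oob])) < 2:
                n_failures += 1
                continue
            tr_idx, te_idx = boot, oob
        else:
            tr_idx, te_idx = stratified_split(y_all, params.train_fraction, run_seed)
        X_tr, y_tr = X_all[tr_idx], y_all[tr_idx]
        X_te, y_te = X_all[te_idx], y_all[te_idx]
        for spec in models:
            try:
                est, hp, _ = nested_cv_train(spec, X_tr, y_tr, params.inner_folds, run_seed)
                test_auc = auroc(decision_scores(est, X_te), y_te)
                pred = np.asarray(est.predict(X_te), dtype=int)
                tp = int(((pred == 1) & (y_te == 1)).sum())
                fn = int(((pred == 0) & (y_te == 1)).sum())
                tn = int(((pred == 0) & (y_te == 0)).sum())
                fp = int(((pred == 1) & (y_te == 0)).sum())
                rows.append(
                    {
                        "run": run,
                        "model": spec.kind,
                        "auroc": test_auc,
                        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                        "specificity": tn / (tn + fp) if tn + fp else np.nan,
                    }
                )
                w = _model_weights(spec, est, X_all.shape[1])
                if w is not None:
                    weights.setdefault(spec.kind, []).append(w)
                if spec.kind == "lasso_logistic":
                    selected_runs.append(w != 0)
            except Exception:
                n_failures += 1

    runs_df = pd.DataFrame(rows, columns=["run", "model", "auroc", "sensitivity", "specificity"])
    weight_frames = {
        kind: pd.DataFrame(np.column_stack(ws), index=proteins) if ws else
        pd.DataFrame(index=proteins)
        for kind, ws in weights.items()
    }
    selected_df = (
        pd.DataFrame(np.column_stack(selected_runs), index=proteins)
        if selected_runs
        else pd.DataFrame(index=proteins)
    )
    return BootstrapBench(runs=runs_df, weights=weight_frames, selected=selected_df,
                          n_failures=n_failures)
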