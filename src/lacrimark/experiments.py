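"""Canned simulation experiments: the study conditions under which the
pipeline is exercised and scored.

Two experiments are defined once here and reused by the analysis drivers and
the test suite:

* **null calibration** — cohorts with no planted effects; the bench's mean
  AUROC should sit at chance for every model family and the permutation FDR
  should call (almost) nothing significant.
* **parameter recovery** — six planted signal proteins (1 log2 unit effect,
  unit residual SD, 50 vs 50 samples); the tier list + forward-AUROC
  pipeline should place at least five of the six in the optimal panel in
  most replicates.

Problem sizes (seeds, bootstrap counts, protein counts, reduced
hyperparameter grids) are fixed package choices that keep a full run in the
single-digit minutes on one CPU; effect sizes, sample sizes and noise levels
are the study conditions themselves and are not tuned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffabund import DAParams, permutation_fdr
from .ml import ModelSpec, ResampleParams, bootstrap_bench
from .preprocess import preprocess
from .signature import TierParams, forward_auroc_curve, select_signature, tier_list
from .synthetic import SyntheticConfig, generate_proteome, protein_ids

#: concentrated lasso lambda grid: one penalty scale, so bootstrap weights
#: are comparable across runs (mixing unpenalized and heavily penalized
#: refits would inflate the weight SD artificially)
RECOVERY_LASSO = ModelSpec(
    "lasso_logistic", grid=tuple({"lam": l} for l in (0.1, 0.3, 0.5, 1.0))
)

#: reduced grids for the four-model null bench
NULL_MODELS = [
    ModelSpec("lasso_logistic", grid=tuple({"lam": l} for l in (0.1, 0.3, 1.0, 3.0))),
    ModelSpec("svm_linear", grid=({"C": 0.1}, {"C": 1.0}, {"C": 10.0})),
    ModelSpec("svm_rbf", grid=({"C": 1.0, "gamma": "scale"}, {"C": 10.0, "gamma": "scale"})),
    ModelSpec("random_forest", grid=({"max_features": 2}, {"max_features": 5}), n_trees=100),
]


@dataclass
class NullCalibrationResult:
    auroc_by_model: pd.Series  # mean test AUROC per model over all runs
    runs: pd.DataFrame
    fdr_positive_fraction: float  # mean fraction of proteins at FDR < 0.1
    sam_type1_rate: float  # |d| vs t critical at alpha=0.05, s0=0


def null_calibration(
    n_seeds: int = 5,
    n_proteins: int = 500,
    n_per_group: int = 50,
    n_bootstrap: int = 15,
    n_permutations: int = 100,
    base_seed: int = 0,
) -> NullCalibrationResult:
    """Zero-signal cohorts through preprocessing, DA and the 4-model bench."""
    from scipy import stats

    from .diffabund import sam_statistic

    all_runs = []
    fdr_fracs = []
    type1_num = type1_den = 0
    for i in range(n_seeds):
        seed = base_seed + i
        cfg = SyntheticConfig(
            n_controls=n_per_group, n_cases=n_per_group, n_proteins=n_proteins, seed=seed
        )
        matrix, meta, _ = generate_proteome(cfg)
        imputed, scaled = preprocess(matrix, meta["group"], seed=seed)
        da = permutation_fdr(
            imputed, meta["group"], DAParams(n_permutations=n_permutations, seed=seed)
        )
        fdr_fracs.append(float(da["significant"].mean()))
        # unadjusted type-I error of the statistic itself at s0=0
        case = meta["group"] == "ALS"
        tcrit = stats.t.ppf(0.975, df=2 * n_per_group - 2)
        vals = imputed.values
        d0 = np.array(
            [
                sam_statistic(row[case.to_numpy()], row[~case.to_numpy()], s0=0.0)
                for row in vals.to_numpy()
            ]
        )
        type1_num += int((np.abs(d0) > tcrit).sum())
        type1_den += d0.size
        bench = bootstrap_bench(
            scaled, meta["group"], NULL_MODELS,
            ResampleParams(n_bootstrap=n_bootstrap, inner_folds=4, seed=seed),
        )
        runs = bench.runs.copy()
        runs["seed"] = seed
        all_runs.append(runs)
    runs = pd.concat(all_runs, ignore_index=True)
    return NullCalibrationResult(
        auroc_by_model=runs.groupby("model")["auroc"].mean(),
        runs=runs,
        fdr_positive_fraction=float(np.mean(fdr_fracs)),
        sam_type1_rate=type1_num / type1_den,
    )


@dataclass
class RecoveryResult:
    per_seed: pd.DataFrame  # seed, n_candidates, optimal_k, n_recovered, auroc
    pass_fraction: float  # fraction of seeds recovering >= 5 of 6 planted


def recovery_experiment(
    n_seeds: int = 12,
    n_proteins: int = 200,
    n_per_group: int = 50,
    effect: float = 1.0,
    n_signal: int = 6,
    bench_bootstrap: int = 25,
    curve_bootstrap: int = 40,
    max_candidates: int = 12,
    base_seed: int = 0,
) -> RecoveryResult:
    """Planted-signal cohorts through the full signature-selection pipeline.

    Signals alternate in sign (mirroring a mostly-down-regulated disease
    profile with some up-regulation) and sit on consistently-detected
    proteins; censoring is disabled so the experiment scores the selection
    machinery rather than the imputation.
    """
    planted = protein_ids(n_proteins)[:n_signal]
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        sig = tuple((p, (-effect if j % 2 else effect)) for j, p in enumerate(planted))
        cfg = SyntheticConfig(
            n_controls=n_per_group, n_cases=n_per_group, n_proteins=n_proteins,
            signal_proteins=sig, mnar_midpoint=-100.0, mcar_rate=0.0, seed=seed,
        )
        matrix, meta, _ = generate_proteome(cfg)
        imputed, scaled = preprocess(matrix, meta["group"], seed=seed)
        da = permutation_fdr(imputed, meta["group"], DAParams(n_permutations=100, seed=seed))
        bench = bootstrap_bench(
            scaled, meta["group"], [RECOVERY_LASSO],
            ResampleParams(n_bootstrap=bench_bootstrap, inner_folds=4, seed=seed),
        )
        tiers = tier_list(bench, da, TierParams())
        candidates = tiers[tiers["candidate"]].index.tolist()[:max_candidates]
        if not candidates:
            rows.append({"seed": seed, "n_candidates": 0, "optimal_k": 0,
                         "n_recovered": 0, "auroc": np.nan})
            continue
        curve = forward_auroc_curve(
            scaled, meta["group"], candidates,
            ResampleParams(n_bootstrap=curve_bootstrap, inner_folds=4, seed=seed),
            lasso=RECOVERY_LASSO,
        )
        panel = select_signature(curve)
        rows.append(
            {
                "seed": seed,
                "n_candidates": len(candidates),
                "optimal_k": panel["k"],
                "n_recovered": len(set(planted) & set(panel["panel"])),
                "auroc": panel["auroc"],
            }
        )
    per_seed = pd.DataFrame(rows)
    return RecoveryResult(
        per_seed=per_seed,
        pass_fraction=float((per_seed["n_recovered"] >= min(5, n_signal - 1)).mean()),
    )
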