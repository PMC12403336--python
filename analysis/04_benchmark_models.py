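#!/usr/bin/env python
"""Benchmark the four classifier families on the scaled feature table.

Repeated stratified 80/20 splits; within each training portion, inner
cross-validation tunes the hyperparameters before refitting and scoring the
held-out 20%. Reports mean +- SD AUROC / sensitivity / specificity per model
and stores per-protein lasso weights and selection flags for the signature
stage. Bootstrap count and grids are reduced relative to the ModelSpec
defaults to keep a laptop run in minutes.
"""

import argparse
import json
from pathlib import Path

from lacrimark.io import read_abundance, read_metadata
from lacrimark.ml import ModelSpec, ResampleParams, bootstrap_bench

MODELS = [
    ModelSpec("lasso_logistic", grid=tuple({"lam": l} for l in (0.1, 0.3, 0.5, 1.0, 3.0))),
    ModelSpec("svm_linear", grid=({"C": 0.1}, {"C": 1.0}, {"C": 10.0})),
    ModelSpec("svm_rbf", grid=({"C": 1.0, "gamma": "scale"}, {"C": 10.0, "gamma": "scale"})),
    ModelSpec("random_forest", grid=({"max_features": 2}, {"max_features": 5}), n_trees=200),
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-boot", type=int, default=25)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    scaled = read_abundance(args.data / "scaled.tsv")
    meta = read_metadata(args.data / "metadata.csv", scaled)
    bench = bootstrap_bench(scaled.values, meta["group"], MODELS,
                            ResampleParams(n_bootstrap=args.n_boot, inner_folds=5,
                                           seed=args.seed))
    args.out.mkdir(parents=True, exist_ok=True)
    bench.runs.to_csv(args.out / "bench_runs.csv", index=False)
    bench.weights["lasso_logistic"].to_csv(args.out / "weights_lasso_logistic.csv")
    bench.selected.astype(int).to_csv(args.out / "lasso_selected.csv")
    summary = bench.summary()
    (args.out / "bench_summary.json").write_text(json.dumps(summary.to_dict(), indent=1))

    print(f"{args.n_boot} bootstrap runs per model; {bench.n_failures} failures")
    for model, row in summary.iterrows():
        print(f"  {model:16s} AUROC {row['auroc_mean']:.2f} (+- {row['auroc_std']:.2f}) "
              f"sens {row['sensitivity_mean']:.2f} spec {row['specificity_mean']:.2f}")


if __name__ == "__main__":
    main()
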