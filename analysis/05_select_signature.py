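#!/usr/bin/env python
"""Select the optimal protein signature.

Tier list from the bootstrap bench (lasso selection fraction >= 20%, weight
SD below |mean weight|, differential-abundance significance), then a
forward-AUROC curve over the candidates ranked by mean absolute weight; the
optimal panel is the smallest prefix attaining the maximal mean test AUROC.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from lacrimark.experiments import RECOVERY_LASSO
from lacrimark.io import read_abundance, read_metadata
from lacrimark.ml import BootstrapBench, ResampleParams
from lacrimark.signature import TierParams, forward_auroc_curve, select_signature, tier_list
from lacrimark.synthetic import GroundTruth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--max-candidates", type=int, default=15)
    args = parser.parse_args()

    weights = pd.read_csv(args.out / "weights_lasso_logistic.csv", index_col=0)
    selected = pd.read_csv(args.out / "lasso_selected.csv", index_col=0).astype(bool)
    runs = pd.read_csv(args.out / "bench_runs.csv")
    bench = BootstrapBench(runs=runs, weights={"lasso_logistic": weights}, selected=selected)
    da = pd.read_csv(args.out / "volcano.csv", index_col=0, comment="#")

    tiers = tier_list(bench, da, TierParams())
    tiers.to_csv(args.out / "candidates.csv")
    candidates = tiers[tiers["candidate"]].index.tolist()[: args.max_candidates]
    print(f"{tiers['candidate'].sum()} candidates pass the tier list; "
          f"using the top {len(candidates)} by |mean weight|")
    if not candidates:
        raise SystemExit("no candidates; rerun the bench with more bootstraps")

    scaled = read_abundance(args.data / "scaled.tsv")
    meta = read_metadata(args.data / "metadata.csv", scaled)
    curve = forward_auroc_curve(
        scaled.values, meta["group"], candidates,
        ResampleParams(n_bootstrap=40, inner_folds=4, seed=args.seed), lasso=RECOVERY_LASSO,
    )
    panel = select_signature(curve)
    curve.curve.to_csv(args.out / "signature_curve.csv", index=False)
    (args.out / "panel.json").write_text(
        json.dumps({"panel": panel["panel"], "k": panel["k"], "auroc": panel["auroc"]},
                   indent=1)
    )

    truth = GroundTruth.from_json(args.data / "truth.json")
    overlap = set(panel["panel"]) & set(truth.signal_proteins)
    print(f"optimal panel (k={panel['k']}, mean AUROC {panel['auroc']:.3f}): "
          f"{', '.join(panel['panel'])}")
    print(f"{len(overlap)} of {panel['k']} panel members carry a planted effect")


if __name__ == "__main__":
    main()
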