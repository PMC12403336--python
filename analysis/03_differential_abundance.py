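#!/usr/bin/env python
"""Differential abundance between cases and controls.

SAM-style statistic (s0 = 0.1) with permutation-based FDR (250 label
permutations); proteins at FDR < 0.1 are called significant. Writes the
volcano table (log2 FC, signed FC, statistic, FDR, direction) and reports
the up/down split, which can be compared with the planted ground truth.
"""

import argparse
import json
from pathlib import Path

from lacrimark.diffabund import DAParams, permutation_fdr, volcano_table
from lacrimark.io import provenance_header, read_abundance, read_metadata
from lacrimark.synthetic import GroundTruth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    imputed = read_abundance(args.data / "imputed.tsv")
    imputed.state = "imputed"
    meta = read_metadata(args.data / "metadata.csv", imputed)
    results = permutation_fdr(imputed, meta["group"],
                              DAParams(s0=0.1, fdr_threshold=0.1,
                                       n_permutations=250, seed=args.seed))
    table, counts = volcano_table(results)
    args.out.mkdir(parents=True, exist_ok=True)
    with (args.out / "volcano.csv").open("w") as fh:
        fh.write(provenance_header("da", args.seed))
        table.to_csv(fh)
    (args.out / "da_counts.json").write_text(json.dumps(counts, indent=1))

    truth = GroundTruth.from_json(args.data / "truth.json")
    planted = set(truth.signal_proteins) & set(results.index)
    hits = results.loc[sorted(planted), "significant"].sum()
    print(f"{counts['n_significant']} significant proteins "
          f"({counts['n_down']} down / {counts['n_up']} up) at FDR < 0.1")
    print(f"planted proteins surviving the filter: {len(planted)}; "
          f"called significant: {hits}")


if __name__ == "__main__":
    main()
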