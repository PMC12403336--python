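#!/usr/bin/env python
"""Simulate a discovery-style tear-fluid cohort.

Generates a 54-control / 49-case cohort with 800 proteins, twelve of which
carry planted group effects (six strong "signature-like" proteins, mostly
less abundant in cases, and six weaker ones), plus abundance-dependent
missingness. Writes the raw matrix, sample sheet and ground truth under
results/data/.
"""

import argparse
from pathlib import Path

from lacrimark.io import write_abundance, write_metadata
from lacrimark.synthetic import SyntheticConfig, generate_proteome, protein_ids

STRONG = [-1.0, -1.0, -0.9, -0.8, -1.1, 0.9]  # signature-like effects (log2)
WEAK = [-0.5, -0.4, 0.4, -0.45, 0.5, -0.35]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ids = protein_ids(800)
    signal = tuple(zip(ids[:12], STRONG + WEAK))
    cfg = SyntheticConfig(n_controls=54, n_cases=49, n_proteins=800,
                          signal_proteins=signal, seed=args.seed)
    matrix, metadata, truth = generate_proteome(cfg)

    write_abundance(matrix, args.out / "abundance.tsv", "simulate", args.seed)
    write_metadata(metadata, args.out / "metadata.csv", "simulate", args.seed)
    truth.to_json(args.out / "truth.json")

    miss = matrix.mask.to_numpy().mean()
    print(f"simulated {matrix.shape[0]} proteins x {matrix.shape[1]} samples "
          f"({miss:.0%} missing cells) -> {args.out}")
    print(f"planted effects on {len(signal)} proteins "
          f"({sum(e < 0 for _, e in signal)} down, {sum(e > 0 for _, e in signal)} up)")


if __name__ == "__main__":
    main()
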