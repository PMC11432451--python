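#!/usr/bin/env python
"""Per-mouse detected-gene repertoires: sharing across mice and over time."""

import os

import pandas as pd

PIPE = os.path.join(os.path.dirname(__file__), "..", "results", "pipeline")


def main() -> None:
    summary = pd.read_csv(os.path.join(PIPE, "repertoire_summary.tsv"), sep="\t")
    pairs = pd.read_csv(os.path.join(PIPE, "repertoire_jaccard.tsv"), sep="\t")
    print("shared human detection repertoires at sacrifice:")
    print(summary.to_string(index=False))
    if len(pairs):
        print("\nmatched early/late overlap per mouse (Jaccard + permutation p):")
        print(pairs.to_string(index=False))
        print(f"\nmedian Jaccard index: {pairs.jaccard.median():.4f}")


if __name__ == "__main__":
    main()
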