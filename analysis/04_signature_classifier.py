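#!/usr/bin/env python
"""Therapy-response classification from the 8-gene signature score."""

import os

import pandas as pd

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
PIPE = os.path.join(OUT, "pipeline")


def main() -> None:
    summary = pd.read_csv(os.path.join(PIPE, "signature_summary.tsv"), sep="\t")
    held = pd.read_csv(os.path.join(PIPE, "signature_heldout.tsv"), sep="\t")
    print("held-out logistic classification of tumor-bearing vs treated samples:")
    print(summary.to_string(index=False))
    print("\nheld-out predictions:")
    print(held.sort_values("p_positive", ascending=False).to_string(index=False))
    print(
        "\nscore separation: tumor-bearing mean "
        f"{held.loc[held.label == 1, 'score'].mean():.1f} CPM vs treated "
        f"{held.loc[held.label == 0, 'score'].mean():.1f} CPM"
    )


if __name__ == "__main__":
    main()
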