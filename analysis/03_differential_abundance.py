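#!/usr/bin/env python
"""Differential abundance between PBS and treated xenografts, plus enrichment.

Summarizes the NB Wald table (PBS vs successfully treated, late draws), the
longitudinal impulse screen in the PBS arm, and the pre-ranked enrichment of
the 8-gene tumor signature.
"""

import os

import pandas as pd

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
PIPE = os.path.join(OUT, "pipeline")


def main() -> None:
    dag = pd.read_csv(os.path.join(PIPE, "differential_abundance.tsv"), sep="\t")
    sig = dag[dag.qvalue < 0.05]
    print("differentially abundant genes (q < 0.05) per species:")
    print(sig.groupby("species").size().to_string())
    top = sig.sort_values("qvalue").head(10)[["gene", "baseMean", "log2FC", "qvalue"]]
    print("\ntop genes (PBS vs treated):")
    print(top.to_string(index=False))

    imp = pd.read_csv(os.path.join(PIPE, "impulse_timecourse.tsv"), sep="\t")
    pulsed = imp[imp.qvalue < 0.05]
    print(f"\nimpulse screen (PBS arm): {len(pulsed)} genes with q < 0.05")
    print(pulsed.sort_values("qvalue").head(8)[["gene", "t1", "t2", "qvalue"]].to_string(index=False))

    gsea = pd.read_csv(os.path.join(PIPE, "gsea.tsv"), sep="\t")
    print("\npre-ranked enrichment of the tumor signature:")
    print(gsea.to_string(index=False))

    sig.to_csv(os.path.join(OUT, "dag_significant.tsv"), sep="\t", index=False)
    print(f"\nwrote {os.path.join(OUT, 'dag_significant.tsv')}")


if __name__ == "__main__":
    main()
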