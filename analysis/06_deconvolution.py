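#!/usr/bin/env python
"""Cell-type composition of the human cfRNA profile over the study course."""

import os

import pandas as pd

PIPE = os.path.join(os.path.dirname(__file__), "..", "results", "pipeline")


TP_ORDER = ["pre_humanization", "pre_PDTX", "pre_treatment", "post_treatment", "sacrifice"]


def main() -> None:
    traj = pd.read_csv(os.path.join(PIPE, "deconv_trajectory.tsv"), sep="\t")
    traj["timepoint"] = pd.Categorical(traj.timepoint, TP_ORDER, ordered=True)
    focus = traj[traj.cell_type.isin(["B cell", "plasma cell"])].sort_values(
        ["group", "cell_type", "timepoint"]
    )
    print("mean deconvolved fractions (B and plasma cells) per group × timepoint:")
    print(focus.to_string(index=False))
    for group in ("nonHIS-PDTX-PBS", "HIS-PDTX-PBS"):
        pbs = focus[
            (focus.group == group) & (focus.cell_type == "plasma cell")
        ].set_index("timepoint")["mean_fraction"]
        if {"pre_treatment", "sacrifice"} <= set(pbs.index):
            print(
                f"\n{group}: plasma-cell fraction rises "
                f"{pbs['pre_treatment']:.3f} -> {pbs['sacrifice']:.3f} "
                "from pre-treatment to sacrifice as the tumor grows"
            )
    treated = focus[
        focus.group.str.startswith("HIS-PDTX") & ~focus.group.str.endswith("PBS")
        & (focus.cell_type == "B cell")
    ].groupby("timepoint", observed=True)["mean_fraction"].mean()
    if {"pre_treatment", "post_treatment"} <= set(treated.index):
        print(
            "immunochemotherapy depletes circulating B cells: "
            f"{treated['pre_treatment']:.3f} -> {treated['post_treatment']:.3f}"
        )


if __name__ == "__main__":
    main()
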