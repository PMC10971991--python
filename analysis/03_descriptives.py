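#!/usr/bin/env python
"""Descriptive statistics for the stage-1 panel: group-wise five-number
summaries (boxplot statistics) and the pairwise Pearson correlation table
with uncorrected p-values."""

import json
from pathlib import Path

from metaboselect import correlation_matrix, load_table, summarize_by_group

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = load_table(RESULTS / "cohort.csv")
    panel = json.loads((RESULTS / "stage1_panel.json").read_text())["panel_explored"]

    summary = summarize_by_group(table, panel)
    summary.to_csv(RESULTS / "panel_group_summary.tsv", sep="\t", index=False, float_format="%.12g")
    print("group medians by metabolite:")
    print(summary.pivot(index="feature", columns="group", values="median").round(3))

    with open(RESULTS / "panel_correlations.tsv", "w") as fh:
        fh.write("metabolite_1\tmetabolite_2\tr\tp\tn\n")
        for a, b, res in correlation_matrix(table, panel):
            flag = " *" if res.p < 0.05 else ""
            fh.write(f"{a}\t{b}\t{res.r:.4f}\t{res.p:.6g}\t{res.n}\n")
            print(f"  r({a}, {b}) = {res.r:+.4f}  p = {res.p:.4g}{flag}")


if __name__ == "__main__":
    main()
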