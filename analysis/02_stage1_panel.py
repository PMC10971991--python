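#!/usr/bin/env python
"""Stage 1: rank every metabolite by 1-feature LOO-LDA, then search panels.

Reads results/cohort.csv, writes the single-metabolite ranking and the
accuracy-vs-panel-size trace (the stage-1 analogue of an accuracy curve),
and records the winning panel for the polynomial stage.
"""

import json
from pathlib import Path

from metaboselect import load_table, single_feature_ranking, stage1_search

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = load_table(RESULTS / "cohort.csv")
    ranking = single_feature_ranking(table)
    with open(RESULTS / "stage1_single_ranking.tsv", "w") as fh:
        fh.write("metabolite\tloo_accuracy\n")
        for name, report in ranking:
            fh.write(f"{name}\t{report.overall_accuracy:.12g}\n")
    best_name, best_rep = ranking[0]
    print(f"best single metabolite: {best_name} (LOO accuracy {best_rep.overall_accuracy:.3f})")

    search = stage1_search(table, max_k=4, strategy="forward")
    (RESULTS / "stage1_trace.tsv").write_text(search.trace_tsv())
    sel = search.selected()
    panel = list(search.selected_feature_names())
    explored = [search.feature_names[i] for i in search.per_size[-1].features]
    print(f"winning panel (k={sel.k}): {panel}  LOO accuracy {sel.accuracy:.3f}")
    print(f"largest panel explored: {explored}")
    (RESULTS / "stage1_panel.json").write_text(
        json.dumps({"panel": panel, "panel_explored": explored, "accuracy": sel.accuracy}, indent=1)
    )


if __name__ == "__main__":
    main()
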