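#!/usr/bin/env python
"""Final evaluation: confusion matrix, per-class metrics, posterior table,
and the age-filtered rerun.

The winning stage-2 variables are re-scored by LOO; the report and each
subject's posterior class probabilities go to results/.  Because the
synthetic groups differ in age, the same pipeline is rerun after
excluding controls younger than 50 to check that classification is not an
age artefact."""

import json
from pathlib import Path

import numpy as np

from metaboselect import TermSpec, age_filter, load_table, loo_evaluate, posterior_table
from metaboselect.pipeline import _round12, _write_json
from metaboselect.terms import build_design

RESULTS = Path(__file__).resolve().parent.parent / "results"


def winning_terms():
    spec = json.loads((RESULTS / "stage2_variables.json").read_text())
    panel = tuple(spec["panel"])
    return [TermSpec(metabolites=panel, exponents=tuple(e)) for e in spec["exponents"]]


def evaluate(table, terms, tag):
    design = build_design(table, terms)
    report, records = loo_evaluate(design.to_numpy(), y=table.groups, class_order=table.class_names)
    for rec, sid in zip(records, table.subject_ids):
        rec.subject_id = str(sid)
    _write_json(RESULTS / f"report_{tag}.json", report.to_dict())
    (RESULTS / f"report_{tag}.tsv").write_text(report.to_tsv())
    truth = dict(zip(map(str, table.subject_ids), map(str, table.groups)))
    post_df, summary = posterior_table(records, truth, table.class_names)
    post_df.to_csv(RESULTS / f"posteriors_{tag}.tsv", sep="\t", index=False, float_format="%.12g")
    print(f"[{tag}] n={report.n_total}  LOO accuracy {report.overall_accuracy:.3f}  "
          f"true-class posterior > 0.5 for {summary['true_posterior_gt_half']}/{summary['n']} subjects")
    print(report.to_tsv())
    return report


def main() -> None:
    table = load_table(RESULTS / "cohort.csv")
    terms = winning_terms()
    evaluate(table, terms, "full")

    filtered = age_filter(table, min_age=50.0, restrict_class="control")
    print(f"age filter (<50 y controls removed): {table.class_sizes()} -> {filtered.class_sizes()}")
    evaluate(filtered, terms, "age_filtered")


if __name__ == "__main__":
    main()
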