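#!/usr/bin/env python
"""LD1/LD2 projection and the decision-region map.

Fits the final model on the winning stage-2 variables, prints the two
discriminant functions as explicit linear combinations of the variables,
and writes subject coordinates plus the rasterized decision regions
(three groups -> exactly two discriminant axes; the LD plane carries all
the model's discriminative information)."""

import json
from pathlib import Path

import numpy as np

from metaboselect import fit_lda, load_table, region_grid
from metaboselect.terms import build_design
from metaboselect.lda import LDAModel

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = load_table(RESULTS / "cohort.csv")
    spec = json.loads((RESULTS / "stage2_variables.json").read_text())
    from metaboselect import TermSpec

    terms = [TermSpec(metabolites=tuple(spec["panel"]), exponents=tuple(e)) for e in spec["exponents"]]
    design = build_design(table, terms)
    model = fit_lda(design.to_numpy(), y=table.groups, class_order=table.class_names,
                    feature_names=tuple(design.columns))
    model.save(RESULTS / "final_model.json")

    for axis in range(model.n_axes):
        loadings = " + ".join(
            f"{model.axes[j, axis]:+.4g} x {name}" for j, name in enumerate(design.columns)
        )
        print(f"LD{axis + 1} = {loadings}")

    res = region_grid(model, resolution=400, data=design.to_numpy(), groups=table.groups)
    (RESULTS / "map.tsv").write_text(res.to_tsv())
    with open(RESULTS / "coordinates.tsv", "w") as fh:
        fh.write("subject_id\tgroup\tLD1\tLD2\n")
        for sid, g, (a, b) in zip(table.subject_ids, table.groups, res.coordinates):
            fh.write(f"{sid}\t{g}\t{a:.12g}\t{b:.12g}\n")
    counts = {model.class_names[k]: int(np.sum(res.grid == k)) for k in range(len(model.class_names))}
    print(f"region cell counts at 400x400: {counts}")
    print(f"centroids (LD1, LD2): "
          + ", ".join(f"{c}=({x:.3g},{y:.3g})" for c, (x, y) in zip(model.class_names, res.centroids)))


if __name__ == "__main__":
    main()
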