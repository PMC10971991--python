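#!/usr/bin/env python
"""Why the polynomial stage exists: product-coded class signal.

Two demonstrations on engineered cohorts where class membership lives in
the *product structure* of a metabolite pair rather than in either
marginal:

1. Strict product-only two-class cohorts (both marginals identically
   distributed): degree-1 search stays near chance while the full
   monomial universe reaches 100% LOO accuracy through an interaction
   term, across 50 seeds.
2. A three-class cohort mixing a clean linear marker with a product-coded
   class: the linear stage plateaus below 100% and the two-stage pipeline
   completes it.
"""

from pathlib import Path

import numpy as np

from metaboselect import SyntheticConfig, expand_terms, generate_cohort, stage1_search, stage2_search

RESULTS = Path(__file__).resolve().parent.parent / "results"


def strict_product_only(n_seeds=50):
    wins, lin, full = 0, [], []
    for seed in range(n_seeds):
        table = generate_cohort(SyntheticConfig(
            n_per_group=(20, 20), class_names=("ctrl", "case"), n_metabolites=2,
            nonlinear_spec=((0, 1), (1.0, 9.0)), seed=seed, age_spec=None))
        universe = expand_terms(["M001", "M002"], max_degree=3)
        s_full = stage2_search(table, universe, max_vars=4, strategy="exhaustive", budget=5000)
        deg1 = [t for t in universe if t.degree == 1]
        s_lin = stage2_search(table, deg1, max_vars=2, strategy="exhaustive", budget=100)
        sel = s_full.selected()
        wins += sel.accuracy == 1.0 and s_lin.selected().accuracy < 1.0
        full.append(sel.accuracy)
        lin.append(s_lin.selected().accuracy)
    print(f"strict product-only cohorts ({n_seeds} seeds):")
    print(f"  degree-1-only mean LOO accuracy: {np.mean(lin):.3f} (chance ~ 0.5)")
    print(f"  full term universe mean LOO accuracy: {np.mean(full):.3f}")
    print(f"  stage 2 at 100% while degree-1 below: {wins}/{n_seeds} seeds")


def two_stage_completion(n_seeds=15):
    completed = 0
    accs = []
    for seed in range(n_seeds):
        table = generate_cohort(SyntheticConfig(
            n_per_group=(16, 10, 10), class_names=("a", "b", "c"), n_metabolites=8,
            noise_sigma=0.2,
            marker_spec=((2, (1.0, 8.0, 1.0)), (0, (1.0, 1.0, 1.5)), (1, (1.0, 1.0, 1.5))),
            nonlinear_spec=((0, 1), (1.0, 1.0, 2.5)), nonlinear_sigma=0.05,
            seed=seed, age_spec=None))
        s1 = stage1_search(table, max_k=4, strategy="forward")
        panel = [s1.feature_names[i] for i in s1.per_size[-1].features]
        s2 = stage2_search(table, expand_terms(panel, 3), max_vars=6, strategy="beam", beam_width=20)
        accs.append((s1.selected().accuracy, s2.selected().accuracy))
        completed += s2.selected().accuracy == 1.0 and s1.selected().accuracy < 1.0
    a1 = np.mean([a for a, _ in accs])
    a2 = np.mean([b for _, b in accs])
    print(f"linear + product-coded three-class cohorts ({n_seeds} seeds):")
    print(f"  stage 1 mean LOO accuracy: {a1:.3f}; two-stage mean: {a2:.3f}")
    print(f"  stage 1 < 100% and two-stage = 100%: {completed}/{n_seeds} seeds")


def main() -> None:
    strict_product_only()
    two_stage_completion()


if __name__ == "__main__":
    main()
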