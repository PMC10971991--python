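"""Monomial term expansion and the stage-2 variable search.

After stage 1 fixes a small metabolite panel, the classifier is enriched
with every monomial of the panel concentrations up to total degree 3 —
linear, quadratic and cubic powers plus double and triple interactions.
For m metabolites and maximum degree d there are C(m + d, d) − 1 such
terms (e.g. 34 for m = 4, d = 3).  Stage 2 then reruns the best-subset
search over these term columns, looking for the smallest variable set
with maximal LOO accuracy.

Terms are evaluated on raw concentrations (no centering or scaling), so a
term's column is literally the product of µM values raised to its
exponents; collinearity among terms is handled by the LDA ridge fallback.
Labels use the field's notation: powers with ``^``, products with ``*``,
e.g. ``C3^2*Ac-Orn``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import SampleTable
from .evaluation import ClassificationReport
from .lda import loo_evaluate
from .search import SearchResult, subset_search

__all__ = ["TermSpec", "expand_terms", "build_design", "stage2_search"]


@dataclass(frozen=True)
class TermSpec:
    """One monomial over a metabolite panel: exponent per metabolite."""

    metabolites: tuple[str, ...]
    exponents: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.metabolites) != len(self.exponents):
            raise ValueError("one exponent per metabolite required")
        if any(e < 0 or int(e) != e for e in self.exponents):
            raise ValueError("exponents must be non-negative integers")
        if not 1 <= self.degree <= 3:
            raise ValueError("total degree must lie in [1, 3]")

    @property
    def degree(self) -> int:
        return int(sum(self.exponents))

    @property
    def label(self) -> str:
        parts = []
        for name, e in zip(self.metabolites, self.exponents):
            if e == 1:
                parts.append(name)
            elif e > 1:
                parts.append(f"{name}^{e}")
        return "*".join(parts)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Column of term values for an (n, m) panel concentration matrix."""
        X = np.asarray(X, dtype=float)
        out = np.ones(X.shape[0])
        for j, e in enumerate(self.exponents):
            if e:
                out = out * X[:, j] ** e
        return out


def expand_terms(metabolites: Sequence[str], max_degree: int = 3) -> list[TermSpec]:
    """All monomials of total degree 1..max_degree over the panel.

    Deterministic order: degree ascending, then lexicographic in the
    metabolite-index multiset.  The count is C(m + d, d) − 1.
    """
    names = tuple(metabolites)
    if len(set(names)) != len(names):
        raise ValueError("metabolite names must be unique")
    if not 1 <= max_degree <= 3:
        raise ValueError("max_degree must lie in [1, 3]")
    m = len(names)
    terms: list[TermSpec] = []
    for d in range(1, max_degree + 1):
        for combo in itertools.combinations_with_replacement(range(m), d):
            exps = [0] * m
            for i in combo:
                exps[i] += 1
            terms.append(TermSpec(metabolites=names, exponents=tuple(exps)))
    return terms


def build_design(table: SampleTable, terms: Sequence[TermSpec]) -> pd.DataFrame:
    """One column per term, evaluated on the table's raw concentrations."""
    if not terms:
        raise ValueError("terms must be non-empty")
    panel = terms[0].metabolites
    for t in terms:
        if t.metabolites != panel:
            raise ValueError("all terms must share the same metabolite panel")
    X = table.matrix(list(panel))  # raises KeyError naming unknown metabolites
    data = {t.label: t.evaluate(X) for t in terms}
    return pd.DataFrame(data, index=list(table.subject_ids))


def stage2_search(
    table: SampleTable,
    terms: Sequence[TermSpec],
    max_vars: int = 8,
    strategy: str = "forward",
    budget: int = 100_000,
    patience: int = 2,
    beam_width: int = 20,
    priors_mode: str = "proportional",
) -> SearchResult:
    """Stage-2 search over monomial columns; same contract as stage 1."""
    terms = list(terms)
    if not terms:
        raise ValueError("terms must be non-empty")
    if not 1 <= max_vars <= len(terms):
        raise ValueError("max_vars must lie in [1, number of terms]")
    design = build_design(table, terms)
    D = design.to_numpy()
    y = table.groups
    order = table.class_names

    def evaluate(subset: tuple[int, ...]) -> ClassificationReport:
        report, _ = loo_evaluate(D[:, list(subset)], priors_mode=priors_mode, y=y, class_order=order)
        return report

    return subset_search(
        evaluate,
        n_items=len(terms),
        max_k=max_vars,
        strategy=strategy,
        budget=budget,
        patience=patience,
        beam_width=beam_width,
        feature_names=tuple(design.columns),
    )
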