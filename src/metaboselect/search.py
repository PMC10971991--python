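"""Best-subset feature search under leave-one-out LDA accuracy (stage 1).

For each panel size k the search looks for the feature subset maximizing
overall LOO accuracy, and stops once adding further features no longer
improves the cumulative best ("plateau" rule).  Three deterministic
strategies are provided:

- ``exhaustive``: every C(M, k) subset, lexicographic order, guarded by an
  evaluation budget (the honest but exponential option);
- ``forward``: greedy forward selection (default for wide panels);
- ``beam``: forward selection keeping the best ``beam_width`` partial
  subsets per size.

Ties on accuracy break toward the smaller panel, then the
lexicographically smallest index set, so results are reproducible
regardless of execution order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .cohort import SampleTable
from .evaluation import ClassificationReport
from .lda import loo_evaluate

__all__ = [
    "BudgetExceededError",
    "SizeResult",
    "SearchResult",
    "stage1_search",
    "single_feature_ranking",
    "subset_search",
]


class BudgetExceededError(RuntimeError):
    """Exhaustive enumeration would exceed the evaluation budget."""


@dataclass(frozen=True)
class SizeResult:
    k: int
    features: tuple[int, ...]
    report: ClassificationReport

    @property
    def accuracy(self) -> float:
        return self.report.overall_accuracy


@dataclass
class SearchResult:
    """Best subset per size plus the plateau decision."""

    per_size: list[SizeResult]
    strategy: str
    evaluations: int
    feature_names: Optional[tuple[str, ...]] = None

    def cumulative_best(self) -> list[SizeResult]:
        """Best result over all sizes <= k, for each visited k (ties -> smaller k)."""
        out: list[SizeResult] = []
        best: Optional[SizeResult] = None
        for sr in self.per_size:
            if best is None or sr.accuracy > best.accuracy:
                best = sr
            out.append(best)
        return out

    @property
    def selected_size(self) -> int:
        """Smallest k whose cumulative best accuracy equals the overall maximum."""
        cum = self.cumulative_best()
        top = max(sr.accuracy for sr in cum)
        for sr, c in zip(self.per_size, cum):
            if c.accuracy == top:
                return c.k
        raise AssertionError("unreachable")

    def selected(self) -> SizeResult:
        cum = self.cumulative_best()
        top = max(sr.accuracy for sr in cum)
        for c in cum:
            if c.accuracy == top:
                return c
        raise AssertionError("unreachable")

    def selected_feature_names(self) -> Optional[tuple[str, ...]]:
        if self.feature_names is None:
            return None
        return tuple(self.feature_names[i] for i in self.selected().features)

    def trace_tsv(self) -> str:
        """Accuracy-vs-size trace (one line per panel size)."""
        names = self.feature_names
        lines = ["k\tfeatures\taccuracy\tcumulative_best\tevaluations"]
        for sr, cum in zip(self.per_size, self.cumulative_best()):
            feats = ",".join(str(i) if names is None else names[i] for i in sr.features)
            lines.append(f"{sr.k}\t{feats}\t{sr.accuracy:.12g}\t{cum.accuracy:.12g}\t{self.evaluations}")
        return "\n".join(lines) + "\n"


def subset_search(
    evaluate: Callable[[tuple[int, ...]], ClassificationReport],
    n_items: int,
    max_k: int,
    strategy: str = "forward",
    budget: int = 100_000,
    patience: int = 2,
    beam_width: int = 20,
    feature_names: Optional[Sequence[str]] = None,
) -> SearchResult:
    """Generic best-subset driver over an arbitrary LOO evaluator.

    ``evaluate`` maps a sorted index tuple to a ClassificationReport; it is
    called at most ``budget`` times.  Search stops early after ``patience``
    consecutive sizes without cumulative-best improvement.
    """
    if not 1 <= max_k <= n_items:
        raise ValueError("max_k must lie in [1, number of items]")
    if strategy not in ("exhaustive", "forward", "beam"):
        raise ValueError(f"unknown strategy {strategy!r}")

    evaluations = 0
    cache: dict[tuple[int, ...], float] = {}

    def run(subset: tuple[int, ...]) -> ClassificationReport:
        nonlocal evaluations
        evaluations += 1
        return evaluate(subset)

    per_size: list[SizeResult] = []
    best_cum = -1.0
    stall = 0
    # beam frontier: list of (accuracy, subset) partial solutions
    frontier: list[tuple[int, ...]] = [()]

    for k in range(1, max_k + 1):
        best_k: Optional[SizeResult] = None
        if strategy == "exhaustive":
            n_this = math.comb(n_items, k)
            if evaluations + n_this > budget:
                raise BudgetExceededError(
                    f"size {k} needs {n_this} evaluations (done {evaluations}, budget {budget}); "
                    "use strategy='forward' or 'beam'"
                )
            for subset in itertools.combinations(range(n_items), k):
                rep = run(subset)
                if best_k is None or rep.overall_accuracy > best_k.accuracy:
                    best_k = SizeResult(k, subset, rep)
        else:
            candidates: list[tuple[int, ...]] = []
            seen: set[tuple[int, ...]] = set()
            for base in frontier:
                for j in range(n_items):
                    if j in base:
                        continue
                    cand = tuple(sorted(base + (j,)))
                    if cand not in seen:
                        seen.add(cand)
                        candidates.append(cand)
            candidates.sort()
            if evaluations + len(candidates) > budget:
                raise BudgetExceededError(
                    f"size {k} needs {len(candidates)} evaluations (done {evaluations}, budget {budget})"
                )
            scored: list[tuple[float, tuple[int, ...], ClassificationReport]] = []
            for cand in candidates:
                rep = run(cand)
                scored.append((rep.overall_accuracy, cand, rep))
                if best_k is None or rep.overall_accuracy > best_k.accuracy:
                    best_k = SizeResult(k, cand, rep)
            # next frontier: greedy keeps only the winner, beam keeps beam_width
            width = 1 if strategy == "forward" else beam_width
            scored.sort(key=lambda t: (-t[0], t[1]))
            frontier = [cand for _, cand, _ in scored[:width]]
        assert best_k is not None
        per_size.append(best_k)
        if best_k.accuracy > best_cum:
            best_cum = best_k.accuracy
            stall = 0
        else:
            stall += 1
        if stall >= patience:
            break

    return SearchResult(
        per_size=per_size,
        strategy=strategy,
        evaluations=evaluations,
        feature_names=None if feature_names is None else tuple(feature_names),
    )


def stage1_search(
    table: SampleTable,
    max_k: int = 8,
    strategy: str = "forward",
    budget: int = 100_000,
    patience: int = 2,
    beam_width: int = 20,
    priors_mode: str = "proportional",
) -> SearchResult:
    """Stage-1 metabolite panel search: LOO-LDA accuracy over raw columns."""
    X = table.concentrations
    y = table.groups
    order = table.class_names

    def evaluate(subset: tuple[int, ...]) -> ClassificationReport:
        report, _ = loo_evaluate(X[:, list(subset)], priors_mode=priors_mode, y=y, class_order=order)
        return report

    return subset_search(
        evaluate,
        n_items=table.n_metabolites,
        max_k=max_k,
        strategy=strategy,
        budget=budget,
        patience=patience,
        beam_width=beam_width,
        feature_names=tuple(table.metabolite_names),
    )


def single_feature_ranking(
    table: SampleTable,
    priors_mode: str = "proportional",
) -> list[tuple[str, ClassificationReport]]:
    """Every metabolite scored by 1-feature LOO-LDA; ordered accuracy desc, name asc."""
    X = table.concentrations
    y = table.groups
    order = table.class_names
    scored = []
    for j, name in enumerate(table.metabolite_names):
        report, _ = loo_evaluate(X[:, [j]], priors_mode=priors_mode, y=y, class_order=order)
        scored.append((str(name), report))
    scored.sort(key=lambda t: (-t[1].overall_accuracy, t[0]))
    return scored
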