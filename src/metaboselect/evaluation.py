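"""Classification reports, correlations, group summaries, and the age ANOVA.

Multi-class sensitivity/specificity/PPV/NPV are computed one-vs-rest per
class and macro-averaged for single-number reporting.  Undefined ratios
(0/0, e.g. PPV of a class never predicted) surface as NaN with an explicit
flag and are excluded from macro averages — silently reporting 0 would
corrupt them.

Confusion matrices are oriented rows = real class, columns = predicted
class; every serialized output states this orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

if TYPE_CHECKING:  # pragma: no cover - import cycle with lda
    from .cohort import SampleTable
    from .lda import PosteriorRecord

__all__ = [
    "ClassificationReport",
    "CorrelationResult",
    "AnovaResult",
    "confusion_matrix",
    "posterior_table",
    "pearson",
    "correlation_matrix",
    "anova_oneway",
    "summarize_by_group",
    "age_filter",
]

_METRICS = ("sensitivity", "specificity", "ppv", "npv")


@dataclass
class ClassificationReport:
    """Confusion matrix plus one-vs-rest metrics (rows = real, cols = predicted)."""

    class_names: tuple[str, ...]
    confusion: np.ndarray                    # (K, K) int
    overall_accuracy: float
    per_class: dict[str, np.ndarray]         # metric -> (K,) with NaN where 0/0
    undefined: dict[str, np.ndarray]         # metric -> (K,) bool flags
    macro: dict[str, float]                  # mean over defined classes
    priors_mode: Optional[str] = None

    @property
    def n_total(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "orientation": "rows=real, columns=predicted",
            "class_names": list(self.class_names),
            "confusion": self.confusion.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "per_class": {m: [None if np.isnan(v) else float(v) for v in vals] for m, vals in self.per_class.items()},
            "undefined": {m: vals.tolist() for m, vals in self.undefined.items()},
            "macro": {m: (None if np.isnan(v) else float(v)) for m, v in self.macro.items()},
            "priors_mode": self.priors_mode,
        }

    def to_tsv(self) -> str:
        lines = ["# confusion matrix: rows=real, columns=predicted"]
        lines.append("real\\pred\t" + "\t".join(self.class_names))
        for name, row in zip(self.class_names, self.confusion):
            lines.append(name + "\t" + "\t".join(str(int(v)) for v in row))
        lines.append(f"overall_accuracy\t{self.overall_accuracy:.12g}")
        for m in _METRICS:
            vals = "\t".join("NA" if np.isnan(v) else f"{v:.12g}" for v in self.per_class[m])
            lines.append(f"{m}\t{vals}")
        return "\n".join(lines) + "\n"


def confusion_matrix(
    real: Sequence[str],
    predicted: Sequence[str],
    class_order: Sequence[str],
    priors_mode: Optional[str] = None,
) -> ClassificationReport:
    """Build a report from paired real/predicted label sequences."""
    real = np.asarray(real, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if real.shape != predicted.shape:
        raise ValueError("real and predicted label sequences differ in length")
    order = tuple(class_order)
    lookup = {c: i for i, c in enumerate(order)}
    unknown = {u for u in (set(real) | set(predicted)) if u not in lookup}
    if unknown:
        raise ValueError(f"label(s) outside class_order: {sorted(unknown)}")
    K = len(order)
    conf = np.zeros((K, K), dtype=int)
    for r, p in zip(real, predicted):
        conf[lookup[r], lookup[p]] += 1
    return report_from_confusion(conf, order, priors_mode=priors_mode)


def report_from_confusion(
    confusion: np.ndarray,
    class_names: Sequence[str],
    priors_mode: Optional[str] = None,
) -> ClassificationReport:
    """Metrics from an already-counted matrix (rows = real, cols = predicted)."""
    conf = np.asarray(confusion, dtype=int)
    K = conf.shape[0]
    if conf.shape != (K, K) or K != len(tuple(class_names)):
        raise ValueError("confusion must be K x K matching class_names")
    if np.any(conf < 0):
        raise ValueError("confusion counts must be non-negative")
    total = conf.sum()
    tp = np.diag(conf).astype(float)
    fn = conf.sum(axis=1) - tp
    fp = conf.sum(axis=0) - tp
    tn = total - tp - fn - fp

    def ratio(num, den):
        num, den = np.asarray(num, float), np.asarray(den, float)
        out = np.full(K, np.nan)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        return out, ~ok

    per_class, undefined = {}, {}
    for m, (num, den) in {
        "sensitivity": (tp, tp + fn),
        "specificity": (tn, tn + fp),
        "ppv": (tp, tp + fp),
        "npv": (tn, tn + fn),
    }.items():
        per_class[m], undefined[m] = ratio(num, den)
    macro = {m: float(np.nanmean(v)) if np.any(~np.isnan(v)) else float("nan") for m, v in per_class.items()}
    return ClassificationReport(
        class_names=tuple(class_names),
        confusion=conf,
        overall_accuracy=float(tp.sum() / total) if total else float("nan"),
        per_class=per_class,
        undefined=undefined,
        macro=macro,
        priors_mode=priors_mode,
    )


def posterior_table(
    records: Sequence["PosteriorRecord"],
    truth: dict[str, str],
    class_names: Sequence[str],
) -> tuple[pd.DataFrame, dict]:
    """Per-subject posterior listing plus a 0.5-threshold summary.

    The summary counts subjects whose posterior for their *true* class
    strictly exceeds 0.5 (a posterior of exactly 0.5 does not count).
    """
    order = tuple(class_names)
    rows = []
    exceed = 0
    for rec in records:
        true = truth[rec.subject_id]
        row = {"subject_id": rec.subject_id, "true": true, "predicted": rec.predicted}
        for c, p in zip(order, rec.posteriors):
            row[f"p_{c}"] = float(p)
        p_true = float(rec.posteriors[order.index(true)])
        row["p_true"] = p_true
        if p_true > 0.5:
            exceed += 1
        rows.append(row)
    df = pd.DataFrame(rows)
    summary = {
        "n": len(rows),
        "true_posterior_gt_half": exceed,
        "true_posterior_le_half": len(rows) - exceed,
    }
    return df, summary


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with the two-sided t-transform p-value.

    t = r·sqrt((n−2)/(1−r²)) against Student-t with n−2 df; no
    multiple-testing correction (pairwise tables report uncorrected p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(np.sum(dx * dx))
    sy = np.sqrt(np.sum(dy * dy))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in input")
    r = float(np.sum(dx * dy) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * scipy.stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, p=p, n=n)


def correlation_matrix(
    table_or_frame,
    features: Optional[Sequence[str]] = None,
) -> list[tuple[str, str, CorrelationResult]]:
    """All C(m,2) pairwise correlations (upper triangle, diagonal omitted)."""
    if isinstance(table_or_frame, pd.DataFrame):
        df = table_or_frame if features is None else table_or_frame[list(features)]
    else:
        feats = list(features) if features is not None else list(table_or_frame.metabolite_names)
        df = pd.DataFrame(table_or_frame.matrix(feats), columns=feats)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 features")
    out = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            out.append((cols[i], cols[j], pearson(df[cols[i]].to_numpy(), df[cols[j]].to_numpy())))
    return out


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def anova_oneway(values: Sequence[float], groups: Sequence[str]) -> AnovaResult:
    """Classical one-way ANOVA: F = MS_between / MS_within."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    order = tuple(dict.fromkeys(groups))
    K = len(order)
    n = len(values)
    if K < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.array([np.sum(groups == g) for g in order])
    if np.any(sizes < 2):
        raise ValueError("every group needs at least 2 values")
    grand = values.mean()
    ss_between = sum(m * (values[groups == g].mean() - grand) ** 2 for g, m in zip(order, sizes))
    ss_within = sum(np.sum((values[groups == g] - values[groups == g].mean()) ** 2) for g in order)
    df_b, df_w = K - 1, n - K
    ms_within = ss_within / df_w
    if ms_within == 0:
        F = 0.0 if ss_between == 0 else float("inf")
    else:
        F = float((ss_between / df_b) / ms_within)
    p = float(scipy.stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    return AnovaResult(F=F, df_between=df_b, df_within=df_w, p=p)


def summarize_by_group(table: "SampleTable", features: Sequence[str]) -> pd.DataFrame:
    """Five-number summary plus mean/SD per (class, feature).

    Quartiles use linear interpolation (the type-7 convention) and SD is
    the n−1 sample estimate; these are the boxplot-friendly defaults.
    """
    feats = list(features)
    X = table.matrix(feats)
    rows = []
    for c in table.class_names:
        mask = table.groups == c
        for j, f in enumerate(feats):
            v = X[mask, j]
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows.append(
                {
                    "group": c,
                    "feature": f,
                    "min": v.min(),
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                    "max": v.max(),
                    "mean": v.mean(),
                    "sd": v.std(ddof=1),
                    "n": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)


def age_filter(
    table: "SampleTable",
    min_age: Optional[float] = None,
    exclude_ids: Optional[Sequence[str]] = None,
    restrict_class: Optional[str] = None,
) -> "SampleTable":
    """Remove young (or listed) subjects, optionally from one class only.

    Used to re-run the analysis on an age-matched cohort: e.g. dropping
    controls younger than a cutoff while leaving patient groups untouched.
    Raises if a class would fall below 2 subjects.
    """
    n = table.n_subjects
    drop = np.zeros(n, dtype=bool)
    if min_age is not None:
        if table.age is None:
            raise ValueError("table has no age column")
        drop |= table.age < min_age
    if exclude_ids is not None:
        drop |= np.isin(table.subject_ids.astype(str), list(map(str, exclude_ids)))
    if restrict_class is not None:
        drop &= table.groups == restrict_class
    keep = ~drop
    remaining = pd.Series(table.groups[keep]).value_counts()
    for c in dict.fromkeys(table.groups):
        if remaining.get(c, 0) < 2:
            raise ValueError(f"age filter would leave class '{c}' with < 2 subjects")
    return table.subset_rows(keep)
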