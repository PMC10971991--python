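"""Multi-class linear discriminant analysis with pooled covariance.

The classifier is the classical Gaussian LDA: every class k has its own
mean vector but all classes share the pooled within-class covariance
S = Σ_k (n_k − 1) S_k / (n − K).  A new observation x is scored by the
squared Mahalanobis distance d_k² = (x − μ_k)ᵀ S⁻¹ (x − μ_k) and the
Bayes posterior

    P(k | x) ∝ π_k · exp(−d_k² / 2),

so with equal priors the rule is nearest-centroid in the Mahalanobis
metric.  Discriminant axes (LD1, LD2, …) are eigenvectors of the
within⁻¹·between scatter problem; at most K − 1 axes exist.

Features are used on their raw concentration scale throughout — no
standardization — so loadings apply directly to µM values (and to
monomials of them in the second, polynomial stage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import scipy.linalg

from .cohort import SampleTable
from .evaluation import ClassificationReport, confusion_matrix

__all__ = [
    "FitError",
    "DegenerateFoldError",
    "LDAModel",
    "PosteriorRecord",
    "fit_lda",
    "classify",
    "classify_batch",
    "loo_evaluate",
]

# ridge escalation for (near-)singular pooled covariance, relative to tr(S)/p
_RIDGE_LADDER = (0.0, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2)
_MAX_CONDITION = 1e12


class FitError(ValueError):
    """The training set cannot support an LDA fit."""


class DegenerateFoldError(FitError):
    """A leave-one-out fold would leave a class with fewer than 2 subjects."""


@dataclass
class LDAModel:
    """Fitted discriminant model (means, pooled covariance, priors, axes)."""

    class_names: tuple[str, ...]
    class_means: np.ndarray      # (K, p)
    pooled_cov: np.ndarray       # (p, p), after any ridge
    priors: np.ndarray           # (K,)
    ridge_used: float
    priors_mode: str
    feature_names: Optional[tuple[str, ...]] = None
    class_counts: Optional[np.ndarray] = None
    _chol: Optional[tuple] = field(default=None, repr=False, compare=False)
    _inv: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    _axes: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]

    @property
    def axes(self) -> np.ndarray:
        """Discriminant loadings (p, n_axes), computed on first access.

        Columns are eigenvectors of the within⁻¹·between scatter problem,
        ordered by decreasing eigenvalue and normalized to unit
        within-class variance; the largest-magnitude loading of each axis
        is made positive.
        """
        if self._axes is None:
            counts = self.class_counts
            if counts is None:
                counts = np.ones(len(self.class_names))
            n = counts.sum()
            grand = (counts @ self.class_means) / n
            centered = self.class_means - grand
            between = (centered.T * counts) @ centered
            n_axes = min(len(self.class_names) - 1, self.n_features)
            evals, evecs = scipy.linalg.eigh(between, self.pooled_cov)
            idx = np.argsort(evals)[::-1][:n_axes]
            axes = evecs[:, idx]
            for a in range(axes.shape[1]):  # sign: largest |loading| positive
                j = int(np.argmax(np.abs(axes[:, a])))
                if axes[j, a] < 0:
                    axes[:, a] = -axes[:, a]
            self._axes = axes
        return self._axes

    @property
    def n_axes(self) -> int:
        return min(len(self.class_names) - 1, self.n_features)

    def _factor(self):
        if self._chol is None:
            self._chol = scipy.linalg.cho_factor(self.pooled_cov, lower=True, check_finite=False)
        return self._chol

    def _precision(self) -> np.ndarray:
        if self._inv is None:
            self._inv = scipy.linalg.cho_solve(self._factor(), np.eye(self.n_features), check_finite=False)
        return self._inv

    def mahalanobis_sq(self, X: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance of each row of X to each class mean."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        inv = self._precision()
        out = np.empty((X.shape[0], len(self.class_names)))
        for k, mu in enumerate(self.class_means):
            diff = X - mu
            out[:, k] = np.einsum("ij,jk,ik->i", diff, inv, diff)
        return out

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "class_means": self.class_means.tolist(),
            "pooled_cov": self.pooled_cov.tolist(),
            "priors": self.priors.tolist(),
            "axes": self.axes.tolist(),
            "ridge_used": self.ridge_used,
            "priors_mode": self.priors_mode,
            "feature_names": None if self.feature_names is None else list(self.feature_names),
            "class_counts": None if self.class_counts is None else self.class_counts.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LDAModel":
        model = cls(
            class_names=tuple(d["class_names"]),
            class_means=np.asarray(d["class_means"], dtype=float),
            pooled_cov=np.asarray(d["pooled_cov"], dtype=float),
            priors=np.asarray(d["priors"], dtype=float),
            ridge_used=float(d["ridge_used"]),
            priors_mode=str(d["priors_mode"]),
            feature_names=None if d.get("feature_names") is None else tuple(d["feature_names"]),
            class_counts=None if d.get("class_counts") is None else np.asarray(d["class_counts"], dtype=float),
        )
        model._axes = np.asarray(d["axes"], dtype=float)
        return model

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "LDAModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PosteriorRecord:
    """Posterior class probabilities for one subject."""

    subject_id: str
    posteriors: np.ndarray       # (K,), sums to 1
    predicted: str
    held_out: bool = False


def _resolve_xy(
    table_or_X: Union[SampleTable, np.ndarray],
    features=None,
    y=None,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], Optional[tuple[str, ...]], np.ndarray]:
    """Accept either (SampleTable, features) or (X, y=labels)."""
    if isinstance(table_or_X, SampleTable):
        table = table_or_X
        X = table.matrix(features)
        labels = table.groups
        class_order = table.class_names
        if features is not None and len(features) and isinstance(list(features)[0], str):
            names: Optional[tuple[str, ...]] = tuple(features)
        elif features is not None:
            names = tuple(table.metabolite_names[int(i)] for i in features)
        else:
            names = tuple(table.metabolite_names)
        ids = table.subject_ids
    else:
        X = np.asarray(table_or_X, dtype=float)
        if y is None:
            raise ValueError("labels y are required when passing a raw matrix")
        labels = np.asarray(y, dtype=object)
        class_order = tuple(dict.fromkeys(labels))
        names = None
        ids = None
    return X, labels, class_order, names, ids


def fit_lda(
    table_or_X: Union[SampleTable, np.ndarray],
    features=None,
    priors_mode: str = "proportional",
    y=None,
    class_order: Optional[Sequence[str]] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> LDAModel:
    """Fit pooled-covariance LDA.

    Accepts either a :class:`SampleTable` plus a feature index/name list,
    or a raw (n, p) matrix with labels ``y``.  ``priors_mode`` is
    ``"proportional"`` (class sample fractions, the convention of standard
    LDA software) or ``"equal"``.
    """
    X, labels, order, names, _ = _resolve_xy(table_or_X, features, y)
    if class_order is not None:
        order = tuple(class_order)
    if feature_names is not None:
        names = tuple(feature_names)
    if priors_mode not in ("proportional", "equal"):
        raise ValueError(f"unknown priors_mode {priors_mode!r}")
    if X.ndim != 2 or X.shape[1] == 0:
        raise FitError("feature matrix must be 2-D with at least one feature")
    if not np.all(np.isfinite(X)):
        raise FitError("non-finite value in feature matrix")

    K = len(order)
    n, p = X.shape
    counts = np.array([np.sum(labels == c) for c in order])
    if np.any(counts < 2):
        small = [c for c, m in zip(order, counts) if m < 2]
        raise FitError(f"every class needs >= 2 subjects to pool covariance; too small: {small}")
    if n - K < 1:
        raise FitError("not enough subjects to estimate the pooled covariance")

    means = np.vstack([X[labels == c].mean(axis=0) for c in order])
    pooled = np.zeros((p, p))
    for c, mu in zip(order, means):
        d = X[labels == c] - mu
        pooled += d.T @ d
    pooled /= n - K

    var = np.diag(pooled)
    if np.any(var <= 0):
        j = int(np.argmax(var <= 0))
        label = names[j] if names is not None else f"feature {j}"
        raise FitError(f"feature '{label}' is constant within every class")

    scale = np.trace(pooled) / p
    ridge_used = 0.0
    cov = pooled
    chol = None
    eye = np.eye(p)
    for eps in _RIDGE_LADDER:
        cov = pooled if eps == 0.0 else pooled + eps * scale * eye
        try:
            chol = scipy.linalg.cho_factor(cov, lower=True, check_finite=False)
        except scipy.linalg.LinAlgError:
            continue
        # escalate only when effectively singular in float64: collinear term
        # columns are otherwise left untouched so tiny discriminative
        # variances survive (a large ridge would wash them out)
        d = np.abs(np.diag(chol[0]))
        if d.min() > d.max() * 1e-15:
            ridge_used = eps * scale
            break
        chol = None
    if chol is None:
        raise FitError("pooled covariance is singular even after ridge escalation")

    if priors_mode == "equal":
        priors = np.full(K, 1.0 / K)
    else:
        priors = counts / n

    model = LDAModel(
        class_names=order,
        class_means=means,
        pooled_cov=cov,
        priors=priors,
        ridge_used=ridge_used,
        priors_mode=priors_mode,
        feature_names=names,
        class_counts=counts.astype(float),
    )
    model._chol = chol
    return model


def classify_batch(model: LDAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posteriors (n, K) and predicted labels (n,) for rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite value in input")
    log_post = np.log(model.priors)[None, :] - 0.5 * model.mahalanobis_sq(X)
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    pred = np.asarray(model.class_names, dtype=object)[np.argmax(post, axis=1)]
    return post, pred


def classify(model: LDAModel, x: np.ndarray, subject_id: str = "", held_out: bool = False) -> PosteriorRecord:
    """Classify a single feature vector; ties go to the first class in order."""
    post, pred = classify_batch(model, np.asarray(x, dtype=float)[None, :])
    return PosteriorRecord(subject_id=subject_id, posteriors=post[0], predicted=str(pred[0]), held_out=held_out)


def loo_evaluate(
    table_or_X: Union[SampleTable, np.ndarray],
    features=None,
    priors_mode: str = "proportional",
    y=None,
    class_order: Optional[Sequence[str]] = None,
) -> tuple[ClassificationReport, list[PosteriorRecord]]:
    """Leave-one-out evaluation: refit on n−1 subjects, classify the held-out one.

    The report aggregates all n held-out predictions; the result depends
    only on the data, never on subject order.
    """
    X, labels, order, names, ids = _resolve_xy(table_or_X, features, y)
    if class_order is not None:
        order = tuple(class_order)
    if ids is None:
        ids = np.array([f"S{i + 1:03d}" for i in range(X.shape[0])], dtype=object)
    counts = {c: int(np.sum(labels == c)) for c in order}
    small = [c for c, m in counts.items() if m < 3]
    if small:
        raise DegenerateFoldError(
            f"class(es) {small} have < 3 subjects: removing one member would leave a single-subject class"
        )
    n, p = X.shape
    K = len(order)
    if not np.all(np.isfinite(X)):
        raise FitError("non-finite value in feature matrix")

    # Per-class sufficient statistics; each fold's pooled covariance is an
    # exact rank-1 downdate of its class scatter, algebraically identical
    # to refitting from scratch.  All folds run through batched LAPACK.
    cls_idx = np.array([order.index(c) for c in labels])
    counts = np.bincount(cls_idx, minlength=K).astype(float)
    sums = np.zeros((K, p))
    scatters = np.zeros((K, p, p))
    for k in range(K):
        Xk = X[cls_idx == k]
        sums[k] = Xk.sum(axis=0)
        d = Xk - Xk.mean(axis=0)
        scatters[k] = d.T @ d
    total_scatter = scatters.sum(axis=0)
    base_means = sums / counts[:, None]

    diffs = X - base_means[cls_idx]                       # x_i - mean of own class
    fk = (counts / (counts - 1.0))[cls_idx]
    pooled_all = (total_scatter[None, :, :] - fk[:, None, None] * diffs[:, :, None] * diffs[:, None, :]) / (
        n - 1.0 - K
    )

    var_diag = np.einsum("ijj->ij", pooled_all)
    if np.any(var_diag <= 0):
        j = int(np.argmax((var_diag <= 0).any(axis=0)))
        label = names[j] if names is not None else f"feature {j}"
        raise FitError(f"feature '{label}' is constant within every class in some fold")

    inv_all = _batched_inverse(pooled_all)

    # held-out class means and fold priors
    means_all = np.broadcast_to(base_means, (n, K, p)).copy()
    mu_out = (sums[cls_idx] - X) / (counts[cls_idx] - 1.0)[:, None]
    means_all[np.arange(n), cls_idx] = mu_out
    fold_counts = np.broadcast_to(counts, (n, K)).copy()
    fold_counts[np.arange(n), cls_idx] -= 1.0
    if priors_mode == "equal":
        log_priors = np.zeros((n, K))
    else:
        log_priors = np.log(fold_counts / (n - 1.0))

    dxm = X[:, None, :] - means_all
    d2 = np.einsum("nkj,njl,nkl->nk", dxm, inv_all, dxm)
    log_post = log_priors - 0.5 * d2
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    pred_idx = np.argmax(post, axis=1)
    class_labels = np.asarray(order, dtype=object)
    preds = class_labels[pred_idx]

    records = [
        PosteriorRecord(subject_id=str(ids[i]), posteriors=post[i], predicted=str(preds[i]), held_out=True)
        for i in range(n)
    ]
    report = confusion_matrix(labels, preds, class_order=order, priors_mode=priors_mode)
    return report, records


def _batched_inverse(pooled_all: np.ndarray) -> np.ndarray:
    """Inverses of per-fold pooled covariances, with the ridge fallback.

    The fast path factorizes the whole (n, p, p) stack at once; only folds
    whose Cholesky fails (or is singular to machine precision) take the
    escalating-ridge detour.
    """
    n, p, _ = pooled_all.shape
    eye = np.eye(p)
    try:
        chol = np.linalg.cholesky(pooled_all)
        piv = np.einsum("ijj->ij", chol)
        if np.all(piv.min(axis=1) > piv.max(axis=1) * 1e-15):
            return np.linalg.inv(pooled_all)
    except np.linalg.LinAlgError:
        pass
    inv_all = np.empty_like(pooled_all)
    for i in range(n):
        pooled = pooled_all[i]
        scale = np.trace(pooled) / p
        ok = False
        for eps in _RIDGE_LADDER:
            cov = pooled if eps == 0.0 else pooled + eps * scale * eye
            try:
                c = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                continue
            d_piv = np.abs(np.diag(c))
            if d_piv.min() > d_piv.max() * 1e-15:
                inv_all[i] = np.linalg.inv(cov)
                ok = True
                break
        if not ok:
            raise FitError("pooled covariance is singular even after ridge escalation")
    return inv_all
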