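"""LD1/LD2 projection and 2-D discriminant decision regions.

For K = 3 classes the discriminant subspace has exactly K − 1 = 2 axes,
so the plane spanned by LD1 and LD2 carries *all* of the model's
discriminative information: classifying in the LD plane is equivalent to
classifying in the ambient feature space.  The region map rasterizes the
plane into cells, each labelled with the class a point at the cell centre
would receive — with equal priors these are the "cake-like" convex
regions of the Mahalanobis-nearest-centroid rule, whose boundaries for
three centroids meet at a single point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import scipy.linalg

from .cohort import SampleTable
from .lda import LDAModel

__all__ = ["MapResult", "project", "region_grid"]


@dataclass
class MapResult:
    """Rasterized decision regions in the LD1/LD2 plane."""

    centroids: np.ndarray            # (K, 2) class centroids in LD coordinates
    class_names: tuple[str, ...]
    grid: np.ndarray                 # (resolution, resolution) int class indices
    bounds: tuple[tuple[float, float], tuple[float, float]]  # ((x0,x1),(y0,y1))
    resolution: int
    coordinates: Optional[np.ndarray] = None   # (n, 2) subject projections
    groups: Optional[np.ndarray] = None

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        (x0, x1), (y0, y1) = self.bounds
        r = self.resolution
        xs = x0 + (np.arange(r) + 0.5) * (x1 - x0) / r
        ys = y0 + (np.arange(r) + 0.5) * (y1 - y0) / r
        return xs, ys

    def class_at(self, x: float, y: float) -> str:
        """Class label of the grid cell containing the point (clipped to bounds)."""
        (x0, x1), (y0, y1) = self.bounds
        r = self.resolution
        i = int(np.clip((x - x0) / (x1 - x0) * r, 0, r - 1))
        j = int(np.clip((y - y0) / (y1 - y0) * r, 0, r - 1))
        return self.class_names[self.grid[j, i]]

    def to_tsv(self) -> str:
        lines = ["# discriminant map: grid rows bottom-to-top, legend below"]
        for k, c in enumerate(self.class_names):
            lines.append(f"# {k}\t{c}")
        (x0, x1), (y0, y1) = self.bounds
        lines.append(f"# bounds\t{x0:.12g}\t{x1:.12g}\t{y0:.12g}\t{y1:.12g}")
        for row in self.grid:
            lines.append("".join(str(int(v)) for v in row))
        return "\n".join(lines) + "\n"


def project(model: LDAModel, data: Union[SampleTable, np.ndarray]) -> np.ndarray:
    """(LD1, LD2) coordinates: inner products with the first two axis loadings."""
    if model.n_axes < 2:
        raise ValueError(
            "model has a single discriminant axis (K = 2); use axes[:, 0] for a 1-D projection"
        )
    if isinstance(data, SampleTable):
        X = data.matrix(list(model.feature_names) if model.feature_names is not None else None)
    else:
        X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")
    return X @ model.axes[:, :2]


def region_grid(
    model: LDAModel,
    bounds=None,
    resolution: int = 400,
    priors_mode: Optional[str] = None,
    data: Union[SampleTable, np.ndarray, None] = None,
    groups=None,
) -> MapResult:
    """Label every cell of an LD-plane raster with its predicted class.

    Cell centres are scored by Mahalanobis distance to the projected class
    centroids under the projected pooled covariance, plus the prior term
    (``priors_mode`` defaults to the model's own mode; ``"equal"`` gives
    the purely geometric nearest-centroid partition).  Default bounds are
    the data range per axis expanded by 10%.
    """
    if priors_mode is None:
        priors_mode = model.priors_mode
    if priors_mode not in ("equal", "proportional"):
        raise ValueError(f"unknown priors_mode {priors_mode!r}")
    if resolution < 2:
        raise ValueError("resolution must be >= 2")

    A = model.axes[:, :2]
    if model.n_axes < 2:
        raise ValueError("region map needs >= 2 discriminant axes (K >= 3)")
    centroids = model.class_means @ A
    cov2 = A.T @ model.pooled_cov @ A  # ~identity under the eigh normalization

    coords = None
    grp = None
    if data is not None:
        coords = project(model, data)
        if isinstance(data, SampleTable):
            grp = data.groups
        elif groups is not None:
            grp = np.asarray(groups, dtype=object)

    if bounds is None:
        ref = coords if coords is not None else centroids
        mins = ref.min(axis=0)
        maxs = ref.max(axis=0)
        span = np.maximum(maxs - mins, 1e-9)
        mins = mins - 0.1 * span
        maxs = maxs + 0.1 * span
        bounds = ((float(mins[0]), float(maxs[0])), (float(mins[1]), float(maxs[1])))
    (x0, x1), (y0, y1) = bounds
    if not (np.isfinite([x0, x1, y0, y1]).all() and x1 > x0 and y1 > y0):
        raise ValueError("bounds must be finite with positive extent per axis")

    xs = x0 + (np.arange(resolution) + 0.5) * (x1 - x0) / resolution
    ys = y0 + (np.arange(resolution) + 0.5) * (y1 - y0) / resolution
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])

    chol = scipy.linalg.cho_factor(cov2, lower=True)
    K = len(model.class_names)
    score = np.empty((pts.shape[0], K))
    if priors_mode == "equal":
        log_priors = np.zeros(K)
    else:
        log_priors = np.log(model.priors)
    for k in range(K):
        diff = pts - centroids[k]
        w = scipy.linalg.cho_solve(chol, diff.T)
        score[:, k] = log_priors[k] - 0.5 * np.einsum("ij,ji->i", diff, w)
    grid = np.argmax(score, axis=1).reshape(resolution, resolution)

    return MapResult(
        centroids=centroids,
        class_names=model.class_names,
        grid=grid,
        bounds=bounds,
        resolution=resolution,
        coordinates=coords,
        groups=grp,
    )
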