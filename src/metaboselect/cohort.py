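"""Synthetic metabolomic cohorts and concentration-table I/O.

The generator emulates a small targeted-metabolomics case/control study:
a handful of diagnostic groups, a wide panel of metabolite concentrations
(µM) measured per subject, and a few engineered signal structures —
group-shifted marker metabolites, correlated metabolite blocks, and an
optional "nonlinear" pair whose product (not either marginal) carries the
class information.

Baseline concentrations are log-normal: each metabolite gets a log-scale
location drawn once from the seed, and subjects scatter around it with a
common log-scale noise SD.  Markers multiply the class mean; correlation
blocks share a latent Gaussian factor; the nonlinear pair uses a latent
sign that is aligned between the two columns in some classes and
anti-aligned in others, so the two marginal distributions are identical in
every class while degree-2 monomials of the pair separate them.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "LoadError",
    "SyntheticConfig",
    "SampleTable",
    "CsvDialect",
    "generate_cohort",
    "load_table",
    "write_table",
]


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration; message names the field."""


class LoadError(ValueError):
    """Malformed concentration CSV; message carries row/column coordinates."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for one synthetic cohort.

    Parameters
    ----------
    n_per_group:
        Subjects per class, in ``class_names`` order.  Defaults mirror a
        46-sample ophthalmic cohort (31 controls, 8 glaucoma, 7 diabetes).
    n_metabolites:
        Width of the concentration panel (default 188, the size of a
        standard targeted kit).
    marker_spec:
        ``(metabolite_index, per_class_shift)`` pairs.  Each shift is a
        multiplicative factor applied to that class's mean concentration
        (1.0 = no signal).
    correlation_blocks:
        ``(indices, rho)`` pairs; the listed columns share a latent factor
        giving pairwise latent correlation ``rho``.  Blocks must be
        disjoint.
    nonlinear_spec:
        ``((i, j), per_class_shift)``: plants class signal in the product
        of columns i and j.  A latent sign s = ±1 per subject displaces
        both columns by ±a on the log scale; classes with shift > 1 get
        aligned signs (product bimodal, boosted by the shift), classes
        with shift ≤ 1 anti-aligned signs (product constant).  The
        amplitude is a = max_c |ln shift_c| / 2, shared by all classes, so
        every marginal is the same two-point mixture and carries no class
        information.
    noise_sigma:
        Log-scale SD of subject scatter (0.3 ≈ 30% biological CV).
    nonlinear_sigma:
        Residual log-scale jitter on the nonlinear pair (kept tight so the
        product relation, not marginal spread, is the signal).
    age_spec:
        Optional per-class (mean, SD) in years; ages are Gaussian
        truncated at 18.
    """

    n_per_group: tuple[int, ...] = (31, 8, 7)
    n_metabolites: int = 188
    class_names: tuple[str, ...] = ("control", "glaucoma", "diabetes")
    marker_spec: tuple[tuple[int, tuple[float, ...]], ...] = ()
    correlation_blocks: tuple[tuple[tuple[int, ...], float], ...] = ()
    nonlinear_spec: Optional[tuple[tuple[int, int], tuple[float, ...]]] = None
    noise_sigma: float = 0.3
    nonlinear_sigma: float = 0.1
    seed: int = 0
    age_spec: Optional[tuple[tuple[float, float], ...]] = (
        (56.0, 13.0),
        (67.5, 7.5),
        (72.0, 3.0),
    )

    def __post_init__(self) -> None:
        k = len(self.class_names)
        if len(set(self.class_names)) != k or k < 2:
            raise ConfigError("class_names: must be >= 2 unique labels")
        if len(self.n_per_group) != k:
            raise ConfigError("n_per_group: length must match class_names")
        if any(int(n) != n or n < 2 for n in self.n_per_group):
            raise ConfigError("n_per_group: all group sizes must be integers >= 2")
        if self.n_metabolites < 1:
            raise ConfigError("n_metabolites: must be a positive integer")
        if not (self.noise_sigma > 0 and math.isfinite(self.noise_sigma)):
            raise ConfigError("noise_sigma: must be a finite positive real")
        if not (self.nonlinear_sigma > 0 and math.isfinite(self.nonlinear_sigma)):
            raise ConfigError("nonlinear_sigma: must be a finite positive real")
        for idx, shifts in self.marker_spec:
            if not 0 <= idx < self.n_metabolites:
                raise ConfigError(f"marker_spec: index {idx} >= n_metabolites")
            if len(shifts) != k:
                raise ConfigError(f"marker_spec: shifts for index {idx} must have one entry per class")
            if any(not (s > 0 and math.isfinite(s)) for s in shifts):
                raise ConfigError(f"marker_spec: shifts for index {idx} must be finite and positive")
        seen: set[int] = set()
        for indices, rho in self.correlation_blocks:
            if len(indices) < 2:
                raise ConfigError("correlation_blocks: each block needs >= 2 indices")
            if any(not 0 <= i < self.n_metabolites for i in indices):
                raise ConfigError("correlation_blocks: index out of range")
            if len(set(indices)) != len(indices) or seen & set(indices):
                raise ConfigError("correlation_blocks: blocks must be disjoint index sets")
            seen.update(indices)
            if not 0 <= rho < 1:
                raise ConfigError("correlation_blocks: rho must lie in [0, 1)")
        if self.nonlinear_spec is not None:
            (i, j), shifts = self.nonlinear_spec
            if i == j or not (0 <= i < self.n_metabolites and 0 <= j < self.n_metabolites):
                raise ConfigError("nonlinear_spec: pair must be two distinct valid indices")
            if len(shifts) != k:
                raise ConfigError("nonlinear_spec: one shift per class required")
            if any(not (s > 0 and math.isfinite(s)) for s in shifts):
                raise ConfigError("nonlinear_spec: shifts must be finite and positive")
        if self.age_spec is not None:
            if len(self.age_spec) != k:
                raise ConfigError("age_spec: one (mean, SD) pair per class required")
            if any(sd <= 0 or mu <= 0 for mu, sd in self.age_spec):
                raise ConfigError("age_spec: means and SDs must be positive")


@dataclass
class SampleTable:
    """Wide concentration table: one row per subject, one column per metabolite."""

    subject_ids: np.ndarray        # (n,) str
    groups: np.ndarray             # (n,) str
    metabolite_names: np.ndarray   # (p,) str
    concentrations: np.ndarray     # (n, p) float, µM, >= 0
    age: Optional[np.ndarray] = None  # (n,) float, years

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        self.metabolite_names = np.asarray(self.metabolite_names, dtype=object)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        n, p = self.concentrations.shape
        if len(self.subject_ids) != n or len(self.groups) != n:
            raise ValueError("subject_ids/groups length must equal the row count")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        if len(self.metabolite_names) != p or len(set(self.metabolite_names)) != p:
            raise ValueError("metabolite_names must be unique and match the column count")
        if not np.all(np.isfinite(self.concentrations)):
            raise ValueError("concentrations must be finite (no missing values)")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        counts = pd.Series(self.groups).value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"every class needs >= 2 subjects; too small: {small}")
        if self.age is not None:
            self.age = np.asarray(self.age, dtype=float)
            if len(self.age) != n or np.any(self.age < 0) or not np.all(np.isfinite(self.age)):
                raise ValueError("age must be one finite non-negative value per subject")

    # -- convenience -------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.concentrations.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.concentrations.shape[1]

    @property
    def class_names(self) -> tuple[str, ...]:
        """Class labels in order of first appearance."""
        return tuple(dict.fromkeys(self.groups))

    def class_sizes(self) -> dict[str, int]:
        return {c: int(np.sum(self.groups == c)) for c in self.class_names}

    def column_indices(self, names: Sequence[str]) -> list[int]:
        lookup = {m: i for i, m in enumerate(self.metabolite_names)}
        missing = [m for m in names if m not in lookup]
        if missing:
            raise KeyError(f"unknown metabolite(s): {missing}")
        return [lookup[m] for m in names]

    def matrix(self, features: Optional[Sequence] = None) -> np.ndarray:
        """Concentration sub-matrix for integer indices or metabolite names."""
        if features is None:
            return self.concentrations
        features = list(features)
        if features and isinstance(features[0], str):
            idx = self.column_indices(features)
        else:
            idx = [int(f) for f in features]
        return self.concentrations[:, idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.concentrations, columns=list(self.metabolite_names))
        df.insert(0, "group", self.groups)
        if self.age is not None:
            df.insert(1, "age", self.age)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def subset_rows(self, mask: np.ndarray) -> "SampleTable":
        return SampleTable(
            subject_ids=self.subject_ids[mask],
            groups=self.groups[mask],
            metabolite_names=self.metabolite_names.copy(),
            concentrations=self.concentrations[mask],
            age=None if self.age is None else self.age[mask],
        )


def _metabolite_labels(p: int) -> np.ndarray:
    return np.array([f"M{i + 1:03d}" for i in range(p)], dtype=object)


def generate_cohort(config: SyntheticConfig) -> SampleTable:
    """Draw one cohort from the configuration; bitwise-reproducible per seed.

    The draw order is fixed (baseline locations, latent matrix, block
    factors, nonlinear signs, ages) so identical configs give identical
    tables.
    """
    rng = np.random.default_rng(config.seed)
    k = len(config.class_names)
    n = int(sum(config.n_per_group))
    p = config.n_metabolites
    groups = np.repeat(np.asarray(config.class_names, dtype=object), config.n_per_group)
    class_index = np.repeat(np.arange(k), config.n_per_group)

    # metabolite-specific log-scale location, drawn once: median ~5 µM,
    # spanning roughly 0.05-500 µM across the panel
    mu = rng.normal(math.log(5.0), 1.5, size=p)
    z = rng.standard_normal((n, p))
    for indices, rho in config.correlation_blocks:
        f = rng.standard_normal(n)
        for i in indices:
            z[:, i] = math.sqrt(rho) * f + math.sqrt(1.0 - rho) * z[:, i]
    log_conc = mu[None, :] + config.noise_sigma * z

    if config.nonlinear_spec is not None:
        (i, j), shifts = config.nonlinear_spec
        log_shift = np.log(np.asarray(shifts, dtype=float))
        amplitude = float(np.max(np.abs(log_shift))) / 2.0
        align = np.where(log_shift > 0, 1.0, -1.0)[class_index]
        s = rng.choice([-1.0, 1.0], size=n)
        eps_i = rng.standard_normal(n)
        eps_j = rng.standard_normal(n)
        log_conc[:, i] = mu[i] + amplitude * s + config.nonlinear_sigma * eps_i
        log_conc[:, j] = mu[j] + amplitude * align * s + config.nonlinear_sigma * eps_j

    # markers apply after the nonlinear overwrite so a marker placed on a
    # nonlinear column adds a marginal shift on top of the product signal
    for m_idx, shifts in config.marker_spec:
        log_conc[:, m_idx] += np.log(np.asarray(shifts))[class_index]

    age = None
    if config.age_spec is not None:
        means = np.asarray([m for m, _ in config.age_spec])[class_index]
        sds = np.asarray([s for _, s in config.age_spec])[class_index]
        age = means + sds * rng.standard_normal(n)
        while np.any(age < 18):  # truncate at adulthood by resampling
            bad = age < 18
            age[bad] = means[bad] + sds[bad] * rng.standard_normal(int(bad.sum()))

    return SampleTable(
        subject_ids=np.array([f"S{i + 1:03d}" for i in range(n)], dtype=object),
        groups=groups,
        metabolite_names=_metabolite_labels(p),
        concentrations=np.exp(log_conc),
        age=age,
    )


def study_config(seed: int = 0, nonlinear: bool = True, n_metabolites: int = 188) -> SyntheticConfig:
    """Default cohort recipe emulating a 46-sample, 3-group ophthalmic study.

    Four marker metabolites mimic the structure of a selected diagnostic
    panel: a clean diabetes marker (acetyl-ornithine-like), two
    glaucoma-shifted metabolites whose marginal shifts are only partial,
    and a mildly shifted fourth; two of them form a positively correlated
    block.  With ``nonlinear=True`` the decisive glaucoma signal is
    carried by the *product structure* of the two partially shifted
    metabolites (a small two-point latent aligned in glaucoma,
    anti-aligned elsewhere), so the linear stage plateaus below full
    accuracy and the polynomial stage has something genuine to find.
    Ages follow the group means of a refractive-surgery control pool
    (56 / 67.5 / 72 y).
    """
    i_pc, i_orn, i_c3, i_cdc = 9, 19, 29, 39
    markers = (
        (i_pc, (1.0, 2.5, 1.0)),    # PC-like: partial glaucoma shift
        (i_orn, (1.0, 1.0, 4.5)),   # Ac-Orn-like: strong diabetes marker
        (i_c3, (1.0, 2.5, 1.0)),    # C3-like: partial glaucoma shift
        (i_cdc, (1.0, 1.3, 1.6)),   # C3-DC-like: mild shifts in both diseases
    )
    nl = ((i_c3, i_pc), (1.0, 2.5, 1.0)) if nonlinear else None
    return SyntheticConfig(
        n_per_group=(31, 8, 7),
        n_metabolites=n_metabolites,
        noise_sigma=0.25,
        marker_spec=markers,
        correlation_blocks=(((i_orn, i_cdc), 0.45),),
        nonlinear_spec=nl,
        nonlinear_sigma=0.05,
        seed=seed,
    )


def expected_class_means(config: SyntheticConfig) -> np.ndarray:
    """Population mean concentration per (class, metabolite) implied by the config.

    Replays the generator's baseline draw for the log-scale locations and
    applies the log-normal mean formula exp(µ + σ²/2) with marker shifts;
    nonlinear columns get the two-point-mixture factor cosh(a)·exp(σ_nl²/2),
    identical for every class (their marginals carry no signal).
    """
    rng = np.random.default_rng(config.seed)
    k = len(config.class_names)
    p = config.n_metabolites
    mu = rng.normal(math.log(5.0), 1.5, size=p)
    means = np.tile(np.exp(mu + config.noise_sigma**2 / 2.0), (k, 1))
    if config.nonlinear_spec is not None:
        (i, j), shifts = config.nonlinear_spec
        amplitude = float(np.max(np.abs(np.log(np.asarray(shifts))))) / 2.0
        factor = math.cosh(amplitude) * math.exp(config.nonlinear_sigma**2 / 2.0)
        means[:, i] = np.exp(mu[i]) * factor
        means[:, j] = np.exp(mu[j]) * factor
    for m_idx, shifts in config.marker_spec:
        means[:, m_idx] *= np.asarray(shifts, dtype=float)
    return means


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping and missing-value policy for concentration CSVs."""

    id_col: str = "subject_id"
    group_col: str = "group"
    age_col: Optional[str] = "age"
    missing_policy: str = "impute-half-min"  # or "error"
    drop_missing_fraction: float = 0.2


def load_table(path, dialect: CsvDialect = CsvDialect()) -> SampleTable:
    """Read a wide CSV into a validated :class:`SampleTable`.

    Empty/below-LOD cells are imputed as half the column's minimum positive
    value under the default policy; metabolites missing in more than
    ``drop_missing_fraction`` of subjects are dropped.
    """
    df = pd.read_csv(path)
    if dialect.group_col not in df.columns:
        raise LoadError(f"missing group column '{dialect.group_col}' in {path}")
    if dialect.id_col not in df.columns:
        raise LoadError(f"missing id column '{dialect.id_col}' in {path}")
    ids = df[dialect.id_col].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise LoadError(f"duplicate subject id '{dup.iloc[0]}' at row {dup.index[0] + 2}")

    meta_cols = [c for c in df.columns if c not in (dialect.id_col, dialect.group_col, dialect.age_col)]
    numeric = {}
    for c in meta_cols:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna() & (df[c].astype(str).str.strip() != "")
        if bad.any():
            raise LoadError(f"non-numeric value in column '{c}' at row {bad.idxmax() + 2}")
        numeric[c] = col
    conc = pd.DataFrame(numeric, index=df.index)

    frac_missing = conc.isna().mean()
    keep = frac_missing[frac_missing <= dialect.drop_missing_fraction].index
    conc = conc[keep]
    if conc.isna().any().any():
        if dialect.missing_policy == "error":
            col = conc.columns[conc.isna().any().argmax()]
            raise LoadError(f"missing value in column '{col}'")
        for c in conc.columns[conc.isna().any()]:
            positive = conc[c][conc[c] > 0]
            if positive.empty:
                raise LoadError(f"column '{c}' has no positive value to impute from")
            conc[c] = conc[c].fillna(positive.min() / 2.0)

    age = None
    if dialect.age_col is not None and dialect.age_col in df.columns:
        age = pd.to_numeric(df[dialect.age_col], errors="coerce").to_numpy()
    return SampleTable(
        subject_ids=ids.to_numpy(dtype=object),
        groups=df[dialect.group_col].astype(str).to_numpy(dtype=object),
        metabolite_names=np.asarray(conc.columns, dtype=object),
        concentrations=conc.to_numpy(dtype=float),
        age=age,
    )


def write_table(table: SampleTable, path) -> None:
    """Write the cohort as an RFC-4180 wide CSV (round-trips via load_table)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(path, index=False)
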