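"""Clustered-data containers and design-matrix construction.

Long-format tables (one row per observation) are turned into the stacked
design matrices of a linear mixed model

    y = beta0 * 1 + X beta + Z gamma + eps,

with a response vector ``y``, a fixed-effects matrix ``X`` (the intercept is
kept separate, so ``X`` carries no column of ones) and per-cluster
random-effects designs ``Z_i`` whose stacked form is block-diagonal.
Observations are reordered on ingestion so each cluster occupies a contiguous
block of rows; the original row order is retained so fitted values can be
mapped back to the input table.

The module also classifies fixed-effect covariates as *cluster-constant*
(one value per cluster, e.g. gender or treatment arm) versus
*cluster-varying* — the distinction that drives the random-effects
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "DataError",
    "NumericError",
    "LMMData",
    "CovariateClassification",
    "build_design",
    "classify_covariates",
]


class ConfigurationError(ValueError):
    """A column name, option or model specification is invalid."""


class DataError(ValueError):
    """The data violate a precondition (missing values, zero variance, ...)."""


class NumericError(ArithmeticError):
    """A numerical operation produced a non-finite or singular result."""


@dataclass(eq=False)
class LMMData:
    """Clustered observations with fixed- and random-effects designs.

    Rows are ordered cluster by cluster: observations of cluster ``i`` occupy
    the contiguous slice ``cluster_starts[i]:cluster_starts[i + 1]``.

    Attributes
    ----------
    y : (N,) response vector, N = sum of the cluster sizes n_i.
    X : (N, p) fixed-effects design without an intercept column.
    Z : (N, q) stacked rows of the per-cluster random-effects designs; the
        full random-effects design is the block-diagonal diag(Z_1, ..., Z_n).
    cluster_index : (N,) integer cluster position (0..n-1) per row,
        non-decreasing.
    cluster_labels : (n,) original cluster identifiers, in block order.
    covariate_names : p fixed-effect labels.
    random_effect_spec : q labels; ``"(intercept)"`` first when a random
        intercept is present, the remaining entries name covariates carrying
        random slopes.
    has_random_intercept : whether column 0 of ``Z`` is the ones column.
    original_order : (N,) position of each (reordered) row in the input
        table, so ``values[argsort(original_order)]`` restores input order.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    cluster_index: np.ndarray
    cluster_labels: np.ndarray
    covariate_names: list[str]
    random_effect_spec: list[str]
    has_random_intercept: bool = True
    original_order: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.cluster_index = np.asarray(self.cluster_index, dtype=np.intp)
        N = self.y.shape[0]
        if self.X.shape[0] != N or self.Z.shape[0] != N:
            raise ConfigurationError(
                f"design rows ({self.X.shape[0]}, {self.Z.shape[0]}) do not "
                f"match the {N} responses"
            )
        if self.cluster_index.shape[0] != N:
            raise ConfigurationError("cluster_index length does not match y")
        if np.any(np.diff(self.cluster_index) < 0):
            raise ConfigurationError(
                "observations must be contiguous and sorted by cluster"
            )
        if len(self.covariate_names) != self.p:
            raise ConfigurationError("covariate_names length != p")
        if len(self.random_effect_spec) != self.q:
            raise ConfigurationError("random_effect_spec length != q")
        counts = np.bincount(self.cluster_index, minlength=self.n)
        if np.any(counts < 1):
            raise DataError("every cluster needs at least one observation")

    # -- shapes ---------------------------------------------------------
    @property
    def N(self) -> int:
        """Total number of observations."""
        return self.y.shape[0]

    @property
    def n(self) -> int:
        """Number of clusters."""
        return int(self.cluster_index[-1]) + 1 if self.N else 0

    @property
    def p(self) -> int:
        """Number of fixed-effect covariates (intercept excluded)."""
        return self.X.shape[1]

    @property
    def q(self) -> int:
        """Number of random effects per cluster."""
        return self.Z.shape[1]

    @property
    def cluster_sizes(self) -> np.ndarray:
        """(n,) observations per cluster."""
        return np.bincount(self.cluster_index, minlength=self.n)

    @property
    def cluster_starts(self) -> np.ndarray:
        """(n + 1,) slice boundaries of the cluster blocks."""
        key = "cluster_starts"
        if key not in self._cache:
            self._cache[key] = np.concatenate(
                [[0], np.cumsum(self.cluster_sizes)]
            )
        return self._cache[key]

    @property
    def Z_blocks(self) -> list[np.ndarray]:
        """Per-cluster random-effects designs Z_i (n_i x q views)."""
        s = self.cluster_starts
        return [self.Z[s[i]: s[i + 1]] for i in range(self.n)]


@dataclass
class CovariateClassification:
    """Cluster-constant flags and the per-cluster representative rows.

    ``representatives`` holds the first observation of every cluster for all
    covariates (n x p); only columns flagged cluster-constant are meaningful
    as cluster-level values.
    """

    is_cluster_constant: np.ndarray
    representatives: np.ndarray

    def cluster_constant_matrix(self) -> np.ndarray:
        """(n, k) representative matrix of the cluster-constant covariates."""
        return self.representatives[:, self.is_cluster_constant]


def build_design(
    table: pd.DataFrame,
    response: str,
    cluster: str,
    fixed: list[str],
    random_slopes: list[str] | None = None,
    random_intercept: bool = True,
    standardize: bool = False,
) -> LMMData:
    """Assemble an :class:`LMMData` from a long-format table.

    Parameters
    ----------
    table : one row per observation.
    response, cluster : column names of the response and cluster identifier.
    fixed : fixed-effect covariate column names (order defines beta).
    random_slopes : covariate columns that additionally carry a random slope.
    random_intercept : include a random intercept (ones column of Z_i).
    standardize : center/scale fixed covariates to unit variance (off by
        default; simulated covariates are already standard normal).

    Rows are sorted stably by cluster so blocks are contiguous; the original
    positions are kept in ``original_order``.
    """
    random_slopes = list(random_slopes or [])
    fixed = list(fixed)
    if not random_intercept and not random_slopes:
        raise ConfigurationError("model needs at least one random effect")
    used = [response, cluster] + fixed + [
        s for s in random_slopes if s not in fixed
    ]
    missing_cols = [c for c in used if c not in table.columns]
    if missing_cols:
        raise ConfigurationError(f"unknown column(s): {missing_cols}")
    for s in random_slopes:
        if s not in fixed:
            warnings.warn(
                f"random slope on {s!r} without a corresponding fixed "
                "effect",
                UserWarning,
                stacklevel=2,
            )
    sub = table[list(dict.fromkeys(used))]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise DataError(f"missing values in column(s): {bad}")

    order = np.argsort(table[cluster].to_numpy(), kind="stable")
    labels, cluster_index = np.unique(
        table[cluster].to_numpy()[order], return_inverse=True
    )
    y = table[response].to_numpy(dtype=float)[order]
    X = table[fixed].to_numpy(dtype=float)[order] if fixed else np.empty((len(y), 0))
    if standardize and X.shape[1]:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    cols = []
    spec = []
    if random_intercept:
        cols.append(np.ones(len(y)))
        spec.append("(intercept)")
    for s in random_slopes:
        cols.append(table[s].to_numpy(dtype=float)[order])
        spec.append(s)
    Z = np.column_stack(cols)

    return LMMData(
        y=y,
        X=X,
        Z=Z,
        cluster_index=cluster_index,
        cluster_labels=labels,
        covariate_names=fixed,
        random_effect_spec=spec,
        has_random_intercept=random_intercept,
        original_order=order,
    )


def classify_covariates(data: LMMData) -> CovariateClassification:
    """Flag each fixed-effect covariate as cluster-constant or not.

    A covariate is cluster-constant iff its value is *exactly* identical
    within every cluster (no numeric tolerance). The returned classification
    carries the n-row representative matrix taken from the first observation
    of each cluster.
    """
    starts = data.cluster_starts[:-1]
    reps = data.X[starts]
    expanded = reps[data.cluster_index]
    is_const = np.all(data.X == expanded, axis=0)
    return CovariateClassification(
        is_cluster_constant=np.asarray(is_const, dtype=bool),
        representatives=reps,
    )
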