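"""Duality-diagram engine and non-symmetric correspondence analysis (NSC).

An ordination here is a *duality diagram*: a triple (Z, d, q) of a
transformed table, row weights and a column metric, whose generalized
eigendecomposition (equivalently the SVD of ``D^1/2 Z Q^1/2``) yields
eigenvalues, column axes orthonormal under ``diag(q)``, and row scores.

NSC decomposes the predictability of a frequency table's columns from its
row profiles: with row profiles ``a_ij = f_ij / f_i.`` and column masses
``c_j = f_.j / N`` it analyses ``Z_ij = m (a_ij - c_j)`` under row-mass
weights ``d_i = f_i. / N`` and the uniform column metric ``q_j = 1/m``.
Group-centroid condensation of a diagram (the supervision step) analyses
weighted group means instead of individual rows/columns, which bounds the
non-null axes at (number of groups - 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DataError, NumericalError

#: eigenvalues below this fraction of the leading eigenvalue count as null axes
NULL_AXIS_RTOL = 1e-12


@dataclass
class DualityDiagram:
    """An ordination result.

    Attributes
    ----------
    Z : (n, m) transformed table
    row_weights : length-n nonnegative weights summing to 1
    col_metric : length-m positive column metric
    eigenvalues : nonincreasing, nonnegative; sums to ``total_inertia``
    col_axes : (m, K), orthonormal under ``diag(col_metric)``
    row_scores : (n, K) row coordinates ``Z Q col_axes``
    centering : length-m vector subtracted from row profiles (NSC only)
    """

    Z: np.ndarray
    row_weights: np.ndarray
    col_metric: np.ndarray
    eigenvalues: np.ndarray
    col_axes: np.ndarray
    row_scores: np.ndarray
    total_inertia: float
    row_ids: list | None = None
    col_ids: list | None = None
    centering: np.ndarray | None = None

    @property
    def n_nonnull_axes(self) -> int:
        lam = self.eigenvalues
        if lam.size == 0 or lam[0] <= 0:
            return 0
        return int(np.sum(lam > NULL_AXIS_RTOL * lam[0]))


@dataclass
class GroupCondensation:
    """Weighted group-centroid condensation of a duality diagram."""

    group_labels: list
    Z_bar: np.ndarray
    group_weights: np.ndarray
    between_inertia_ratio: float
    diagram: DualityDiagram


def inertia(Z: np.ndarray, d: np.ndarray, q: np.ndarray) -> float:
    """Total weighted inertia ``sum_i d_i sum_j q_j Z_ij^2``."""
    return float(np.einsum("i,ij,j->", d, Z**2, q))


def diagonalize(
    Z: np.ndarray,
    d: np.ndarray,
    q: np.ndarray,
    n_components: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generalized eigendecomposition of a duality diagram.

    Equivalent to the SVD of ``D^1/2 Z Q^1/2``: eigenvalues are squared
    singular values, column axes are the right singular vectors
    back-transformed by ``Q^-1/2`` (hence q-orthonormal), and row scores
    are ``Z Q col_axes``.  Axis signs are fixed so the largest-magnitude
    entry of each column axis is positive.
    """
    Z = np.asarray(Z, dtype=float)
    d = np.asarray(d, dtype=float)
    q = np.asarray(q, dtype=float)
    n, m = Z.shape
    if d.shape != (n,) or q.shape != (m,):
        raise DataError("diagonalize: inconsistent dimensions")
    if np.any(d < 0) or np.any(q <= 0):
        raise DataError("diagonalize: d must be >= 0 and q > 0")
    k_max = min(n, m)
    if n_components is None:
        n_components = k_max
    if n_components < 1:
        raise DataError("n_components must be >= 1")
    k = min(n_components, k_max)
    M = np.sqrt(d)[:, None] * Z * np.sqrt(q)[None, :]
    try:
        _, s, vt = np.linalg.svd(M, full_matrices=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError(f"SVD failed: {exc}") from exc
    eigenvalues = s**2
    V = vt.T[:, :k]
    # deterministic sign: dominant loading of each axis is positive
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    V = V * flip[None, :]
    col_axes = V / np.sqrt(q)[:, None]
    row_scores = (Z * q[None, :]) @ col_axes
    return eigenvalues[:k], col_axes, row_scores


def nsc(
    F: np.ndarray,
    row_weights: np.ndarray | None = None,
    n_components: int | None = None,
    row_ids: Sequence | None = None,
    col_ids: Sequence | None = None,
) -> DualityDiagram:
    """Non-symmetric correspondence analysis of a nonnegative table.

    Parameters
    ----------
    F
        Nonnegative table (n rows x m columns) with positive grand total.
    row_weights
        Optional externally imposed row weights (used when coupling a motif
        table under the expression table's gene weights).  When omitted the
        natural row masses ``f_i. / N`` are used.  The centering is always
        the ``row_weights``-weighted mean profile, so rows of Z average to
        zero under the active weights.

    Rows with zero sum are assigned the mean column profile, so they carry
    zero inertia but remain projectable.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2:
        raise DataError("nsc requires a 2-D table")
    if np.any(F < 0):
        raise DataError("negative entries")
    total = F.sum()
    if total <= 0:
        raise DataError("nsc requires a table with positive grand total")
    n, m = F.shape
    row_sums = F.sum(axis=1)
    nonzero = row_sums > 0
    if row_weights is None:
        d = row_sums / total
    else:
        d = np.asarray(row_weights, dtype=float)
        if d.shape != (n,):
            raise DataError("row_weights length mismatch")
        if np.any(d < 0) or not np.isclose(d.sum(), 1.0, atol=1e-8):
            raise DataError("row_weights must be nonnegative and sum to 1")
    a = np.zeros_like(F)
    a[nonzero] = F[nonzero] / row_sums[nonzero, None]
    # centering: d-weighted mean profile; zero-sum rows sit exactly at it
    d_zero = d[~nonzero].sum()
    if d_zero >= 1.0:
        raise DataError("all row weight concentrated on zero-sum rows")
    c = (d[nonzero] @ a[nonzero]) / (1.0 - d_zero)
    a[~nonzero] = c
    Z = m * (a - c[None, :])
    q = np.full(m, 1.0 / m)
    total_inertia = inertia(Z, d, q)
    eigenvalues, col_axes, row_scores = diagonalize(Z, d, q, n_components)
    return DualityDiagram(
        Z=Z,
        row_weights=d,
        col_metric=q,
        eigenvalues=eigenvalues,
        col_axes=col_axes,
        row_scores=row_scores,
        total_inertia=total_inertia,
        row_ids=list(row_ids) if row_ids is not None else None,
        col_ids=list(col_ids) if col_ids is not None else None,
        centering=c,
    )


def _labels_array(
    labels: Mapping | Sequence, ids: Sequence | None, n: int, what: str
) -> np.ndarray:
    if isinstance(labels, Mapping):
        if ids is None:
            raise DataError(f"label map given but diagram has no {what} ids")
        out = np.array([labels.get(i) for i in ids], dtype=object)
    else:
        out = np.asarray(labels, dtype=object)
        if out.shape != (n,):
            raise DataError(f"expected {n} {what} labels, got {out.shape}")
    return out


def group_condense(
    dd: DualityDiagram, groups: Mapping | Sequence
) -> GroupCondensation:
    """Condense a diagram's rows to weighted group centroids.

    The centroid of group g is the ``d``-weighted mean of its rows; group
    weights are the summed row weights.  The between-group inertia ratio is
    the condensed inertia over the total (centroids of a centered table
    never exceed the original inertia).

    ``groups`` is either a label per row or a mapping from row id to label.
    Every row with positive weight must be labelled.
    """
    labels = _labels_array(groups, dd.row_ids, dd.Z.shape[0], "row")
    missing = (labels == None) & (dd.row_weights > 0)  # noqa: E711
    if missing.any():
        raise DataError(
            f"rows with positive weight lack a group label: "
            f"{np.flatnonzero(missing)[:10].tolist()}"
        )
    keep = labels != None  # noqa: E711
    uniq = sorted(set(labels[keep]))
    g = len(uniq)
    Z_bar = np.zeros((g, dd.Z.shape[1]))
    w = np.zeros(g)
    for gi, lab in enumerate(uniq):
        mask = labels == lab
        w[gi] = dd.row_weights[mask].sum()
        if w[gi] > 0:
            Z_bar[gi] = dd.row_weights[mask] @ dd.Z[mask] / w[gi]
    between = inertia(Z_bar, w, dd.col_metric)
    ratio = between / dd.total_inertia if dd.total_inertia > 0 else 0.0
    eigenvalues, col_axes, row_scores = diagonalize(Z_bar, w, dd.col_metric)
    diagram = DualityDiagram(
        Z=Z_bar,
        row_weights=w,
        col_metric=dd.col_metric,
        eigenvalues=eigenvalues,
        col_axes=col_axes,
        row_scores=row_scores,
        total_inertia=between,
        row_ids=uniq,
        col_ids=dd.col_ids,
    )
    return GroupCondensation(
        group_labels=uniq,
        Z_bar=Z_bar,
        group_weights=w,
        between_inertia_ratio=float(ratio),
        diagram=diagram,
    )


def condense_columns(
    dd: DualityDiagram, groups: Mapping | Sequence
) -> tuple[DualityDiagram, list]:
    """Condense a diagram's *columns* to q-weighted group centroid columns.

    Used for supervision of an expression ordination whose columns are
    arrays: the condensed diagram keeps the gene rows and row weights but
    replaces the array columns by group centroids, with the summed column
    metric as the new (group) metric.  Because NSC rows are centered, the
    weighted mean of the centroid columns is zero, so the condensed diagram
    has at most (groups - 1) non-null axes.
    """
    n, m = dd.Z.shape
    labels = _labels_array(groups, dd.col_ids, m, "column")
    missing = (labels == None) & (dd.col_metric > 0)  # noqa: E711
    if missing.any():
        raise DataError("columns with positive metric lack a group label")
    uniq = sorted(set(labels[labels != None]))  # noqa: E711
    g = len(uniq)
    C = np.zeros((n, g))
    w = np.zeros(g)
    for gi, lab in enumerate(uniq):
        mask = labels == lab
        w[gi] = dd.col_metric[mask].sum()
        C[:, gi] = dd.Z[:, mask] @ dd.col_metric[mask] / w[gi]
    total_inertia = inertia(C, dd.row_weights, w)
    eigenvalues, col_axes, row_scores = diagonalize(C, dd.row_weights, w)
    condensed = DualityDiagram(
        Z=C,
        row_weights=dd.row_weights,
        col_metric=w,
        eigenvalues=eigenvalues,
        col_axes=col_axes,
        row_scores=row_scores,
        total_inertia=total_inertia,
        row_ids=dd.row_ids,
        col_ids=uniq,
    )
    return condensed, uniq


class NonSymmetricCorrespondenceAnalysis(BaseEstimator, TransformerMixin):
    """Sklearn-style NSC ordination of a nonnegative table.

    ``fit(X)`` builds the duality diagram of X; ``transform(X')`` projects
    new rows (as row profiles centered on the fitted mean profile) onto the
    fitted axes.

    Attributes (after fit)
    ----------------------
    eigenvalues_, col_axes_, row_scores_, row_weights_, col_metric_,
    total_inertia_, diagram_
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        dd = nsc(np.asarray(X), n_components=self.n_components)
        self.diagram_ = dd
        self.eigenvalues_ = dd.eigenvalues
        self.col_axes_ = dd.col_axes
        self.row_scores_ = dd.row_scores
        self.row_weights_ = dd.row_weights
        self.col_metric_ = dd.col_metric
        self.total_inertia_ = dd.total_inertia
        self.centering_ = dd.centering
        self.n_features_in_ = dd.Z.shape[1]
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).row_scores_

    def transform(self, X):
        if not hasattr(self, "diagram_"):
            raise DataError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise DataError("negative entries")
        m = self.n_features_in_
        if X.shape[1] != m:
            raise DataError("column count differs from the fitted table")
        row_sums = X.sum(axis=1)
        a = np.where(
            row_sums[:, None] > 0,
            X / np.where(row_sums[:, None] > 0, row_sums[:, None], 1.0),
            self.centering_[None, :],
        )
        Z = m * (a - self.centering_[None, :])
        return (Z * self.col_metric_[None, :]) @ self.col_axes_
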