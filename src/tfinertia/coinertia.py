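"""Co-inertia analysis: coupling two ordinations over shared gene rows.

Co-inertia analysis (CIA) takes two duality diagrams whose rows are the
same genes under one shared row weighting, forms the weighted cross matrix
``W = Z_A^T D Z_B`` and decomposes ``Q_A^1/2 W Q_B^1/2`` by SVD.  Each axis
pair maximizes the squared weighted covariance between gene scores of the
two tables; the RV coefficient summarizes the global co-structure in [0,1].

Supervision (between-group analysis) condenses the expression diagram's
array columns to two weighted group-centroid columns before the coupling.
Because NSC rows are centered, the condensed table has exactly one
non-null axis for two groups, and motifs are ranked by their signed
loading on it (positive pole = group 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .data import ComparisonSpec, ExpressionMatrix, MotifIncidenceTable, SampleDesign
from .exceptions import DataError
from .ordination import (
    NULL_AXIS_RTOL,
    DualityDiagram,
    condense_columns,
    diagonalize,
    nsc,
)


@dataclass
class CoinertiaResult:
    """Coupled-axes result of a co-inertia analysis."""

    singular_values: np.ndarray
    array_loadings: np.ndarray
    motif_loadings: np.ndarray
    gene_scores_A: np.ndarray
    gene_scores_B: np.ndarray
    rv: float
    total_coinertia: float
    array_ids: list | None = None
    motif_ids: list | None = None
    gene_ids: list | None = None
    eigenvalues_A: np.ndarray | None = None
    eigenvalues_B: np.ndarray | None = None

    @property
    def n_nonnull_axes(self) -> int:
        s = self.singular_values
        if s.size == 0 or s[0] <= 0:
            return 0
        return int(np.sum(s > NULL_AXIS_RTOL * s[0]))


@dataclass
class RankedMotifList:
    """Motifs ordered by signed association with a comparison's group 1."""

    comparison: str
    threshold_label: str
    motif_ids: list[str]
    scores: np.ndarray
    coinertia: CoinertiaResult | None = field(default=None, repr=False)

    def rank_of(self, motif_id: str) -> int:
        """1-based rank of a motif in this list."""
        return self.motif_ids.index(motif_id) + 1


def cia(
    ddA: DualityDiagram,
    ddB: DualityDiagram,
    common_d: np.ndarray | None = None,
    n_components: int | None = None,
) -> CoinertiaResult:
    """Co-inertia analysis of two diagrams sharing weighted gene rows.

    ``common_d`` defaults to ``ddA.row_weights`` and must match both
    diagrams' row dimension and sum to 1.  Axis signs are fixed so each
    axis's dominant B-side (motif) loading is positive.
    """
    if ddA.Z.shape[0] != ddB.Z.shape[0]:
        raise DataError("diagrams have different numbers of gene rows")
    if (
        ddA.row_ids is not None
        and ddB.row_ids is not None
        and ddA.row_ids != ddB.row_ids
    ):
        raise DataError("gene row order differs between the two diagrams")
    d = ddA.row_weights if common_d is None else np.asarray(common_d, float)
    if d.shape != (ddA.Z.shape[0],) or not np.isclose(d.sum(), 1.0, atol=1e-8):
        raise DataError("common_d must cover all gene rows and sum to 1")
    if ddA.total_inertia <= 0 or ddB.total_inertia <= 0:
        raise DataError("zero inertia in one of the coupled tables")
    qA, qB = ddA.col_metric, ddB.col_metric
    W = ddA.Z.T @ (d[:, None] * ddB.Z)
    M = np.sqrt(qA)[:, None] * W * np.sqrt(qB)[None, :]
    U, s, vt = np.linalg.svd(M, full_matrices=False)
    total_coinertia = float(np.sum(s**2))
    k_max = s.size
    k = k_max if n_components is None else min(n_components, k_max)
    U, s, V = U[:, :k], s[:k], vt.T[:, :k]
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    U = U * flip[None, :]
    V = V * flip[None, :]
    array_loadings = U / np.sqrt(qA)[:, None]
    motif_loadings = V / np.sqrt(qB)[:, None]
    gene_scores_A = (ddA.Z * qA[None, :]) @ array_loadings
    gene_scores_B = (ddB.Z * qB[None, :]) @ motif_loadings
    # full eigenvalue sets of both diagrams, for the RV denominator
    lamA = _full_eigenvalues(ddA)
    lamB = _full_eigenvalues(ddB)
    denom = np.sqrt(np.sum(lamA**2) * np.sum(lamB**2))
    rv = total_coinertia / denom if denom > 0 else 0.0
    return CoinertiaResult(
        singular_values=s,
        array_loadings=array_loadings,
        motif_loadings=motif_loadings,
        gene_scores_A=gene_scores_A,
        gene_scores_B=gene_scores_B,
        rv=float(rv),
        total_coinertia=total_coinertia,
        array_ids=ddA.col_ids,
        motif_ids=ddB.col_ids,
        gene_ids=ddA.row_ids if ddA.row_ids is not None else ddB.row_ids,
        eigenvalues_A=lamA,
        eigenvalues_B=lamB,
    )


def _full_eigenvalues(dd: DualityDiagram) -> np.ndarray:
    k_max = min(dd.Z.shape)
    if dd.eigenvalues.size >= k_max:
        return dd.eigenvalues
    lam, _, _ = diagonalize(dd.Z, dd.row_weights, dd.col_metric)
    return lam


def unsupervised_projection(
    expr: ExpressionMatrix, motifs: MotifIncidenceTable
) -> CoinertiaResult:
    """Unsupervised CIA of an expression matrix with a motif table.

    Both tables must already be aligned to identical gene rows.  The
    expression NSC's gene weights are imposed on the motif ordination so
    the two analyses share one weighted gene space; the returned loadings
    are the sample and motif projections onto the co-inertia axes.
    """
    if expr.gene_ids != motifs.gene_ids:
        raise DataError("inputs are not gene-aligned; call align_gene_rows first")
    ddA = nsc(expr.values, row_ids=expr.gene_ids, col_ids=expr.sample_ids)
    ddB = nsc(
        motifs.counts,
        row_weights=ddA.row_weights,
        row_ids=motifs.gene_ids,
        col_ids=motifs.motif_ids,
    )
    return cia(ddA, ddB, ddA.row_weights)


def supervised_motif_ranking(
    expr: ExpressionMatrix,
    motifs: MotifIncidenceTable,
    design: SampleDesign,
    comparison: ComparisonSpec,
) -> RankedMotifList:
    """Supervised (between-group) CIA ranking motifs for one comparison.

    The expression matrix is restricted to the comparison's samples, its
    NSC columns are condensed to the two weighted group-centroid columns,
    and the condensed diagram is coupled with the motif ordination under
    the expression gene weights.  With two groups exactly one non-null
    axis remains; motifs are ranked by their signed loading on it, with
    the axis oriented so group 1's centroid loading is positive.  Ties
    break lexicographically by motif id.
    """
    g1, g2 = comparison.resolve(design)
    if not g1 or not g2:
        raise DataError(f"comparison {comparison.name}: empty group")
    sub = expr.subset_samples(g1 + g2)
    if sub.gene_ids != motifs.gene_ids:
        raise DataError("inputs are not gene-aligned; call align_gene_rows first")
    ddA = nsc(sub.values, row_ids=sub.gene_ids, col_ids=sub.sample_ids)
    labels = {s: "group1" for s in g1}
    labels.update({s: "group2" for s in g2})
    ddA_cond, group_order = condense_columns(ddA, labels)
    ddB = nsc(
        motifs.counts,
        row_weights=ddA.row_weights,
        row_ids=motifs.gene_ids,
        col_ids=motifs.motif_ids,
    )
    result = cia(ddA_cond, ddB, ddA.row_weights)
    i1 = group_order.index("group1")
    if result.array_loadings[i1, 0] < 0:
        result.array_loadings[:, 0] *= -1
        result.motif_loadings[:, 0] *= -1
        result.gene_scores_A[:, 0] *= -1
        result.gene_scores_B[:, 0] *= -1
    scores = result.motif_loadings[:, 0]
    order = sorted(
        range(len(motifs.motif_ids)),
        key=lambda j: (-scores[j], motifs.motif_ids[j]),
    )
    return RankedMotifList(
        comparison=comparison.name,
        threshold_label=motifs.threshold_label,
        motif_ids=[motifs.motif_ids[j] for j in order],
        scores=scores[order],
        coinertia=result,
    )


class CoInertiaAnalysis(BaseEstimator):
    """Sklearn-style co-inertia analysis of two nonnegative gene tables.

    ``fit(X, Y)`` runs NSC on both tables (rows = shared genes, X's row
    weights imposed on Y) and couples them.

    Attributes (after fit)
    ----------------------
    singular_values_ : nonincreasing axis covariances
    x_loadings_, y_loadings_ : column loadings of X and Y
    x_scores_, y_scores_ : gene co-scores from each table
    rv_ : RV coefficient in [0, 1]
    total_coinertia_ : sum of squared singular values
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, Y=None, y=None):
        if Y is None:
            Y = y
        if Y is None:
            raise DataError("CoInertiaAnalysis.fit requires two tables")
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise DataError("X and Y must share their gene rows")
        ddA = nsc(X)
        ddB = nsc(Y, row_weights=ddA.row_weights)
        res = cia(ddA, ddB, ddA.row_weights, n_components=self.n_components)
        self.result_ = res
        self.singular_values_ = res.singular_values
        self.x_loadings_ = res.array_loadings
        self.y_loadings_ = res.motif_loadings
        self.x_scores_ = res.gene_scores_A
        self.y_scores_ = res.gene_scores_B
        self.rv_ = res.rv
        self.total_coinertia_ = res.total_coinertia
        return self

    def score(self, X=None, Y=None) -> float:
        """Global co-structure of the fitted pair (the RV coefficient)."""
        if not hasattr(self, "rv_"):
            raise DataError("estimator is not fitted")
        return self.rv_
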