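"""Quantile normalization of expression matrices.

Forces every column (array) of a matrix onto the identical empirical
distribution: the reference distribution is the row-wise mean of the
column-sorted matrix, and tied values within a column receive the mean of
the reference values at their tied positions.
"""

from __future__ import annotations

import numpy as np

from .data import ExpressionMatrix
from .exceptions import DataError


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of ``values``.

    Parameters
    ----------
    values
        Real matrix with no missing values and at least one column.

    Returns
    -------
    A new matrix in which every column has the same sorted value multiset
    (the mean across columns of each sorted position).  Ties within a
    column are assigned the average of the tied reference values, which
    makes the transform idempotent.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise DataError("quantile_normalize requires a non-empty 2-D matrix")
    if not np.all(np.isfinite(values)):
        raise DataError("quantile_normalize requires finite values")
    n, m = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        # tie-group index per sorted position
        grp = np.cumsum(np.r_[True, sorted_col[1:] != sorted_col[:-1]]) - 1
        sums = np.bincount(grp, weights=reference)
        counts = np.bincount(grp)
        out[order, j] = (sums / counts)[grp]
    return out


def quantile_normalize_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize an :class:`ExpressionMatrix` across its arrays."""
    return ExpressionMatrix(
        expr.gene_ids, expr.sample_ids, quantile_normalize(expr.values)
    )
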