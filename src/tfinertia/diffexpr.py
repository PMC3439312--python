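"""Two-group moderated-t differential expression with empirical Bayes.

Per gene the two-group contrast yields a log2 fold change, a pooled
within-group variance ``s_g^2`` on ``d_g = n1 + n2 - 2`` degrees of
freedom.  An inverse-chi-square prior with ``d0`` degrees of freedom and
scale ``s0^2`` is estimated from the whole variance population by the
method of moments on ``log s^2`` (digamma/trigamma matching), giving the
posterior variance ``(d0 s0^2 + d_g s_g^2) / (d0 + d_g)`` and a moderated
t on ``d0 + d_g`` degrees of freedom.  This shrinkage stabilizes the
per-gene variance when replication is small.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data import ComparisonSpec, ExpressionMatrix, SampleDesign
from .exceptions import DataError, NumericalError


@dataclass
class ModerationParams:
    """Empirical-Bayes variance prior: ``d0`` df and scale ``s0^2``.

    ``d0 = inf`` means complete shrinkage to the common variance; ``d0 = 0``
    means no moderation at all.
    """

    d0: float
    s02: float

    def posterior_variance(self, s2: np.ndarray, dg: np.ndarray) -> np.ndarray:
        s2 = np.asarray(s2, dtype=float)
        dg = np.asarray(dg, dtype=float)
        if np.isinf(self.d0):
            return np.full_like(s2, self.s02)
        if self.d0 == 0:
            return s2.copy()
        return (self.d0 * self.s02 + dg * s2) / (self.d0 + dg)


def fit_two_group(
    expr: ExpressionMatrix,
    design: SampleDesign,
    comparison: ComparisonSpec,
) -> pd.DataFrame:
    """Per-gene two-group summary statistics for one comparison.

    Returns a frame indexed by gene with columns ``logFC`` (group1 mean
    minus group2 mean on the log2 scale), ``s2`` (pooled within-group
    variance), ``df`` (n1 + n2 - 2), plus the group sizes as attributes
    ``n1``/``n2`` in ``frame.attrs``.
    """
    g1, g2 = comparison.resolve(design)
    return fit_two_group_arrays(expr, g1, g2)


def fit_two_group_arrays(
    expr: ExpressionMatrix, group1: Sequence[str], group2: Sequence[str]
) -> pd.DataFrame:
    n1, n2 = len(group1), len(group2)
    if n1 < 2 or n2 < 2:
        raise DataError(
            f"each group needs >= 2 samples (got {n1} and {n2})"
        )
    x1 = expr.subset_samples(list(group1)).values
    x2 = expr.subset_samples(list(group2)).values
    logfc = x1.mean(axis=1) - x2.mean(axis=1)
    ss1 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = (ss1 + ss2) / df
    frame = pd.DataFrame(
        {"logFC": logfc, "s2": s2, "df": float(df)}, index=expr.gene_ids
    )
    frame.attrs["n1"] = n1
    frame.attrs["n2"] = n2
    return frame


def _trigamma_inverse(y: float) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 by Newton iteration."""
    if y <= 0:
        raise NumericalError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_prior(s2: np.ndarray, dg: float | np.ndarray) -> ModerationParams:
    """Method-of-moments fit of the variance prior from all genes.

    Matches the mean and variance of ``log s^2`` (corrected by the
    digamma/trigamma moments of a scaled chi-square on ``dg`` df) to a
    scaled inverse chi-square prior.  A non-positive excess variance means
    the per-gene variances are exhaustively explained by sampling noise,
    in which case ``d0 = inf`` (full shrinkage to the common variance).
    """
    s2 = np.asarray(s2, dtype=float)
    n = s2.size
    if n < 10:
        raise DataError("prior estimation needs >= 10 genes")
    if np.any(s2 < 0):
        raise DataError("variances must be nonnegative")
    if np.all(s2 == 0):
        raise DataError("all variances are zero; degenerate input")
    dg = np.broadcast_to(np.asarray(dg, dtype=float), s2.shape)
    # zero variances are offset away from zero, mirroring the standard
    # moments estimator's handling
    x = np.maximum(s2, 1e-5 * np.median(s2))
    z = np.log(x)
    e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    emean = float(e.mean())
    evar = float(((e - emean) ** 2).sum() / (e.size - 1))
    evar -= float(np.mean(special.polygamma(1, dg / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = math.exp(
            emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    else:
        d0 = math.inf
        s02 = float(np.mean(x))
    return ModerationParams(d0=d0, s02=s02)


def moderate(
    logfc: np.ndarray,
    s2: np.ndarray,
    dg: float | np.ndarray,
    n1: int,
    n2: int,
    d0: float | None = None,
    s02: float | None = None,
) -> tuple[ModerationParams, np.ndarray, np.ndarray]:
    """Moderated t-statistics and two-sided p-values for a two-group fit.

    The prior is estimated from the data unless ``d0`` (and optionally
    ``s02``) are forced; ``d0 = 0`` reproduces the ordinary two-sample t.
    """
    logfc = np.asarray(logfc, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    dg_arr = np.broadcast_to(np.asarray(dg, dtype=float), s2.shape)
    if d0 is None:
        params = estimate_prior(s2, dg_arr)
    else:
        if s02 is None:
            s02 = estimate_prior(s2, dg_arr).s02 if d0 != 0 else 1.0
        params = ModerationParams(d0=float(d0), s02=float(s02))
    s2_post = params.posterior_variance(s2, dg_arr)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    df_total = params.d0 + dg_arr
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return params, t, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    expr: ExpressionMatrix,
    design: SampleDesign,
    comparison: ComparisonSpec,
    d0: float | None = None,
) -> pd.DataFrame:
    """Full moderated-t analysis of one comparison.

    Returns a frame indexed by gene with columns ``logFC, s2, df, t, p,
    adj_p`` (BH-adjusted); the fitted prior is stored in
    ``frame.attrs["prior"]``.
    """
    fit = fit_two_group(expr, design, comparison)
    params, t, p = moderate(
        fit["logFC"].to_numpy(),
        fit["s2"].to_numpy(),
        fit["df"].to_numpy(),
        fit.attrs["n1"],
        fit.attrs["n2"],
        d0=d0,
    )
    out = fit.copy()
    out["t"] = t
    out["p"] = p
    out["adj_p"] = bh_adjust(p)
    out.attrs["prior"] = params
    out.attrs["comparison"] = comparison.name
    return out


def significant_genes(
    de: pd.DataFrame, fc_min: float = 1.3, alpha: float = 0.05
) -> dict[str, int]:
    """Signed significant gene set at the fold-change/FDR thresholds.

    A gene passes with ``2^|logFC| >= fc_min`` and ``adj_p <= alpha``
    (both boundaries inclusive) and is tagged +1 (up) or -1 (down) by the
    sign of its log fold change.
    """
    if fc_min <= 0 or alpha <= 0:
        raise DataError("thresholds must be positive")
    logfc = de["logFC"].to_numpy()
    adj = de["adj_p"].to_numpy()
    passing = (2.0 ** np.abs(logfc) >= fc_min) & (adj <= alpha)
    return {
        gene: (1 if lf > 0 else -1)
        for gene, lf, ok in zip(de.index, logfc, passing)
        if ok and lf != 0
    }


def consensus_gene_list(
    signed_sets: Sequence[Mapping[str, int]],
    min_support: int | None = None,
) -> pd.DataFrame:
    """Genes significant with one consistent direction across comparisons.

    A gene qualifies when it is significant with the *same* direction in
    at least ``min_support`` comparisons (default: all of them); any gene
    significant in both directions anywhere is excluded outright.
    Returns a frame (gene, direction, support) ordered by support
    descending then gene id.
    """
    if len(signed_sets) < 1:
        raise DataError("need at least one signed gene set")
    if min_support is None:
        min_support = len(signed_sets)
    up: dict[str, int] = {}
    down: dict[str, int] = {}
    for s in signed_sets:
        for gene, direction in s.items():
            if direction > 0:
                up[gene] = up.get(gene, 0) + 1
            else:
                down[gene] = down.get(gene, 0) + 1
    rows = []
    for gene in sorted(set(up) | set(down)):
        if gene in up and gene in down:
            continue  # direction conflict
        direction = 1 if gene in up else -1
        support = up.get(gene, 0) + down.get(gene, 0)
        if support >= min_support:
            rows.append({"gene": gene, "direction": direction, "support": support})
    frame = pd.DataFrame(rows, columns=["gene", "direction", "support"])
    return frame.sort_values(
        ["support", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
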