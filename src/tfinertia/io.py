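"""Readers and writers for the package's plain-text interchange formats.

Matrices travel as TSV: first column = gene id, header row = sample or
motif ids, UTF-8, '.' decimal.  Designs and qPCR/dose-response tables are
CSV with headers.  Ordination and co-inertia results serialize as a
directory of TSVs plus a small JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, MotifIncidenceTable
from .exceptions import DataError


def read_expression_tsv(path) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        [str(g) for g in frame.index],
        [str(s) for s in frame.columns],
        frame.to_numpy(dtype=float),
    )


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_motif_tsv(path, threshold_label: str) -> MotifIncidenceTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    counts = frame.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise DataError(f"{path}: motif table must be numeric")
    return MotifIncidenceTable(
        [str(g) for g in frame.index],
        [str(m) for m in frame.columns],
        counts.astype(int),
        threshold_label,
    )


def write_motif_tsv(motifs: MotifIncidenceTable, path) -> None:
    motifs.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def write_ordination(result, out_dir) -> None:
    """Serialize a DualityDiagram or CoinertiaResult to a directory of TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"type": type(result).__name__}
    if hasattr(result, "eigenvalues"):  # DualityDiagram
        pd.Series(result.eigenvalues, name="eigenvalue").to_csv(
            out / "eigenvalues.tsv", sep="\t", index_label="axis"
        )
        pd.DataFrame(result.col_axes, index=result.col_ids).to_csv(
            out / "col_axes.tsv", sep="\t", index_label="col_id"
        )
        pd.DataFrame(result.row_scores, index=result.row_ids).to_csv(
            out / "row_scores.tsv", sep="\t", index_label="row_id"
        )
        manifest["total_inertia"] = float(result.total_inertia)
        manifest["row_weights"] = [float(x) for x in result.row_weights]
        manifest["col_metric"] = [float(x) for x in result.col_metric]
    else:  # CoinertiaResult
        pd.Series(result.singular_values, name="singular_value").to_csv(
            out / "singular_values.tsv", sep="\t", index_label="axis"
        )
        pd.DataFrame(result.array_loadings, index=result.array_ids).to_csv(
            out / "array_loadings.tsv", sep="\t", index_label="array_id"
        )
        pd.DataFrame(result.motif_loadings, index=result.motif_ids).to_csv(
            out / "motif_loadings.tsv", sep="\t", index_label="motif_id"
        )
        pd.DataFrame(result.gene_scores_A, index=result.gene_ids).to_csv(
            out / "gene_scores_A.tsv", sep="\t", index_label="gene_id"
        )
        pd.DataFrame(result.gene_scores_B, index=result.gene_ids).to_csv(
            out / "gene_scores_B.tsv", sep="\t", index_label="gene_id"
        )
        manifest["rv"] = float(result.rv)
        manifest["total_coinertia"] = float(result.total_coinertia)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def write_ranked_motifs(ranked, path) -> None:
    """Write a RankedMotifList as TSV (rank, motif_id, score, comparison, threshold)."""
    frame = pd.DataFrame(
        {
            "rank": np.arange(1, len(ranked.motif_ids) + 1),
            "motif_id": ranked.motif_ids,
            "score": ranked.scores,
            "comparison": ranked.comparison,
            "threshold": ranked.threshold_label,
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_ranked_motifs(path):
    from .coinertia import RankedMotifList

    frame = pd.read_csv(path, sep="\t")
    return RankedMotifList(
        comparison=str(frame["comparison"].iloc[0]),
        threshold_label=str(frame["threshold"].iloc[0]),
        motif_ids=[str(m) for m in frame["motif_id"]],
        scores=frame["score"].to_numpy(dtype=float),
    )
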