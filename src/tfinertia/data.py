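"""Core data model: sample designs, expression matrices, motif tables.

The pipeline couples two tables measured on the same genes: a log2
expression matrix (genes x arrays) with an accompanying sample design, and
one or more gene x motif binding-site incidence tables, each produced at a
labelled PSSM score threshold.  Everything downstream (ordination,
co-inertia, differential expression) consumes these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError

VEHICLE = "vehicle"
DRUG = "drug"

DESIGN_COLUMNS = [
    "sample_id",
    "cell_line",
    "treatment",
    "dose_uM",
    "timepoint_hr",
    "replicate",
]


def _format_dose(dose: float) -> str:
    return f"{dose:g}"


@dataclass
class SampleDesign:
    """Sample annotation table for an array experiment.

    One row per array with columns ``sample_id, cell_line, treatment,
    dose_uM, timepoint_hr, replicate``.  ``dose_uM`` is zero exactly for
    vehicle-treated (control) samples.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"design table missing columns: {missing}")
        self.table = self.table.loc[:, DESIGN_COLUMNS].reset_index(drop=True)
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise DataError(f"duplicate sample_ids: {dupes}")
        vehicle = self.table["treatment"] == VEHICLE
        zero_dose = self.table["dose_uM"] == 0
        if (vehicle != zero_dose).any():
            bad = self.table.loc[vehicle != zero_dose, "sample_id"].tolist()
            raise DataError(
                f"dose must be 0 exactly for vehicle samples; violated by {bad}"
            )
        if (self.table["replicate"] < 1).any():
            raise DataError("replicate numbers must be positive integers")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def subset(self, sample_ids: Sequence[str]) -> "SampleDesign":
        keep = self.table["sample_id"].isin(set(sample_ids))
        return SampleDesign(self.table.loc[keep].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleDesign":
        return cls(pd.read_csv(path))


def enumerate_design(
    arms: Sequence[tuple[str, str, float, Sequence[float], int]],
) -> SampleDesign:
    """Expand experimental arms into a full sample design.

    Each arm is ``(cell_line, treatment, dose_uM, timepoints, n_replicates)``
    and contributes one sample per (timepoint, replicate).  Rows are ordered
    deterministically by (cell_line, treatment, dose, timepoint, replicate).

    Raises
    ------
    DataError
        If two arms declare the same (cell_line, treatment, dose, timepoint)
        cell.
    """
    seen: set[tuple] = set()
    rows = []
    for cell_line, treatment, dose, timepoints, n_replicates in arms:
        if n_replicates < 0:
            raise DataError("n_replicates must be >= 0")
        for tp in timepoints:
            cell = (cell_line, treatment, float(dose), float(tp))
            if cell in seen:
                raise DataError(f"duplicate arm cell: {cell}")
            seen.add(cell)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "cell_line": cell_line,
                        "treatment": treatment,
                        "dose_uM": float(dose),
                        "timepoint_hr": float(tp),
                        "replicate": rep,
                    }
                )
    frame = pd.DataFrame(
        rows, columns=[c for c in DESIGN_COLUMNS if c != "sample_id"]
    )
    frame = frame.sort_values(
        ["cell_line", "treatment", "dose_uM", "timepoint_hr", "replicate"],
        kind="mergesort",
    ).reset_index(drop=True)
    frame.insert(
        0,
        "sample_id",
        [
            f"{r.cell_line}.{r.treatment}.{_format_dose(r.dose_uM)}uM."
            f"{_format_dose(r.timepoint_hr)}h.r{r.replicate}"
            for r in frame.itertuples()
        ],
    )
    return SampleDesign(frame)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 intensities."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("gene_ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("sample_ids must be unique")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise DataError(f"unknown sample_ids: {missing}")
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(
            self.gene_ids, list(sample_ids), self.values[:, cols]
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), self.sample_ids, self.values[rows, :]
        )


@dataclass
class MotifIncidenceTable:
    """Genes x motifs table of nonnegative binding-site hit counts.

    ``threshold_label`` records the PSSM score cutoff at which the table was
    scanned; stricter cutoffs give sparser (nested) tables.
    """

    gene_ids: list[str]
    motif_ids: list[str]
    counts: np.ndarray
    threshold_label: str

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.motif_ids = list(self.motif_ids)
        self.counts = np.asarray(self.counts)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("gene_ids must be unique")
        if len(set(self.motif_ids)) != len(self.motif_ids):
            raise DataError("motif_ids must be unique")
        if self.counts.shape != (len(self.gene_ids), len(self.motif_ids)):
            raise DataError("counts shape inconsistent with ids")
        if np.any(self.counts < 0):
            raise DataError("counts must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.gene_ids, columns=self.motif_ids
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "MotifIncidenceTable":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return MotifIncidenceTable(
            list(gene_ids),
            self.motif_ids,
            self.counts[rows, :],
            self.threshold_label,
        )

    def targets(self, motif_id: str) -> set[str]:
        """Genes with at least one predicted site for ``motif_id``."""
        j = self.motif_ids.index(motif_id)
        hits = np.asarray(self.counts[:, j]) > 0
        return {g for g, h in zip(self.gene_ids, hits) if h}


@dataclass(frozen=True)
class ComparisonSpec:
    """A two-group contrast over cells of the sample design.

    Each group is a set of (treatment, dose_uM, timepoint_hr) cells within
    one cell line; groups must be disjoint and every declared cell must
    match at least one sample when resolved against a design.
    """

    name: str
    cell_line: str
    group1: frozenset[tuple[str, float, float]]
    group2: frozenset[tuple[str, float, float]]

    def __post_init__(self) -> None:
        overlap = self.group1 & self.group2
        if overlap:
            raise DataError(
                f"comparison {self.name}: groups overlap in cells {sorted(overlap)}"
            )
        if not self.group1 or not self.group2:
            raise DataError(f"comparison {self.name}: empty group")

    def resolve(self, design: SampleDesign) -> tuple[list[str], list[str]]:
        """Map each group's cells to sample ids in design order."""
        out = []
        for label, cells in (("group1", self.group1), ("group2", self.group2)):
            tbl = design.table
            in_line = tbl["cell_line"] == self.cell_line
            mask = np.zeros(len(tbl), dtype=bool)
            for treatment, dose, tp in cells:
                cell_mask = (
                    in_line
                    & (tbl["treatment"] == treatment)
                    & (tbl["dose_uM"] == float(dose))
                    & (tbl["timepoint_hr"] == float(tp))
                )
                if not cell_mask.any():
                    raise DataError(
                        f"comparison {self.name} {label}: cell "
                        f"({treatment}, {dose}, {tp}) matches no sample"
                    )
                mask |= np.asarray(cell_mask)
            out.append(tbl.loc[mask, "sample_id"].tolist())
        return out[0], out[1]


def align_gene_rows(
    expr: ExpressionMatrix, motifs: MotifIncidenceTable
) -> tuple[ExpressionMatrix, MotifIncidenceTable]:
    """Restrict both tables to their shared genes, in expression row order.

    Promoter scans never cover every array probe, so the coupled analyses
    run on the gene-id intersection.  The expression matrix's relative row
    order is preserved and imposed on the motif table.
    """
    motif_genes = set(motifs.gene_ids)
    shared = [g for g in expr.gene_ids if g in motif_genes]
    if not shared:
        raise DataError("gene-id intersection of the two tables is empty")
    if shared == expr.gene_ids and shared == motifs.gene_ids:
        return expr, motifs
    return expr.subset_genes(shared), motifs.subset_genes(shared)


def collapse_probes(
    expr: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probe-level rows to gene level, keeping the brightest probe.

    For each gene with several mapped probes, the probe with the maximum
    mean intensity represents the gene.  Probes absent from the map keep
    their original identifier.
    """
    means = expr.values.mean(axis=1)
    best: dict[str, tuple[float, int]] = {}
    order: list[str] = []
    for i, probe in enumerate(expr.gene_ids):
        gene = probe_to_gene.get(probe, probe)
        if gene not in best:
            order.append(gene)
            best[gene] = (means[i], i)
        elif means[i] > best[gene][0]:
            best[gene] = (means[i], i)
    rows = [best[g][1] for g in order]
    return ExpressionMatrix(order, expr.sample_ids, expr.values[rows, :])
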