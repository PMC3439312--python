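"""End-to-end orchestration of the coupled-table analysis.

Runs, in order: gene alignment (and optional quantile normalization),
unsupervised co-inertia projections per cell line, supervised motif
rankings per comparison x PSSM threshold, rank-product combination across
thresholds, top-K consensus across comparisons, per-comparison moderated-t
differential expression, the cross-comparison consensus gene list, motif
target enrichment of that list, and -- when qPCR / dose-response inputs
are supplied -- relative quantification, dysregulation calls, IC50 fits
and the sensitivity concordance.  Every stage writes its table under the
output directory, so any downstream stage can be re-run from disk.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import study
from .coinertia import supervised_motif_ranking, unsupervised_projection
from .data import ComparisonSpec, SampleDesign, align_gene_rows
from .diffexpr import consensus_gene_list, differential_expression, significant_genes
from .enrichment import motif_enrichment_table
from .exceptions import ConfigError, DataError
from .io import (
    read_expression_tsv,
    read_motif_tsv,
    write_ordination,
    write_ranked_motifs,
)
from .pheno import (
    add_calls,
    ic50_per_cell_line,
    percent_survival,
    relative_quantification,
    sensitivity_concordance,
)
from .preprocess import quantile_normalize_expression
from .rankagg import consensus_top, rank_products

log = logging.getLogger("tfinertia")


@dataclass
class PipelineConfig:
    """Paths and thresholds of a full pipeline run."""

    expression: str
    design: str
    motifs: dict[str, str]  # threshold label -> TSV path
    out_dir: str
    ct: str | None = None
    dose_response: str | None = None
    comparisons: list[ComparisonSpec] | None = None
    quantile_normalize: bool = False
    fc_min: float = 1.3
    alpha: float = 0.05
    rq_fold: float = 2.0
    top_k: int = 10
    min_support: int | None = None
    de_min_support: int | None = None
    enrichment_threshold: str = "0.8"
    reference_gene: str = "GAPDH"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("fc_min", self.fc_min),
            ("alpha", self.alpha),
            ("rq_fold", self.rq_fold),
            ("top_k", self.top_k),
        ):
            if value <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.enrichment_threshold not in self.motifs:
            raise ConfigError(
                f"enrichment_threshold {self.enrichment_threshold!r} has no "
                f"motif table (have {sorted(self.motifs)})"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        comparisons = None
        if "comparisons" in raw:
            comparisons = [
                ComparisonSpec(
                    name=str(c["name"]),
                    cell_line=str(c["cell_line"]),
                    group1=frozenset(
                        (str(t), float(d), float(tp)) for t, d, tp in c["group1"]
                    ),
                    group2=frozenset(
                        (str(t), float(d), float(tp)) for t, d, tp in c["group2"]
                    ),
                )
                for c in raw.pop("comparisons")
            ]
        try:
            cfg = cls(comparisons=comparisons, **raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
        return cfg

    def input_paths(self) -> list[str]:
        paths = [self.expression, self.design, *self.motifs.values()]
        if self.ct:
            paths.append(self.ct)
        if self.dose_response:
            paths.append(self.dose_response)
        return paths


def _stage(name: str, t0: float, detail: str, output=None) -> None:
    log.info(
        "stage=%s elapsed=%.2fs %s%s",
        name,
        time.perf_counter() - t0,
        detail,
        f" out={output}" if output else "",
    )


def run_full(config: PipelineConfig) -> dict:
    """Execute the complete analysis; returns the summary dictionary."""
    missing = [p for p in config.input_paths() if not Path(p).exists()]
    if missing:
        raise ConfigError(f"missing input files: {missing}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run start seed=%d out=%s", config.seed, out)
    summary: dict = {"seed": config.seed}

    t0 = time.perf_counter()
    expr = read_expression_tsv(config.expression)
    design = SampleDesign.from_csv(config.design)
    motif_tables = {
        label: read_motif_tsv(path, label)
        for label, path in sorted(config.motifs.items())
    }
    if set(expr.sample_ids) != set(design.sample_ids):
        raise DataError("expression samples do not match the design table")
    _stage("load", t0, f"expr={expr.shape} tables={len(motif_tables)}")

    if config.quantile_normalize:
        t0 = time.perf_counter()
        expr = quantile_normalize_expression(expr)
        _stage("quantile_normalize", t0, f"expr={expr.shape}")

    t0 = time.perf_counter()
    shared = set(expr.gene_ids)
    for t in motif_tables.values():
        shared &= set(t.gene_ids)
    if not shared:
        raise DataError("no genes shared by expression and all motif tables")
    ref = motif_tables[config.enrichment_threshold]
    expr, ref_aligned = align_gene_rows(
        expr.subset_genes([g for g in expr.gene_ids if g in shared]), ref
    )
    motif_tables = {
        label: t.subset_genes(expr.gene_ids) for label, t in motif_tables.items()
    }
    _stage("align", t0, f"genes={len(expr.gene_ids)}")

    comparisons = (
        config.comparisons
        if config.comparisons is not None
        else study.study_comparisons()
    )

    # unsupervised projections per cell line at the reference threshold
    t0 = time.perf_counter()
    for line in sorted(set(design.table["cell_line"])):
        ids = design.table.loc[
            design.table["cell_line"] == line, "sample_id"
        ].tolist()
        res = unsupervised_projection(
            expr.subset_samples(ids), motif_tables[config.enrichment_threshold]
        )
        write_ordination(res, out / f"unsupervised_{line}")
    _stage("unsupervised", t0, f"cell_lines={len(set(design.table['cell_line']))}",
           out / "unsupervised_*")

    # supervised rankings per comparison x threshold
    t0 = time.perf_counter()
    rankings_by_comparison: dict[str, list] = {}
    for comp in comparisons:
        per_threshold = []
        for label, table in motif_tables.items():
            ranked = supervised_motif_ranking(expr, table, design, comp)
            write_ranked_motifs(
                ranked, out / f"ranked_{comp.name}_thr{label}.tsv"
            )
            per_threshold.append(ranked)
        rankings_by_comparison[comp.name] = per_threshold
    _stage(
        "supervise",
        t0,
        f"comparisons={len(comparisons)} thresholds={len(motif_tables)}",
    )

    # rank products across thresholds, then consensus across comparisons
    t0 = time.perf_counter()
    combined: dict[str, list[str]] = {}
    for name, ranked_lists in rankings_by_comparison.items():
        rp = rank_products([r.motif_ids for r in ranked_lists])
        rp.to_frame().to_csv(
            out / f"rankproduct_{name}.tsv", sep="\t", index_label="motif_id"
        )
        combined[name] = rp.combined_order
    consensus_tfs = consensus_top(
        combined, top_k=config.top_k, min_support=config.min_support
    )
    consensus_tfs.to_csv(out / "consensus_tfs.tsv", sep="\t", index=False)
    summary["consensus_motifs"] = consensus_tfs["motif_id"].tolist()
    _stage("rankprod", t0, f"consensus={len(consensus_tfs)}",
           out / "consensus_tfs.tsv")

    # differential expression per comparison and consensus gene list
    t0 = time.perf_counter()
    signed_sets = []
    for comp in comparisons:
        de = differential_expression(expr, design, comp)
        de.to_csv(out / f"de_{comp.name}.tsv", sep="\t", index_label="gene")
        signed_sets.append(
            significant_genes(de, fc_min=config.fc_min, alpha=config.alpha)
        )
    consensus_genes = consensus_gene_list(
        signed_sets, min_support=config.de_min_support
    )
    consensus_genes.to_csv(out / "consensus_genes.tsv", sep="\t", index=False)
    summary["n_consensus_genes"] = int(len(consensus_genes))
    _stage("diffexpr", t0, f"consensus_genes={len(consensus_genes)}",
           out / "consensus_genes.tsv")

    # motif enrichment of the consensus list against the aligned background
    t0 = time.perf_counter()
    enrich = motif_enrichment_table(
        set(consensus_genes["gene"]),
        set(expr.gene_ids),
        motif_tables[config.enrichment_threshold],
    )
    enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    summary["top_enriched_motif"] = (
        str(enrich["motif_id"].iloc[0]) if len(enrich) else None
    )
    _stage("enrichment", t0, f"motifs={len(enrich)}", out / "enrichment.tsv")

    # phenotype block: IC50s first, then qPCR concordance against them
    ic50s = None
    if config.dose_response:
        t0 = time.perf_counter()
        curve = pd.read_csv(config.dose_response)
        surv = percent_survival(curve)
        surv.to_csv(out / "percent_survival.tsv", sep="\t", index=False)
        ic50s = ic50_per_cell_line(surv)
        ic50s.to_csv(out / "ic50.tsv", sep="\t", index=False)
        summary["ic50_uM"] = dict(
            zip(ic50s["cell_line"], (float(v) for v in ic50s["ic50_uM"]))
        )
        _stage("ic50", t0, f"cell_lines={len(ic50s)}", out / "ic50.tsv")

    if config.ct:
        t0 = time.perf_counter()
        ct = pd.read_csv(config.ct)
        rq = add_calls(
            relative_quantification(ct, config.reference_gene),
            fold_threshold=config.rq_fold,
        )
        rq.to_csv(out / "rq.tsv", sep="\t", index=False)
        if ic50s is not None:
            ic50_map = dict(zip(ic50s["cell_line"], ic50s["ic50_uM"]))
            rows = []
            for gene, sub in rq.groupby("gene", sort=True):
                log2rq = dict(zip(sub["cell_line"], sub["log2_rq"]))
                try:
                    rho, switch = sensitivity_concordance(log2rq, ic50_map)
                except DataError:
                    continue
                rows.append(
                    {"gene": gene, "spearman_rho": rho, "switch_index": switch}
                )
            concordance = pd.DataFrame(
                rows, columns=["gene", "spearman_rho", "switch_index"]
            )
            concordance.to_csv(out / "concordance.tsv", sep="\t", index=False)
            summary["concordance"] = rows
        _stage("qpcr", t0, f"rows={len(rq)}", out / "rq.tsv")

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    _write_report(out, summary, config)
    log.info("run complete out=%s", out)
    return summary


def _write_report(out: Path, summary: dict, config: PipelineConfig) -> None:
    lines = [
        "# Pipeline report",
        "",
        f"- seed: {config.seed}",
        f"- fold-change threshold: {config.fc_min}",
        f"- FDR threshold: {config.alpha}",
        f"- consensus: top_k={config.top_k}, "
        f"min_support={config.min_support or 'all'}",
        f"- consensus motifs: {', '.join(summary.get('consensus_motifs', [])) or 'none'}",
        f"- consensus genes: {summary.get('n_consensus_genes', 0)}",
    ]
    if "ic50_uM" in summary:
        lines.append("- IC50 (uM): " + ", ".join(
            f"{k}={v:.3g}" for k, v in summary["ic50_uM"].items()
        ))
    with open(out / "report.md", "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
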