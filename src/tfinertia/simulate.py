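"""Seeded generators for every input the pipeline consumes.

Each generator plants known structure -- driver motifs whose targets
shift in the responding samples, a sensitivity-graded qPCR fold-change
pattern, and dose-response curves with known IC50s -- and records it in a
truth dictionary so every pipeline stage can be scored without re-deriving
the ground truth.  All generators are pure functions of the configuration
(including its seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import study
from .data import DRUG, ExpressionMatrix, MotifIncidenceTable, SampleDesign
from .exceptions import ConfigError
from .io import write_expression_tsv, write_motif_tsv

#: planted IC50s (uM) per cell line, most to least drug-sensitive
DEFAULT_IC50S = {
    "BT474": 0.036,
    "SKBR3": 0.080,
    "EFM192A": 0.193,
    "HCC1954": 0.416,
    "MDAMB453": 6.08,
    "MDAMB231": 7.46,
}

#: planted treated-vs-control log2 fold change per cell line (same order as
#: DEFAULT_IC50S): graded with sensitivity and switching sign in the two
#: insensitive lines
DEFAULT_QPCR_LOG2FC = (3.0, 2.2, 1.4, 0.8, -1.2, -2.0)

DEFAULT_QPCR_GENES = ("RESP1", "RESP2", "RESP3", "RESP4", "RESP5")
#: per-gene multiplier on the shared fold-change pattern
DEFAULT_QPCR_GENE_SCALE = (1.0, 0.85, 1.15, 0.75, 1.25)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the reference conditions as
    defaults: a 96-array two-cell-line design, 2000 genes x 100 motifs at
    four nested PSSM thresholds, five driver motifs with a 1.5 log2-unit
    effect, and six phenotyped cell lines."""

    seed: int = 0
    n_genes: int = 2000
    n_motifs: int = 100
    pssm_thresholds: tuple[float, ...] = (0.7, 0.75, 0.8, 0.85)
    reference_threshold: str = "0.8"
    target_density: float = 0.10
    threshold_retention: float = 0.7
    n_driver_motifs: int = 5
    delta: float = 1.5
    noise_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    cell_lines: tuple[str, ...] = study.CELL_LINES
    n_replicates: int = study.N_REPLICATES
    sensitivity_profile: dict = field(
        default_factory=lambda: dict(study.SENSITIVITY_PROFILE)
    )
    # qPCR block
    qpcr_genes: tuple[str, ...] = DEFAULT_QPCR_GENES
    qpcr_gene_scale: tuple[float, ...] = DEFAULT_QPCR_GENE_SCALE
    qpcr_log2fc: tuple[float, ...] = DEFAULT_QPCR_LOG2FC
    qpcr_cell_lines: tuple[str, ...] = tuple(DEFAULT_IC50S)
    qpcr_replicates: int = 3
    ct_noise_sd: float = 0.15
    reference_ct: float = 20.0
    basal_offset: float = 5.0
    reference_gene: str = "GAPDH"
    # dose-response block
    planted_ic50: dict = field(default_factory=lambda: dict(DEFAULT_IC50S))
    hill: float = 1.2
    dr_noise_pct: float = 3.0
    dr_replicates: int = 3
    blank_a405: float = 0.05
    a620: float = 0.02
    signal_amplitude: float = 1.0

    def __post_init__(self) -> None:
        thr = self.pssm_thresholds
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise ConfigError("pssm_thresholds must be strictly increasing")
        if not 0 < self.target_density < 1:
            raise ConfigError("target_density must lie in (0, 1)")
        if not 0 < self.threshold_retention <= 1:
            raise ConfigError("threshold_retention must lie in (0, 1]")
        if self.n_driver_motifs > self.n_motifs:
            raise ConfigError("n_driver_motifs exceeds n_motifs")
        if any(v <= 0 for v in self.planted_ic50.values()):
            raise ConfigError("planted IC50s must be positive")

    @property
    def threshold_labels(self) -> list[str]:
        return [f"{t:g}" for t in self.pssm_thresholds]

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def motif_ids(self) -> list[str]:
        width = len(str(self.n_motifs))
        return [f"M{i:0{width}d}" for i in range(1, self.n_motifs + 1)]


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, cfg.seed])


def simulate_motif_tables(cfg: SimulationConfig) -> list[MotifIncidenceTable]:
    """One gene x motif incidence table per PSSM threshold, nested.

    Hits at the base (loosest) threshold appear with ``target_density``
    per (gene, motif); each stricter threshold binomially thins the
    previous table, so a positive count at a strict threshold implies a
    positive count at every looser one.
    """
    rng = _rng(cfg, 1)
    genes, motifs = cfg.gene_ids(), cfg.motif_ids()
    hit = rng.random((cfg.n_genes, cfg.n_motifs)) < cfg.target_density
    counts = np.where(hit, 1 + rng.poisson(0.3, size=hit.shape), 0)
    tables = []
    for label in cfg.threshold_labels:
        tables.append(
            MotifIncidenceTable(genes, motifs, counts.copy(), label)
        )
        counts = rng.binomial(counts, cfg.threshold_retention)
    return tables


def driver_motifs(cfg: SimulationConfig) -> list[str]:
    """The planted driver motifs (a seeded choice among all motifs)."""
    rng = _rng(cfg, 2)
    ids = cfg.motif_ids()
    chosen = rng.choice(cfg.n_motifs, size=cfg.n_driver_motifs, replace=False)
    return sorted(ids[i] for i in chosen)


def responsive_samples(cfg: SimulationConfig, design: SampleDesign) -> list[str]:
    out = []
    for row in design.table.itertuples():
        profile = cfg.sensitivity_profile.get(row.cell_line, frozenset())
        if row.treatment == DRUG and (row.dose_uM, row.timepoint_hr) in profile:
            out.append(row.sample_id)
    return out


def simulate_expression(
    cfg: SimulationConfig, motif_tables: list[MotifIncidenceTable]
) -> tuple[ExpressionMatrix, SampleDesign, dict]:
    """Log2 expression with the driver effect planted in responding samples.

    Gene baselines are Normal(baseline_mean, baseline_sd^2); targets of
    any driver motif (at the reference threshold) gain ``delta`` log2
    units in the responding dose/time samples of each cell line; Gaussian
    noise is added everywhere.  Intensities are floored at 0.01 so the
    matrix stays a valid nonnegative ordination input.
    """
    rng = _rng(cfg, 3)
    design = study.study_design(cfg.cell_lines, cfg.n_replicates)
    genes = cfg.gene_ids()
    drivers = driver_motifs(cfg)
    ref_table = next(
        t for t in motif_tables if t.threshold_label == cfg.reference_threshold
    )
    target_genes: set[str] = set()
    for m in drivers:
        target_genes |= ref_table.targets(m)
    target_ind = np.array([g in target_genes for g in genes], dtype=float)
    resp_ids = responsive_samples(cfg, design)
    resp_ind = np.array(
        [s in set(resp_ids) for s in design.sample_ids], dtype=float
    )
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    values = (
        baseline[:, None]
        + cfg.delta * target_ind[:, None] * resp_ind[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, design.n_samples))
    )
    values = np.maximum(values, 0.01)
    expr = ExpressionMatrix(genes, design.sample_ids, values)
    truth = {
        "driver_motifs": drivers,
        "responsive_genes": sorted(target_genes),
        "responsive_samples": resp_ids,
        "delta": cfg.delta,
        "reference_threshold": cfg.reference_threshold,
    }
    return expr, design, truth


def simulate_ct_tables(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """qPCR Ct replicates with a sensitivity-graded fold-change pattern.

    The reference gene cycles around ``reference_ct``; target control Cts
    sit ``basal_offset`` cycles above it, and treated Cts are shifted by
    minus the planted log2 fold change, which declines (and crosses sign)
    across cell lines ordered by planted IC50.
    """
    rng = _rng(cfg, 4)
    lines = list(cfg.qpcr_cell_lines)
    pattern = dict(zip(lines, cfg.qpcr_log2fc))
    rows = []
    planted: dict[str, dict[str, float]] = {}
    for line in lines:
        for gene, scale in zip(cfg.qpcr_genes, cfg.qpcr_gene_scale):
            planted.setdefault(gene, {})[line] = pattern[line] * scale
        for cond in ("control", "treated"):
            for rep in range(1, cfg.qpcr_replicates + 1):
                rows.append(
                    {
                        "cell_line": line,
                        "gene": cfg.reference_gene,
                        "condition": cond,
                        "replicate": rep,
                        "ct": cfg.reference_ct
                        + rng.normal(0.0, cfg.ct_noise_sd),
                    }
                )
                for gene, scale in zip(cfg.qpcr_genes, cfg.qpcr_gene_scale):
                    shift = pattern[line] * scale if cond == "treated" else 0.0
                    rows.append(
                        {
                            "cell_line": line,
                            "gene": gene,
                            "condition": cond,
                            "replicate": rep,
                            "ct": cfg.reference_ct
                            + cfg.basal_offset
                            - shift
                            + rng.normal(0.0, cfg.ct_noise_sd),
                        }
                    )
    truth = {
        "planted_log2fc": planted,
        "planted_ic50": {c: cfg.planted_ic50[c] for c in lines},
    }
    return pd.DataFrame(rows), truth


#: concentration grid per cell line, as multiples of its planted IC50
DOSE_GRID = (0.01, 0.05, 0.2, 0.5, 1.0, 2.0, 5.0, 20.0, 100.0)


def simulate_dose_response(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Plate absorbances for 4PL dose-response curves with planted IC50s.

    Survival follows a four-parameter log-logistic curve (asymptotes
    100/0, slope ``hill``) with Gaussian noise of ``dr_noise_pct`` percent
    of the control signal; absorbance at 405 nm decomposes into blank +
    signal x survival/100, with a small constant at 620 nm.
    """
    rng = _rng(cfg, 5)
    rows = []
    for line, ic50 in cfg.planted_ic50.items():
        concs = [ic50 * f for f in DOSE_GRID]
        for rep in range(cfg.dr_replicates):
            rows.append(
                {
                    "cell_line": line,
                    "conc_uM": 0.0,
                    "a405": cfg.blank_a405,
                    "a620": cfg.a620,
                    "well_type": "blank",
                }
            )
            rows.append(
                {
                    "cell_line": line,
                    "conc_uM": 0.0,
                    "a405": cfg.blank_a405
                    + cfg.signal_amplitude
                    + rng.normal(0, cfg.dr_noise_pct / 100 * cfg.signal_amplitude),
                    "a620": cfg.a620,
                    "well_type": "control",
                }
            )
            for conc in concs:
                surv = 100.0 / (1.0 + (conc / ic50) ** cfg.hill)
                noise = rng.normal(
                    0, cfg.dr_noise_pct / 100 * cfg.signal_amplitude
                )
                rows.append(
                    {
                        "cell_line": line,
                        "conc_uM": conc,
                        "a405": cfg.blank_a405
                        + cfg.signal_amplitude * surv / 100.0
                        + noise,
                        "a620": cfg.a620,
                        "well_type": "treated",
                    }
                )
    truth = {"planted_ic50": dict(cfg.planted_ic50), "hill": cfg.hill}
    return pd.DataFrame(rows), truth


def simulate_all(cfg: SimulationConfig, out_dir) -> dict:
    """Write every synthetic input file plus ``truth.json`` to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = simulate_motif_tables(cfg)
    expr, design, truth_expr = simulate_expression(cfg, tables)
    ct, truth_ct = simulate_ct_tables(cfg)
    dr, truth_dr = simulate_dose_response(cfg)
    write_expression_tsv(expr, out / "expression.tsv")
    design.to_csv(out / "design.csv")
    motif_paths = {}
    for t in tables:
        path = out / f"motifs_{t.threshold_label}.tsv"
        write_motif_tsv(t, path)
        motif_paths[t.threshold_label] = str(path)
    ct.to_csv(out / "ct.csv", index=False)
    dr.to_csv(out / "dose_response.csv", index=False)
    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
            if not isinstance(v, dict)
        },
        "expression": truth_expr,
        "qpcr": truth_ct,
        "dose_response": truth_dr,
    }
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return {
        "expression": str(out / "expression.tsv"),
        "design": str(out / "design.csv"),
        "motifs": motif_paths,
        "ct": str(out / "ct.csv"),
        "dose_response": str(out / "dose_response.csv"),
        "truth": str(out / "truth.json"),
    }
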