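"""Overrepresentation of motif targets within a differential gene list.

Each motif's predicted targets (genes with at least one site at the
chosen PSSM threshold) are tested for enrichment in the foreground gene
list against the promoter-informed background using the one-tailed
hypergeometric (Fisher exact) upper tail: P(X >= observed overlap).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .data import MotifIncidenceTable
from .exceptions import DataError
from .diffexpr import bh_adjust


@dataclass
class EnrichmentRow:
    """One motif's 2x2 contingency counts and one-tailed p-value.

    a = foreground targets, b = foreground non-targets, c = background
    targets outside the foreground, d = remaining background.  The odds
    ratio uses a 0.5 continuity correction for reporting only; the
    p-value is exact.
    """

    motif_id: str
    a: int
    b: int
    c: int
    d: int
    p: float

    @property
    def odds_ratio(self) -> float:
        return ((self.a + 0.5) * (self.d + 0.5)) / (
            (self.b + 0.5) * (self.c + 0.5)
        )


def hypergeom_overrep(
    foreground: Collection[str],
    background: Collection[str],
    targets: Collection[str],
) -> tuple[float, tuple[int, int, int, int]]:
    """Upper-tail hypergeometric p for target overrepresentation.

    ``foreground`` must be a subset of ``background``; ``targets`` is
    intersected with the background before counting.  Returns the exact
    one-tailed p-value P(X >= a) and the 2x2 counts (a, b, c, d).
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise DataError(
            f"foreground is not a subset of background "
            f"({len(fg - bg)} genes outside)"
        )
    tg = set(targets) & bg
    a = len(fg & tg)
    b = len(fg) - a
    c = len(tg) - a
    d = len(bg) - a - b - c
    # P(X >= a) with population |bg|, successes |tg|, draws |fg|
    p = float(hypergeom.sf(a - 1, len(bg), len(tg), len(fg)))
    p = min(p, 1.0)
    return p, (a, b, c, d)


def motif_enrichment_table(
    de_genes: Collection[str],
    background_genes: Collection[str],
    motifs: MotifIncidenceTable,
) -> pd.DataFrame:
    """Per-motif target overrepresentation in a gene list.

    ``background_genes`` should be the genes with promoter information
    that are measured on the expression platform.  A gene counts as a
    target of a motif when its hit count is positive.  Rows are sorted by
    ascending p (ties by motif id); a BH-adjusted column is included for
    reference although calls are conventionally made on the raw p.
    """
    bg = set(background_genes)
    if not bg:
        raise DataError("empty background")
    rows = []
    for motif_id in motifs.motif_ids:
        p, (a, b, c, d) = hypergeom_overrep(
            de_genes, bg, motifs.targets(motif_id)
        )
        row = EnrichmentRow(motif_id, a, b, c, d, p)
        rows.append(
            {
                "motif_id": motif_id,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "p": p,
                "odds_ratio": row.odds_ratio,
            }
        )
    frame = pd.DataFrame(rows)
    frame["adj_p"] = bh_adjust(frame["p"].to_numpy())
    return frame.sort_values(["p", "motif_id"]).reset_index(drop=True)
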