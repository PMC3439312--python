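"""Canonical two-cell-line time-course layout and its six contrasts.

The reference design profiles two drug-sensitive breast cancer cell lines
(BT474 and SKBR3) over a lapatinib time course: vehicle (0.1% DMSO) at
0/2/6/12/24 h, 0.1 uM drug at 2/6/12/24 h and 1 uM drug at 2/6/12 h, in
quadruplicate -- 48 arrays per cell line, 96 in total.  The six two-group
comparisons contrast the responding dose/time cells (late high-dose in
BT474; late samples at either dose in SKBR3) against the remaining
samples of the same cell line.
"""

from __future__ import annotations

from .data import DRUG, VEHICLE, ComparisonSpec, SampleDesign, enumerate_design

CELL_LINES = ("BT474", "SKBR3")

VEHICLE_TIMEPOINTS = (0.0, 2.0, 6.0, 12.0, 24.0)
LOW_DOSE = 0.1
LOW_DOSE_TIMEPOINTS = (2.0, 6.0, 12.0, 24.0)
HIGH_DOSE = 1.0
HIGH_DOSE_TIMEPOINTS = (2.0, 6.0, 12.0)
N_REPLICATES = 4

#: dose/time cells in which each cell line mounts a transcriptional response
SENSITIVITY_PROFILE: dict[str, frozenset[tuple[float, float]]] = {
    "BT474": frozenset({(HIGH_DOSE, 6.0), (HIGH_DOSE, 12.0)}),
    "SKBR3": frozenset(
        {
            (LOW_DOSE, 6.0),
            (LOW_DOSE, 12.0),
            (HIGH_DOSE, 6.0),
            (HIGH_DOSE, 12.0),
        }
    ),
}


def study_arms(
    cell_lines=CELL_LINES, n_replicates: int = N_REPLICATES
) -> list[tuple]:
    """Arm list for :func:`~tfinertia.data.enumerate_design`."""
    arms = []
    for line in cell_lines:
        arms.append((line, VEHICLE, 0.0, VEHICLE_TIMEPOINTS, n_replicates))
        arms.append((line, DRUG, LOW_DOSE, LOW_DOSE_TIMEPOINTS, n_replicates))
        arms.append((line, DRUG, HIGH_DOSE, HIGH_DOSE_TIMEPOINTS, n_replicates))
    return arms


def study_design(
    cell_lines=CELL_LINES, n_replicates: int = N_REPLICATES
) -> SampleDesign:
    return enumerate_design(study_arms(cell_lines, n_replicates))


def _cells(treatment: str, dose: float, timepoints) -> set[tuple]:
    return {(treatment, dose, tp) for tp in timepoints}


def study_comparisons() -> list[ComparisonSpec]:
    """The six two-group contrasts of the reference design.

    Group 1 always contains the responding dose/time cells; group 2 the
    contrasted remainder.  Per-comparison sample totals with 4 replicates
    are 48, 16, 48, 44, 48 and 44.
    """
    vehicle_all = _cells(VEHICLE, 0.0, VEHICLE_TIMEPOINTS)
    c1 = ComparisonSpec(
        name="C1",
        cell_line="BT474",
        group1=frozenset(_cells(DRUG, HIGH_DOSE, (6.0, 12.0))),
        group2=frozenset(
            _cells(DRUG, LOW_DOSE, LOW_DOSE_TIMEPOINTS)
            | _cells(DRUG, HIGH_DOSE, (2.0,))
            | vehicle_all
        ),
    )
    c2 = ComparisonSpec(
        name="C2",
        cell_line="BT474",
        group1=frozenset(_cells(DRUG, HIGH_DOSE, (6.0, 12.0))),
        group2=frozenset(_cells(DRUG, LOW_DOSE, (6.0, 12.0))),
    )
    skbr3_late_both = _cells(DRUG, HIGH_DOSE, (6.0, 12.0)) | _cells(
        DRUG, LOW_DOSE, (6.0, 12.0)
    )
    c3 = ComparisonSpec(
        name="C3",
        cell_line="SKBR3",
        group1=frozenset(skbr3_late_both),
        group2=frozenset(
            _cells(DRUG, LOW_DOSE, (2.0, 24.0))
            | _cells(DRUG, HIGH_DOSE, (2.0,))
            | vehicle_all
        ),
    )
    c4 = ComparisonSpec(
        name="C4",
        cell_line="SKBR3",
        group1=frozenset(skbr3_late_both),
        group2=frozenset(
            _cells(DRUG, LOW_DOSE, (2.0,))
            | _cells(DRUG, HIGH_DOSE, (2.0,))
            | vehicle_all
        ),
    )
    skbr3_12h_both = _cells(DRUG, HIGH_DOSE, (12.0,)) | _cells(
        DRUG, LOW_DOSE, (12.0,)
    )
    c5 = ComparisonSpec(
        name="C5",
        cell_line="SKBR3",
        group1=frozenset(skbr3_12h_both),
        group2=frozenset(
            _cells(DRUG, LOW_DOSE, (2.0, 6.0, 24.0))
            | _cells(DRUG, HIGH_DOSE, (2.0, 6.0))
            | vehicle_all
        ),
    )
    c6 = ComparisonSpec(
        name="C6",
        cell_line="SKBR3",
        group1=frozenset(skbr3_12h_both),
        group2=frozenset(
            _cells(DRUG, LOW_DOSE, (2.0, 6.0))
            | _cells(DRUG, HIGH_DOSE, (2.0, 6.0))
            | vehicle_all
        ),
    )
    return [c1, c2, c3, c4, c5, c6]
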