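"""qPCR relative quantification and dose-response phenotyping.

Relative quantification follows the comparative threshold-cycle model:
``dCt = Ct(target) - Ct(reference)`` per condition, ``ddCt = dCt(treated)
- dCt(control)`` and ``RQ = 2^-ddCt`` (amplification efficiency fixed at
2).  A fold change of at least 2 in either direction flags a gene as
dysregulated.  Dose-response absorbances are converted to % survival of
untreated controls and a four-parameter log-logistic curve yields the
IC50, the concentration at 50% absolute survival.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DataError, NumericalError

CT_COLUMNS = ["cell_line", "gene", "condition", "replicate", "ct"]
DOSE_COLUMNS = ["cell_line", "conc_uM", "a405", "a620", "well_type"]


def validate_ct_table(ct: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise DataError(f"Ct table missing columns: {missing}")
    if (ct["ct"] <= 0).any():
        raise DataError("Ct values must be positive")
    bad = set(ct["condition"]) - {"control", "treated"}
    if bad:
        raise DataError(f"unknown conditions: {sorted(bad)}")
    if reference_gene not in set(ct["gene"]):
        raise DataError(f"reference gene {reference_gene!r} absent from table")
    return ct


def relative_quantification(
    ct: pd.DataFrame, reference_gene: str = "GAPDH"
) -> pd.DataFrame:
    """ddCt relative quantification of every target gene per cell line.

    Replicate Cts are averaged within each (cell line, gene, condition)
    before forming dCt; the untreated control acts as the calibrator.
    Returns a frame with columns ``cell_line, gene, dct_control,
    dct_treated, ddct, rq, log2_rq, fold_change, rq_sd`` where
    ``fold_change`` is the signed display value (RQ if >= 1 else -1/RQ)
    and ``rq_sd`` the standard deviation of per-replicate RQ values when
    replicates are matched.
    """
    ct = validate_ct_table(ct, reference_gene)
    rows = []
    for cell_line, sub in ct.groupby("cell_line", sort=True):
        ref = sub[sub["gene"] == reference_gene]
        ref_means = {}
        for cond in ("control", "treated"):
            r = ref[ref["condition"] == cond]
            if r.empty:
                raise DataError(
                    f"reference gene missing for ({cell_line}, {cond})"
                )
            ref_means[cond] = r["ct"].mean()
        for gene, gsub in sub[sub["gene"] != reference_gene].groupby(
            "gene", sort=True
        ):
            dct = {}
            for cond in ("control", "treated"):
                g = gsub[gsub["condition"] == cond]
                if g.empty:
                    raise DataError(
                        f"gene {gene} missing condition {cond} in {cell_line}"
                    )
                dct[cond] = g["ct"].mean() - ref_means[cond]
            ddct = dct["treated"] - dct["control"]
            rq = 2.0 ** (-ddct)
            # per-replicate spread: pair target and reference by replicate
            rep_rq = []
            for cond in ("treated",):
                g = gsub[gsub["condition"] == cond].set_index("replicate")["ct"]
                r = ref[ref["condition"] == cond].set_index("replicate")["ct"]
                shared = g.index.intersection(r.index)
                for rep in shared:
                    rep_dct = g.loc[rep] - r.loc[rep]
                    rep_rq.append(2.0 ** (-(rep_dct - dct["control"])))
            rq_sd = float(np.std(rep_rq, ddof=1)) if len(rep_rq) > 1 else math.nan
            rows.append(
                {
                    "cell_line": cell_line,
                    "gene": gene,
                    "dct_control": dct["control"],
                    "dct_treated": dct["treated"],
                    "ddct": ddct,
                    "rq": rq,
                    "log2_rq": -ddct,
                    "fold_change": rq if rq >= 1 else -1.0 / rq,
                    "rq_sd": rq_sd,
                }
            )
    return pd.DataFrame(rows)


def classify_dysregulated(rq: float, fold_threshold: float = 2.0) -> str:
    """Call a gene up/down/none by the symmetric fold-change rule."""
    if fold_threshold <= 1:
        raise DataError("fold_threshold must be > 1")
    if rq >= fold_threshold:
        return "up"
    if rq <= 1.0 / fold_threshold:
        return "down"
    return "none"


def add_calls(rq_table: pd.DataFrame, fold_threshold: float = 2.0) -> pd.DataFrame:
    out = rq_table.copy()
    out["call"] = [classify_dysregulated(r, fold_threshold) for r in out["rq"]]
    return out


def sensitivity_concordance(
    log2rq: Mapping[str, float], ic50: Mapping[str, float]
) -> tuple[float, int | None]:
    """Correlate a gene's treatment response with cell-line drug sensitivity.

    Cell lines present in both mappings are ordered by ascending IC50
    (most sensitive first).  Returns the Spearman correlation of log2 RQ
    with IC50, and the 1-based position of the single sign change of
    log2 RQ along that order when the sign sequence is (+...+-...-) or
    (-...-+...+); otherwise the switch index is None.
    """
    lines = sorted(set(log2rq) & set(ic50), key=lambda c: (ic50[c], c))
    if len(lines) < 3:
        raise DataError("need >= 3 cell lines with both values")
    x = np.array([log2rq[c] for c in lines])
    y = np.array([ic50[c] for c in lines])
    if np.all(y == y[0]):
        raise DataError("all IC50s tied; correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    signs = np.sign(x)
    switch: int | None = None
    if np.all(signs != 0):
        changes = np.flatnonzero(signs[1:] != signs[:-1])
        if len(changes) == 1:
            switch = int(changes[0]) + 2  # 1-based position of first flipped sign
    return rho, switch


def percent_survival(curve: pd.DataFrame) -> pd.DataFrame:
    """% survival per tested concentration from raw plate absorbances.

    ``curve`` has columns ``cell_line, conc_uM, a405, a620, well_type``
    with well types ``treated``, ``control`` (untreated cells) and
    ``blank`` (no cells).  The per-well signal is A405 - A620; the blank
    mean is subtracted and survival is the treated signal as a percentage
    of the control signal, floored at 0.
    """
    missing = [c for c in DOSE_COLUMNS if c not in curve.columns]
    if missing:
        raise DataError(f"dose-response table missing columns: {missing}")
    rows = []
    for cell_line, sub in curve.groupby("cell_line", sort=True):
        signal = sub["a405"] - sub["a620"]
        blank = signal[sub["well_type"] == "blank"].mean()
        if np.isnan(blank):
            blank = 0.0
        control = signal[sub["well_type"] == "control"].mean() - blank
        if not control > 0:
            raise DataError(
                f"{cell_line}: control signal does not exceed blank"
            )
        treated = sub[sub["well_type"] == "treated"]
        for conc, tsub in treated.groupby("conc_uM", sort=True):
            tsignal = (tsub["a405"] - tsub["a620"]).mean() - blank
            rows.append(
                {
                    "cell_line": cell_line,
                    "conc_uM": float(conc),
                    "pct_survival": max(0.0, 100.0 * tsignal / control),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class IC50Result:
    """IC50 estimate with the fitted 4PL parameters.

    ``method`` records whether the value came from the least-squares fit
    or from the log-linear interpolation fallback; ``extrapolated`` flags
    an IC50 outside the tested concentration range.
    """

    ic50: float
    lower: float
    upper: float
    hill: float
    ec50: float
    residual_norm: float
    method: str
    extrapolated: bool


def _four_pl(x: np.ndarray, lower: float, upper: float, hill: float, ec50: float):
    return lower + (upper - lower) / (1.0 + (x / ec50) ** hill)


def _interpolate_ic50(conc: np.ndarray, surv: np.ndarray) -> float:
    """Log-linear interpolation of the 50% crossing between bracketing points."""
    order = np.argsort(conc)
    c, s = conc[order], surv[order]
    above = s >= 50.0
    for i in range(len(c) - 1):
        if above[i] != above[i + 1]:
            lc1, lc2 = math.log(c[i]), math.log(c[i + 1])
            frac = (50.0 - s[i]) / (s[i + 1] - s[i])
            return math.exp(lc1 + frac * (lc2 - lc1))
    raise NumericalError("no crossing")


def fit_ic50(conc: np.ndarray, survival: np.ndarray) -> IC50Result:
    """Four-parameter log-logistic fit of % survival against concentration.

    Requires >= 4 distinct positive concentrations with survival on both
    sides of 50%.  The IC50 is the concentration at 50% absolute survival
    on the fitted curve; when the fit fails to converge or never reaches
    50%, the value falls back to log-linear interpolation between the
    bracketing measurements.
    """
    conc = np.asarray(conc, dtype=float)
    survival = np.asarray(survival, dtype=float)
    keep = conc > 0
    conc, survival = conc[keep], survival[keep]
    if len(np.unique(conc)) < 4:
        raise DataError("need >= 4 distinct positive concentrations")
    if survival.min() >= 50.0 or survival.max() <= 50.0:
        raise NumericalError("no crossing")
    lo, hi = conc.min(), conc.max()
    guess_ec50 = _interpolate_ic50(conc, survival)
    # upper asymptote capped at the largest observed response: survival is
    # already normalized to untreated controls, so the top plateau cannot
    # meaningfully exceed what was measured
    upper_cap = float(survival.max())
    p0 = [min(max(0.0, survival.min()), 45.0), upper_cap, 1.0, guess_ec50]
    bounds = ([0.0, 0.0, 0.05, lo / 1e3], [49.0, upper_cap, 20.0, hi * 1e3])
    try:
        popt, _ = optimize.curve_fit(
            _four_pl, conc, survival, p0=p0, bounds=bounds, maxfev=20000
        )
        lower, upper, hill, ec50 = (float(v) for v in popt)
        resid = float(np.linalg.norm(_four_pl(conc, *popt) - survival))
        if upper <= 50.0:
            raise NumericalError("fitted curve never reaches 50%")
        # concentration at absolute 50% survival on the fitted curve
        ratio = (upper - lower) / (50.0 - lower) - 1.0
        if ratio <= 0:
            raise NumericalError("fitted curve never crosses 50%")
        ic50 = ec50 * ratio ** (1.0 / hill)
        method = "fit"
    except (RuntimeError, NumericalError):
        ic50 = _interpolate_ic50(conc, survival)
        lower, upper, hill, ec50 = math.nan, math.nan, math.nan, math.nan
        resid = math.nan
        method = "interpolation"
    return IC50Result(
        ic50=float(ic50),
        lower=lower,
        upper=upper,
        hill=hill,
        ec50=ec50,
        residual_norm=resid,
        method=method,
        extrapolated=not (lo <= ic50 <= hi),
    )


def ic50_per_cell_line(survival_table: pd.DataFrame) -> pd.DataFrame:
    """Fit one IC50 per cell line from a % survival table."""
    rows = []
    for cell_line, sub in survival_table.groupby("cell_line", sort=True):
        res = fit_ic50(
            sub["conc_uM"].to_numpy(), sub["pct_survival"].to_numpy()
        )
        rows.append(
            {
                "cell_line": cell_line,
                "ic50_uM": res.ic50,
                "hill": res.hill,
                "method": res.method,
                "extrapolated": res.extrapolated,
            }
        )
    return pd.DataFrame(rows)
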