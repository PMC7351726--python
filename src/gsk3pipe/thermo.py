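"""Dock-score / inhibition-constant / IC50 thermodynamics and correlations.

The conversions all follow from the same relation

    dG = R T ln(Ki)          (Ki in mol/L, dG in kcal/mol)

with two temperature conventions: the docking engine's predicted inhibition
constants correspond to T = 298.15 K, while the IC50-derived experimental
binding free energies use R = 1.987e-3 kcal/K/mol and T = 300 K with the
IC50 taken as equal to Ki.  The correlation analysis joins the cytotoxicity
and docking tables per cell line and regresses dG_exp on the dock score.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .constants import R_KCAL, ThermoConstants, DEFAULT_THERMO
from .data import CytotoxEntry, DockRecord

#: marker returned for censored IC50 entries, which carry no point estimate
EXCLUDED = None

CensoringRule = Literal["drop", "at-bound"]
#: default inclusion rule for the dock-vs-experiment correlations.  Censored
#: entries are placed at their 20 uM assay bound; this is the rule that
#: reproduces the published per-cell-line correlations (see docs/methods.md).
DEFAULT_CENSORING: CensoringRule = "at-bound"


class DegenerateDataError(ValueError):
    """Raised when a correlation or fit is requested on degenerate data."""


def dg_to_ki(dg: float, T: float = 298.15, R: float = R_KCAL) -> float:
    """Convert a binding free energy (kcal/mol) to an inhibition constant (mol/L)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(dg / (R * T))


def ki_to_dg(ki: float, T: float = 298.15, R: float = R_KCAL) -> float:
    """Convert an inhibition constant (mol/L) to a binding free energy (kcal/mol)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if ki <= 0:
        raise ValueError("inhibition constant must be positive")
    return R * T * math.log(ki)


def ic50_to_dg_exp(
    entry: CytotoxEntry | float,
    constants: ThermoConstants = DEFAULT_THERMO,
) -> float | None:
    """Experimental binding free energy (kcal/mol) from an IC50 in uM.

    The IC50 is treated as equal to the inhibition constant and converted to
    mol/L before taking dG = R * T_exp * ln(Ki).  Censored entries yield the
    EXCLUDED marker (None), never a number.
    """
    if isinstance(entry, CytotoxEntry):
        if entry.censored:
            return EXCLUDED
        ic50_uM = entry.ic50_uM
    else:
        ic50_uM = float(entry)
    if ic50_uM <= 0:
        raise ValueError("IC50 must be positive")
    return constants.R_kcal * constants.T_exp * math.log(ic50_uM * 1e-6)


def pearson_r(pairs: Sequence[tuple[float, float]]) -> float:
    """Product-moment correlation of paired observations."""
    if len(pairs) < 3:
        raise DegenerateDataError("need at least 3 pairs")
    x, y = np.asarray(pairs, dtype=float).T
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in x or y")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    return max(-1.0, min(1.0, r))  # guard float overshoot on exact lines


def linear_fit(pairs: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """Least-squares line y = a*x + b; returns (slope, intercept, rmse).

    The RMSE is the root-mean-square residual about the fitted line, in
    y-units, with no degrees-of-freedom correction.
    """
    if len(pairs) < 3:
        raise DegenerateDataError("need at least 3 pairs")
    x, y = np.asarray(pairs, dtype=float).T
    if np.ptp(x) == 0:
        raise DegenerateDataError("zero variance in x")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return float(slope), float(intercept), rmse


@dataclass(frozen=True)
class CorrelationSummary:
    cell_line: str
    n: int
    r: float
    slope: float
    intercept: float
    rmse: float  # kcal/mol

    def __post_init__(self) -> None:
        assert -1.0 <= self.r <= 1.0 and self.n >= 3 and self.rmse >= 0


def dock_vs_exp(
    cytotox: Iterable[CytotoxEntry],
    dock: Iterable[DockRecord],
    cell_line: str,
    constants: ThermoConstants = DEFAULT_THERMO,
    censoring: CensoringRule = DEFAULT_CENSORING,
) -> CorrelationSummary:
    """Correlate dock scores against IC50-derived binding free energies.

    Joins the two tables on compound id for one cell line, converts each
    quantified IC50 to dG_exp, and correlates against the dock score.
    Compounds without a dock score (the reference drug) never enter.
    Censored entries are handled per ``censoring``: "at-bound" places them at
    the 20 uM assay bound (the rule under which the published per-cell-line
    correlations are recovered); "drop" excludes them.
    """
    dock_by_id = {r.compound_id: r for r in dock}
    pairs, rows = [], []
    for entry in cytotox:
        if entry.cell_line != cell_line or entry.compound_id not in dock_by_id:
            continue
        if entry.censored:
            if censoring == "drop":
                continue
            dg_exp = ic50_to_dg_exp(entry.ic50_uM, constants)
        else:
            dg_exp = ic50_to_dg_exp(entry, constants)
        pairs.append((dock_by_id[entry.compound_id].dg_dock, dg_exp))
        rows.append(entry.compound_id)
    if len(pairs) < 3:
        raise DegenerateDataError(
            f"fewer than 3 joinable compounds for cell line {cell_line}")
    # order-independence: correlate in a canonical compound order
    order = sorted(range(len(rows)), key=lambda i: rows[i])
    pairs = [pairs[i] for i in order]
    slope, intercept, rmse = linear_fit(pairs)
    return CorrelationSummary(cell_line=cell_line, n=len(pairs),
                              r=pearson_r(pairs), slope=slope,
                              intercept=intercept, rmse=rmse)


def screen_by_threshold(
    dock: Iterable[DockRecord], threshold: float
) -> dict[str, list[str]]:
    """Partition compounds by dock score against an energy threshold.

    Scores at or below (at least as negative as) the threshold are labeled
    potential inhibitors; ties pass.
    """
    if threshold >= 0:
        raise ValueError("threshold must be negative (a binding energy)")
    out: dict[str, list[str]] = {"potential-inhibitor": [], "below-threshold": []}
    for rec in dock:
        key = "potential-inhibitor" if rec.dg_dock <= threshold else "below-threshold"
        out[key].append(rec.compound_id)
    return out
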