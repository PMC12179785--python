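"""Assay arithmetic: RT-activity standard curves, H-scores, MFI ratios.

Covers the quantitative conventions of the accompanying wet-lab assays:

* product-enhanced RT (PERT) qPCR — a log-linear standard curve
  ``Cq = slope * log10(pU) + intercept`` fitted to recombinant-RT serial
  dilutions, pU extrapolation of sample Cq values with a 40-cycle
  background cutoff, and delta-Cq against a no-RT negative control;
* in situ hybridisation / immunocytochemistry — the H-score (cells binned
  0-4 by signal intensity, score = sum of bin index x percent of cells,
  range 0-400), per-cell channel MFI ratios, and per-cell fold change
  normalised so the control population's median equals 1.

Inputs are per-well standards (pU, Cq) and per-cell records (marker flag,
background-corrected area-adjusted MFI per channel, nuclear area), read
from TSV.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class Detection(enum.Enum):
    BELOW_DETECTION = "BELOW_DETECTION"


BELOW_DETECTION = Detection.BELOW_DETECTION

DEFAULT_CUTOFF_CYCLES = 40.0


@dataclass(frozen=True)
class QpcrStandard:
    pU: float  # known RT amount, picounits
    cq: float

    def __post_init__(self) -> None:
        if self.pU <= 0 or self.cq <= 0:
            raise ValueError("standards require pU > 0 and cq > 0")


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float
    n_levels: int

    def cq_of(self, pU: float) -> float:
        return self.slope * np.log10(pU) + self.intercept


def fit_standard_curve(standards: list[QpcrStandard]) -> StandardCurve:
    """Least-squares fit of Cq on log10(pU).

    Replicate wells at the same pU level are averaged on the Cq scale
    before fitting; at least two distinct pU levels are required.
    """
    table = pd.DataFrame([(s.pU, s.cq) for s in standards], columns=["pU", "cq"])
    levels = table.groupby("pU", sort=True)["cq"].mean().reset_index()
    if len(levels) < 2:
        raise ValueError("standard-curve fitting requires >= 2 distinct pU levels")
    x = np.log10(levels["pU"].to_numpy())
    y = levels["cq"].to_numpy()
    fit = stats.linregress(x, y)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2) if len(levels) > 2 else 1.0,
        n_levels=len(levels),
    )


def extrapolate_pU(
    sample_cq: float,
    curve: StandardCurve,
    cutoff_cycles: float = DEFAULT_CUTOFF_CYCLES,
) -> float | Detection:
    """Invert the standard curve; Cq at or beyond the cutoff is background."""
    if sample_cq >= cutoff_cycles:
        return BELOW_DETECTION
    return float(10 ** ((sample_cq - curve.intercept) / curve.slope))


def delta_cq(negative_control_cq: float, sample_cq: float) -> float:
    """Negative-control Cq minus sample Cq (no-signal samples use the
    control cycle count as their Cq, giving 0 by convention)."""
    return negative_control_cq - sample_cq


def h_score(mfi: np.ndarray | list[float], bin_edges: list[float]) -> float:
    """H-score of a cell population: sum over bins of index x percent.

    ``bin_edges`` are the four ascending thresholds separating bins 0-4
    (bin 0 = below the first edge, the no-signal bin anchored at the
    negative-control ceiling).  Bounded [0, 400]; invariant under any
    monotone intensity rescaling that preserves bin membership.
    """
    values = np.asarray(mfi, dtype=float)
    if values.size == 0:
        raise ValueError("h_score requires at least one cell")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.shape != (4,) or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be 4 strictly increasing thresholds (5 bins, scores 0-4)")
    scores = np.digitize(values, edges)
    pct = np.bincount(scores, minlength=5) / values.size * 100.0
    return float(np.dot(np.arange(5), pct))


def default_bin_edges(mfi: np.ndarray | list[float], negative_ceiling: float) -> list[float]:
    """Quantile bin edges with bin 0 anchored at the negative-control
    ceiling: signal above background is split into quartiles."""
    values = np.asarray(mfi, dtype=float)
    positive = values[values > negative_ceiling]
    if positive.size == 0:
        return [negative_ceiling, negative_ceiling * 2, negative_ceiling * 3, negative_ceiling * 4]
    qs = np.quantile(positive, [0.25, 0.5, 0.75])
    edges = [negative_ceiling] + [float(q) for q in qs]
    for i in range(1, 4):
        if edges[i] <= edges[i - 1]:
            edges[i] = np.nextafter(edges[i - 1], np.inf)
    return edges


def mfi_ratio(
    cells: pd.DataFrame,
    numerator_channel: str,
    denominator_channel: str,
) -> tuple[pd.Series, int]:
    """Per-cell channel ratio; cells with a zero denominator are excluded
    and counted.  Returns (ratios indexed like ``cells``, n_excluded)."""
    num = cells[numerator_channel].astype(float)
    den = cells[denominator_channel].astype(float)
    keep = den != 0
    return (num[keep] / den[keep]), int((~keep).sum())


def fold_change(
    cells: pd.DataFrame,
    control_cells: pd.DataFrame,
    channel: str,
    area_column: str = "nuclear_area",
) -> pd.Series:
    """Per-cell fold change in area-normalised signal over the control
    population median (control median maps to 1 by construction)."""
    if len(control_cells) == 0:
        raise ValueError("fold_change requires a non-empty control population")
    control = control_cells[channel].astype(float) / control_cells[area_column].astype(float)
    reference = float(control.median())
    if reference == 0:
        raise ValueError("control population has zero median signal/area")
    return (cells[channel].astype(float) / cells[area_column].astype(float)) / reference


def read_standards_tsv(path: str | Path) -> list[QpcrStandard]:
    table = pd.read_csv(path, sep="\t")
    return [QpcrStandard(float(r.pU), float(r.cq)) for r in table.itertuples(index=False)]


def read_cells_tsv(path: str | Path) -> pd.DataFrame:
    """Per-cell table: cell_id, is_marker_positive, nuclear_area, plus one
    column per MFI channel."""
    table = pd.read_csv(path, sep="\t")
    required = {"cell_id", "nuclear_area"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cell table missing required columns: {sorted(missing)}")
    if (table["nuclear_area"] <= 0).any():
        raise ValueError("nuclear_area must be positive")
    return table
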