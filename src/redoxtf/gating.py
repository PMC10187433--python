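"""Activation gating: control-derived thresholds and quadrant classification.

Thresholds are fitted on an untreated (dose 0) population as upper
quantiles of the FOXO1 nuclear fraction and of log10 nuclear p53 (the p53
axis is log-scaled, matching how the measurement spans decades), then
applied with strict inequality so a control-typical cell is never called
active.  Each cell lands in one of four quadrants: both, FOXO1-only,
p53-only, or neither active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .simulate import SnapshotCell

__all__ = ["Thresholds", "QuadrantTable", "fit_thresholds", "classify_cells",
           "quadrant_table", "LABELS"]

LABELS = ("both", "foxo_only", "p53_only", "neither")

#: Minimum control size for a stable upper-quantile fit.
MIN_CONTROL_CELLS = 100


@dataclass(frozen=True)
class Thresholds:
    """Activation cutoffs: FOXO1 nuclear fraction and log10 nuclear p53."""

    foxo_nf_cut: float
    p53_log_cut: float
    method: tuple[str, float] = ("quantile", 0.99)

    def __post_init__(self) -> None:
        if not 0.0 < self.foxo_nf_cut < 1.0:
            raise InputError(
                f"foxo_nf_cut must be in (0,1), got {self.foxo_nf_cut}")
        if not math.isfinite(self.p53_log_cut):
            raise InputError("p53_log_cut must be finite")


def fit_thresholds(control: Sequence[SnapshotCell], q: float = 0.99,
                   method: str = "quantile") -> Thresholds:
    """Fit activation cutoffs from an untreated control population.

    ``method="quantile"`` (default): the ``q``-quantile of each control
    statistic.  ``method="mean_sd"``: mean + 3 SD, with ``q`` ignored.
    """
    if len(control) < MIN_CONTROL_CELLS:
        raise InputError(
            f"control must have >= {MIN_CONTROL_CELLS} cells, got {len(control)}")
    doses = {c.dose for c in control}
    if doses != {0.0}:
        raise InputError(
            f"control must be dose 0 only; found doses {sorted(doses)}")
    nf = np.array([c.foxo1_nf for c in control])
    logp = np.log10([c.p53_nuc for c in control])
    if method == "quantile":
        if not 0.0 < q < 1.0:
            raise InputError(f"q must be in (0,1), got {q}")
        return Thresholds(float(np.quantile(nf, q)),
                          float(np.quantile(logp, q)), ("quantile", q))
    if method == "mean_sd":
        return Thresholds(float(nf.mean() + 3.0 * nf.std()),
                          float(logp.mean() + 3.0 * logp.std()),
                          ("mean_sd", 3.0))
    raise InputError(f"unknown threshold method {method!r}")


def classify_cells(cells: Sequence[SnapshotCell], th: Thresholds) -> list[str]:
    """Quadrant label per cell; activity is strict inequality above the cut."""
    labels = []
    for c in cells:
        foxo = c.foxo1_nf > th.foxo_nf_cut
        p53 = math.log10(c.p53_nuc) > th.p53_log_cut
        labels.append("both" if foxo and p53
                      else "foxo_only" if foxo
                      else "p53_only" if p53
                      else "neither")
    return labels


@dataclass(frozen=True)
class QuadrantTable:
    """Per-dose quadrant fractions (sum to 1) with the cell count."""

    dose: float
    frac_both: float
    frac_foxo_only: float
    frac_p53_only: float
    frac_neither: float
    n: int


def quadrant_table(labels_by_dose: dict[float, Sequence[str]]
                   ) -> tuple[list[QuadrantTable], float]:
    """Per-dose quadrant fractions plus the max over doses of ``frac_both``."""
    tables = []
    for dose in sorted(labels_by_dose):
        labels = list(labels_by_dose[dose])
        if len(labels) == 0:
            raise InputError(f"empty label group for dose {dose}")
        unknown = set(labels) - set(LABELS)
        if unknown:
            raise InputError(f"unknown labels {sorted(unknown)}")
        n = len(labels)
        counts = {lab: labels.count(lab) for lab in LABELS}
        tables.append(QuadrantTable(
            dose=float(dose),
            frac_both=counts["both"] / n,
            frac_foxo_only=counts["foxo_only"] / n,
            frac_p53_only=counts["p53_only"] / n,
            frac_neither=counts["neither"] / n,
            n=n))
    max_both = max(t.frac_both for t in tables)
    return tables, max_both


def quadrants_to_frame(tables: Sequence[QuadrantTable]) -> pd.DataFrame:
    return pd.DataFrame({
        "dose_uM": [t.dose for t in tables],
        "n": [t.n for t in tables],
        "frac_both": [t.frac_both for t in tables],
        "frac_foxo_only": [t.frac_foxo_only for t in tables],
        "frac_p53_only": [t.frac_p53_only for t in tables],
        "frac_neither": [t.frac_neither for t in tables],
    })
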