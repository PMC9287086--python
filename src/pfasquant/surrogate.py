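"""Surrogate internal-standard selection analysis.

When no matched isotope-labeled standard exists for an analyte, a surrogate
standard must be chosen.  Solubility (and hence co-variation of recovery and
ionization) tracks the number of fluorine atoms, so fluorine-count
similarity is a practical selection heuristic.  This module quantifies an
analyte against every candidate internal standard and relates the fit (R²)
of each resulting calibration curve to the fluorine-count difference ΔF —
the scatter that motivates the heuristic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .quant import CalibrationError, fit_calibration
from .registry import CompoundRegistry

__all__ = ["SurrogateScanResult", "surrogate_scan", "rank_surrogates"]


@dataclass(frozen=True)
class SurrogateRow:
    is_id: str
    delta_f: int
    r_squared: float
    slope: float


@dataclass
class SurrogateScanResult:
    """Calibration fit quality of one analyte against each candidate IS."""

    analyte_id: str
    rows: List[SurrogateRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.analyte_id, r.is_id, r.delta_f, r.r_squared, r.slope) for r in self.rows],
            columns=["analyte", "is_id", "delta_f", "r_squared", "slope"],
        )


def surrogate_scan(
    analyte_id: str,
    candidate_ids: Sequence[str],
    areas: pd.DataFrame,
    registry: CompoundRegistry,
    weighting: str = "1/x",
    replicate: Optional[int] = None,
) -> SurrogateScanResult:
    """Fit the analyte's calibration against every candidate internal standard.

    ``replicate`` restricts the fit to one replicate's curve; by default all
    replicates' (level, ratio) points are pooled.  Candidates missing from
    the area table at any level are skipped with a warning.  Rows are sorted
    by ΔF (fluorine-count difference), ascending.
    """
    analyte_f = registry[analyte_id].fluorines
    if analyte_f is None:
        raise ValueError(f"{analyte_id}: fluorine count unknown (mass-only entry)")
    df = areas
    if replicate is not None:
        df = df[df["replicate_id"] == replicate]
    wide = df.pivot_table(index=["replicate_id", "level_ngL"],
                          columns="compound", values="area")
    if analyte_id not in wide.columns:
        raise ValueError(f"{analyte_id} absent from area table")
    levels = wide.index.get_level_values("level_ngL").unique()
    rows: List[SurrogateRow] = []
    for cand in candidate_ids:
        if cand not in wide.columns:
            warnings.warn(f"{cand}: absent from area table; skipped")
            continue
        present = wide[cand].groupby("level_ngL").count()
        if (present == 0).any() or set(present.index) != set(levels):
            warnings.warn(f"{cand}: missing at one or more levels; skipped")
            continue
        cand_f = registry[cand].fluorines
        if cand_f is None:
            warnings.warn(f"{cand}: fluorine count unknown; skipped")
            continue
        ratio = wide[analyte_id] / wide[cand]
        pairs = [
            (lvl, r) for (_rep, lvl), r in ratio.items() if np.isfinite(r)
        ]
        try:
            curve = fit_calibration(pairs, weighting, analyte_id, cand)
        except CalibrationError as exc:
            warnings.warn(f"{cand}: {exc}; skipped")
            continue
        rows.append(SurrogateRow(cand, abs(analyte_f - cand_f),
                                 curve.r_squared, curve.slope))
    rows.sort(key=lambda r: (r.delta_f, r.is_id))
    return SurrogateScanResult(analyte_id, rows)


def rank_surrogates(result: SurrogateScanResult) -> List[str]:
    """Candidates ordered by R² descending; ties by smaller ΔF, then id."""
    if not result.rows:
        raise ValueError("no candidate rows to rank")
    ordered = sorted(result.rows, key=lambda r: (-r.r_squared, r.delta_f, r.is_id))
    return [r.is_id for r in ordered]
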