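"""EPA Method 537.1-style validation statistics.

Given back-calculated quality-control replicate concentrations per
calibration level, this module computes, per compound:

* ``HR_PIR`` — the half range of the prediction interval of results,
  ``s * t(df=N-1, 1-alpha/2) * sqrt(1 + 1/N)`` with ``s`` the sample
  standard deviation of the replicates (alpha defaults to 0.01);
* the PIR recovery criteria — ``(mean ± HR_PIR) / actual x 100`` must fall
  within [50%, 150%] (both bounds inclusive);
* ``MRL`` — the lowest calibration level whose replicates pass both criteria;
* ``DL`` — ``s * t`` applied to the MRL level's replicates;
* ``IDP`` / ``IDA`` — replicate RSD and mean recovery at a mid-level
  concentration (500 ng/L by default).

Reported limits are given both as ng/L of the calibration stock and as pg on
column (concentration x 0.9 dilution x 100 µL injection = x 0.09 under the
default study design).

The t-quantile is two-sided (``1 - alpha/2``) by default, matching the
rendering of the source method's HR_PIR formula; ``sided="one"`` gives the
one-sided EPA-convention variant for the DL.  Both are kept because the two
conventions genuinely coexist in practice; neither is silently preferred.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .synth import StudyDesign

__all__ = [
    "ReplicateSet",
    "PirResult",
    "MrlResult",
    "ValidationResult",
    "half_range_pir",
    "pir_recovery",
    "determine_mrl",
    "detection_limit",
    "idp",
    "ida",
    "pg_on_column",
    "replicate_sets_from_concs",
    "build_validation_report",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = [
    "compound", "mrl_ngL", "mrl_pg_on_column", "dl_ngL", "dl_pg_on_column",
    "idp_pct", "ida_pct",
]


@dataclass(frozen=True)
class ReplicateSet:
    """Back-calculated concentrations of one compound at one nominal level."""

    compound_id: str
    actual_ngL: float
    concentrations: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.actual_ngL <= 0:
            raise ValueError("actual concentration must be positive")
        if len(self.concentrations) < 2:
            raise ValueError("need at least two replicates")

    @property
    def n(self) -> int:
        return len(self.concentrations)

    @property
    def mean(self) -> float:
        return float(np.mean(self.concentrations))

    @property
    def sd(self) -> float:
        return float(np.std(self.concentrations, ddof=1))


@dataclass(frozen=True)
class PirResult:
    level_ngL: float
    mean: float
    hr_pir: float
    upper_pct: float
    lower_pct: float

    @property
    def passes(self) -> bool:
        return self.upper_pct <= 150.0 and self.lower_pct >= 50.0

    @property
    def failing_criterion(self) -> str:
        fails = []
        if self.upper_pct > 150.0:
            fails.append("upper>150%")
        if self.lower_pct < 50.0:
            fails.append("lower<50%")
        return ",".join(fails)


@dataclass(frozen=True)
class MrlResult:
    compound_id: str
    mrl_ngL: Optional[float]  # None when no level passes
    per_level: Tuple[PirResult, ...]

    @property
    def defined(self) -> bool:
        return self.mrl_ngL is not None


@dataclass(frozen=True)
class ValidationResult:
    compound_id: str
    mrl_ngL: Optional[float]
    mrl_pg_on_column: Optional[float]
    dl_ngL: Optional[float]
    dl_pg_on_column: Optional[float]
    idp_pct: Optional[float]
    ida_pct: Optional[float]


def _t_quantile(df: int, alpha: float, sided: str) -> float:
    if sided == "two":
        q = 1 - alpha / 2
    elif sided == "one":
        q = 1 - alpha
    else:
        raise ValueError("sided must be 'one' or 'two'")
    return float(stats.t.ppf(q, df))


def half_range_pir(r: ReplicateSet, alpha: float = 0.01, sided: str = "two") -> float:
    """s * t(N-1, 1-alpha/2) * sqrt(1 + 1/N): prediction-interval half range."""
    t = _t_quantile(r.n - 1, alpha, sided)
    return r.sd * t * math.sqrt(1 + 1 / r.n)


def pir_recovery(r: ReplicateSet, alpha: float = 0.01, sided: str = "two") -> PirResult:
    """Upper/lower prediction-interval recovery of a replicate set, percent."""
    hr = half_range_pir(r, alpha, sided)
    upper = (r.mean + hr) / r.actual_ngL * 100.0
    lower = (r.mean - hr) / r.actual_ngL * 100.0
    return PirResult(r.actual_ngL, r.mean, hr, upper, lower)


def determine_mrl(
    level_sets: Sequence[ReplicateSet],
    alpha: float = 0.01,
    sided: str = "two",
    min_replicates: int = 7,
) -> MrlResult:
    """Lowest calibration level whose replicates pass both PIR criteria.

    Levels with fewer than ``min_replicates`` replicates are excluded with a
    warning.  If no level passes, the MRL is undefined (flagged, not raised).
    """
    usable: List[ReplicateSet] = []
    for r in level_sets:
        if r.n < min_replicates:
            warnings.warn(
                f"{r.compound_id}: level {r.actual_ngL} ng/L has only {r.n} "
                f"replicates (< {min_replicates}); excluded"
            )
            continue
        usable.append(r)
    usable.sort(key=lambda r: r.actual_ngL)
    results = tuple(pir_recovery(r, alpha, sided) for r in usable)
    cid = level_sets[0].compound_id if level_sets else ""
    for res in results:
        if res.passes:
            return MrlResult(cid, res.level_ngL, results)
    return MrlResult(cid, None, results)


def detection_limit(r: ReplicateSet, alpha: float = 0.01, sided: str = "two") -> float:
    """DL = s * t(N-1) from the MRL level's replicate data.

    ``sided="two"`` (default) uses the 1-alpha/2 quantile; ``sided="one"``
    the 1-alpha quantile (EPA 537.1 convention).  Note the algebraic identity
    DL = HR_PIR / sqrt(1 + 1/N) for matching alpha/sidedness.
    """
    return r.sd * _t_quantile(r.n - 1, alpha, sided)


def idp(r: ReplicateSet) -> float:
    """Initial demonstration of precision: replicate RSD percent at mid level."""
    if r.mean == 0:
        raise ValueError("IDP undefined for zero-mean replicates")
    return r.sd / r.mean * 100.0


def ida(r: ReplicateSet) -> float:
    """Initial demonstration of accuracy: mean recovery percent at mid level."""
    return r.mean / r.actual_ngL * 100.0


def pg_on_column(conc_ngL: float, design: StudyDesign = StudyDesign()) -> float:
    """Convert a calibration-stock concentration to injected picograms."""
    if conc_ngL < 0:
        raise ValueError("concentration must be non-negative")
    return design.on_column_pg(conc_ngL)


def trim_replicates(concs: Sequence[float], target_n: int = 7) -> Tuple[float, ...]:
    """Optional trimming rule: drop the largest |z| residual until target_n remain."""
    vals = list(map(float, concs))
    while len(vals) > target_n:
        mu = float(np.mean(vals))
        vals.remove(max(vals, key=lambda v: abs(v - mu)))
    return tuple(vals)


def replicate_sets_from_concs(concs: pd.DataFrame) -> Dict[str, Dict[float, ReplicateSet]]:
    """Group a back-calculated concentration table into per-level replicate sets.

    Expects columns replicate_id, level_ngL, compound, conc_ngL (the output
    of ``quant.calibrate_study`` or an external back-calculation export).
    """
    req = {"replicate_id", "level_ngL", "compound", "conc_ngL"}
    if not req <= set(concs.columns):
        raise ValueError(f"concentration table must have columns {sorted(req)}")
    out: Dict[str, Dict[float, ReplicateSet]] = {}
    for (cid, level), grp in concs.groupby(["compound", "level_ngL"]):
        out.setdefault(cid, {})[float(level)] = ReplicateSet(
            cid, float(level), tuple(grp["conc_ngL"].astype(float))
        )
    return out


def build_validation_report(
    concs: pd.DataFrame,
    design: StudyDesign = StudyDesign(),
    alpha: float = 0.01,
    sided: str = "two",
    min_replicates: int = 7,
    compounds: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, Dict[str, MrlResult]]:
    """Per-compound MRL/DL/IDP/IDA table from back-calculated concentrations.

    Returns ``(report, details)``; ``report`` has one row per compound with
    columns ``compound, mrl_ngL, mrl_pg_on_column, dl_ngL, dl_pg_on_column,
    idp_pct, ida_pct``; ``details`` holds the per-level PIR results.  A
    compound lacking mid-level data gets blank IDP/IDA with a warning.
    """
    sets = replicate_sets_from_concs(concs)
    ids = list(compounds) if compounds is not None else sorted(sets)
    rows = []
    details: Dict[str, MrlResult] = {}
    for cid in ids:
        levels = sets.get(cid, {})
        if not levels:
            warnings.warn(f"{cid}: no replicate data; row skipped")
            continue
        mrl = determine_mrl(list(levels.values()), alpha, sided, min_replicates)
        details[cid] = mrl
        dl = None
        if mrl.defined:
            dl = detection_limit(levels[mrl.mrl_ngL], alpha, sided)
        mid = levels.get(float(design.qc_level_ngL))
        if mid is None:
            warnings.warn(f"{cid}: no replicates at the {design.qc_level_ngL} ng/L "
                          "mid level; IDP/IDA left blank")
            idp_v = ida_v = None
        else:
            idp_v = idp(mid)
            ida_v = ida(mid)
        rows.append(
            {
                "compound": cid,
                "mrl_ngL": mrl.mrl_ngL,
                "mrl_pg_on_column": None if mrl.mrl_ngL is None else pg_on_column(mrl.mrl_ngL, design),
                "dl_ngL": dl,
                "dl_pg_on_column": None if dl is None else pg_on_column(dl, design),
                "idp_pct": idp_v,
                "ida_pct": ida_v,
            }
        )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return report, details


def format_report(report: pd.DataFrame) -> pd.DataFrame:
    """Round report columns for printing: DL 2 dp, pg 3 dp, IDP/IDA 2 dp."""
    out = report.copy()
    out["dl_ngL"] = out["dl_ngL"].round(2)
    out["mrl_pg_on_column"] = out["mrl_pg_on_column"].round(3)
    out["dl_pg_on_column"] = out["dl_pg_on_column"].round(3)
    out["idp_pct"] = out["idp_pct"].round(2)
    out["ida_pct"] = out["ida_pct"].round(2)
    return out
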