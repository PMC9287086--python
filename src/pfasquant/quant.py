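"""Exact-mass XIC extraction, peak integration, spectral verification and
internal-standard ratio calibration.

Quantitation follows the MS1 route: the extracted ion chromatogram of each
analyte's theoretical precursor m/z (within a ppm window) is integrated and
ratioed against its assigned internal standard; a weighted least-squares line
of ratio versus concentration provides back-calculation.  MS2 data serve
qualitative verification through Skyline-style dot-product scores: ``dotp``
compares an observed fragment spectrum against the registry template on
square-root intensities, ``idotp`` compares the observed MS1 isotope envelope
against the theoretical pattern.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chem
from .chem import IsotopePattern
from .registry import CompoundRegistry
from .synth import ScanStream

__all__ = [
    "XIC",
    "PeakArea",
    "CalibrationCurve",
    "SpectrumMatchScore",
    "EmptyXICError",
    "CalibrationError",
    "extract_xic",
    "integrate_peak",
    "score_idotp",
    "score_dotp",
    "fit_calibration",
    "back_calculate",
    "quantify_stream",
    "calibrate_study",
    "cross_validate_calibration",
    "isotopologue_crosstalk_shares",
]


class EmptyXICError(ValueError):
    """No MS1 scans of the requested polarity inside the RT window."""


class CalibrationError(ValueError):
    """Calibration cannot be fitted (degenerate level design, zero slope...)."""


@dataclass
class XIC:
    """Extracted ion chromatogram: summed intensity inside an m/z window."""

    compound_id: str
    rt_min: np.ndarray
    intensity: np.ndarray
    mz: float
    tol_ppm: float

    def __post_init__(self) -> None:
        self.rt_min = np.asarray(self.rt_min, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt_min.size != self.intensity.size:
            raise ValueError("rt and intensity must have equal length")
        if self.rt_min.size and np.any(np.diff(self.rt_min) <= 0):
            raise ValueError("XIC retention times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("XIC intensities must be non-negative")

    def __len__(self) -> int:
        return self.rt_min.size


@dataclass(frozen=True)
class PeakArea:
    compound_id: str
    area: float
    apex_rt: float
    rt_lo: float
    rt_hi: float
    points_across_peak: int
    detected: bool = True


@dataclass
class CalibrationCurve:
    """Weighted least-squares line of area ratio on concentration."""

    compound_id: str
    is_id: str
    weighting: str
    slope: float
    intercept: float
    r_squared: float
    pairs: List[Tuple[float, float]] = field(default_factory=list)


@dataclass(frozen=True)
class SpectrumMatchScore:
    dotp: float
    idotp: float

    def __post_init__(self) -> None:
        if not (0 <= self.dotp <= 1 and 0 <= self.idotp <= 1):
            raise ValueError("match scores must lie in [0, 1]")


def extract_xic(
    stream: ScanStream,
    mz: float,
    tol_ppm: float,
    rt_window: Tuple[float, float],
    polarity: str = "-",
    compound_id: str = "",
) -> XIC:
    """Sum centroid intensities inside ``mz_window(mz, tol_ppm)`` per MS1 scan.

    Only MS1 scans of the requested polarity become sample points; other
    polarities and MS2 scans are skipped entirely (no zero-filling across
    polarity gaps).  A scan with no centroid in the window contributes 0.
    """
    if tol_ppm <= 0:
        raise ValueError("ppm tolerance must be positive")
    lo_rt, hi_rt = rt_window
    lo, hi = chem.mz_window(mz, tol_ppm)
    rts, intens = [], []
    for scan in stream.ms1(polarity):
        if not (lo_rt <= scan.rt_min <= hi_rt):
            continue
        mask = (scan.mz >= lo) & (scan.mz <= hi)
        rts.append(scan.rt_min)
        intens.append(float(scan.intensity[mask].sum()))
    if not rts:
        raise EmptyXICError(
            f"no {polarity} MS1 scans in RT window [{lo_rt}, {hi_rt}] min"
        )
    return XIC(compound_id, np.array(rts), np.array(intens), mz, tol_ppm)


def integrate_peak(
    xic: XIC,
    expected_rt: float,
    max_shift: float = 0.5,
    boundary_fraction: float = 0.02,
) -> PeakArea:
    """Trapezoidal peak integration around the expected retention time.

    The apex is the maximum point within ``expected_rt ± max_shift``;
    boundaries extend outward until the trace falls below
    ``boundary_fraction x apex``.  A valley is crossed (bimodal breakthrough
    peaks integrate as one) as long as it stays above the threshold.  An apex
    of zero intensity yields a flagged not-detected result with area 0.
    """
    if len(xic) == 0:
        raise EmptyXICError("cannot integrate an empty XIC")
    rt, y = xic.rt_min, xic.intensity
    in_win = np.flatnonzero(np.abs(rt - expected_rt) <= max_shift)
    if in_win.size == 0:
        in_win = np.array([int(np.argmin(np.abs(rt - expected_rt)))])
    apex_idx = in_win[int(np.argmax(y[in_win]))]
    apex = y[apex_idx]
    if apex <= 0:
        return PeakArea(xic.compound_id, 0.0, rt[apex_idx], rt[apex_idx],
                        rt[apex_idx], 0, detected=False)
    cut = boundary_fraction * apex
    lo = apex_idx
    while lo > 0 and y[lo - 1] >= cut:
        lo -= 1
    hi = apex_idx
    while hi < y.size - 1 and y[hi + 1] >= cut:
        hi += 1
    sl = slice(lo, hi + 1)
    area = float(np.trapezoid(y[sl], rt[sl]))
    return PeakArea(xic.compound_id, area, float(rt[apex_idx]), float(rt[lo]),
                    float(rt[hi]), hi - lo + 1, detected=True)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(np.dot(a, b) / (na * nb), 0.0, 1.0))


def score_idotp(observed: Sequence[float], predicted: IsotopePattern) -> float:
    """Cosine of the observed vs theoretical isotope envelope (plain intensities)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted.abundance, dtype=float)
    if obs.size != pred.size:
        raise ValueError(
            f"observed envelope has {obs.size} peaks, predicted {pred.size}"
        )
    if not obs.any():
        warnings.warn("all-zero observed isotope envelope; idotp = 0")
        return 0.0
    return _cosine(obs, pred)


def score_dotp(
    observed_mz: Sequence[float],
    observed_intensity: Sequence[float],
    template: Sequence[Tuple[float, float]],
    tol_ppm: float = 20.0,
    sqrt_transform: bool = True,
) -> float:
    """Skyline-style library dot product of an MS2 spectrum vs a template.

    Observed centroids within ``tol_ppm`` of each template fragment are
    summed; the cosine is taken on square-root-transformed intensities by
    default (``sqrt_transform=False`` gives the plain-intensity cosine).
    Template fragments with no observed match contribute zeros.
    """
    if not len(template):
        raise ValueError("empty fragment template")
    omz = np.asarray(observed_mz, dtype=float)
    oint = np.asarray(observed_intensity, dtype=float)
    matched = np.zeros(len(template))
    for i, (fmz, _ab) in enumerate(template):
        lo, hi = chem.mz_window(fmz, tol_ppm)
        mask = (omz >= lo) & (omz <= hi)
        matched[i] = oint[mask].sum()
    tmpl = np.array([ab for _mz, ab in template], dtype=float)
    if sqrt_transform:
        matched = np.sqrt(matched)
        tmpl = np.sqrt(tmpl)
    return _cosine(matched, tmpl)


_WEIGHTS = {
    "none": lambda x: np.ones_like(x),
    "1/x": lambda x: 1.0 / x,
    "1/x^2": lambda x: 1.0 / x**2,
    "1/x2": lambda x: 1.0 / x**2,
}


def fit_calibration(
    pairs: Sequence[Tuple[float, float]],
    weighting: str = "1/x",
    compound_id: str = "",
    is_id: str = "",
) -> CalibrationCurve:
    """Weighted least squares of area ratio on concentration level.

    ``weighting`` is one of ``none``, ``1/x``, ``1/x^2`` (x = level).  R² is
    computed on the weighted fit: 1 - SS_res / SS_tot with both sums taken
    under the weights and the total sum around the weighted mean.
    """
    pairs = [(float(x), float(y)) for x, y in pairs]
    for x, y in pairs:
        if not (math.isfinite(x) and math.isfinite(y)):
            raise CalibrationError(f"non-finite calibration pair ({x}, {y})")
    if weighting not in _WEIGHTS:
        raise CalibrationError(f"unknown weighting {weighting!r}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.unique(x).size < 2:
        raise CalibrationError("need >= 2 distinct concentration levels")
    w = _WEIGHTS[weighting](x)
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (slope * x + intercept)
    ss_res = (w * resid**2).sum()
    ss_tot = (w * (y - ybar) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return CalibrationCurve(compound_id, is_id, weighting, float(slope),
                            float(intercept), float(min(r2, 1.0)), pairs)


def back_calculate(curve: CalibrationCurve, area_ratio: float) -> float:
    """Invert the calibration line; may legitimately return a negative value."""
    if curve.slope == 0:
        raise CalibrationError("cannot back-calculate with zero slope")
    return (area_ratio - curve.intercept) / curve.slope


# ---------------------------------------------------------------------------
# stream-level and study-level drivers


def isotopologue_crosstalk_shares(
    registry: CompoundRegistry,
    tol_ppm: float = 5.0,
    isotope_threshold: float = 5e-3,
    coelution_min: float = 0.1,
) -> Dict[str, List[Tuple[str, float]]]:
    """Predicted isotope-envelope cross-talk between coeluting compounds.

    A lightly labeled internal standard (e.g. a +2 13C2 label) sits only
    ~2.007 Da above its analyte, exactly where the analyte's two-13C
    isotopologue falls: the analyte envelope bleeds into the standard's
    extraction window.  For every ordered pair of coeluting, same-polarity
    compounds this returns the fraction of the source's measured (own-window)
    area expected inside the target's window, keyed by target id.
    """
    comps = [r for r in registry.measurable() if r.element_counts is not None]
    patterns = {}
    for rec in comps:
        patterns[rec.id] = chem.isotope_pattern(
            rec.element_counts, threshold=isotope_threshold,
            charge_species=rec.ion_species,
        )

    def share_in(pat: IsotopePattern, center: float) -> float:
        lo, hi = chem.mz_window(center, tol_ppm)
        return sum(ab for mz, ab in pat.peaks if lo <= mz <= hi)

    out: Dict[str, List[Tuple[str, float]]] = {}
    for target in comps:
        for source in comps:
            if source.id == target.id or source.polarity != target.polarity:
                continue
            if abs(source.rt_min - target.rt_min) > coelution_min:
                continue
            pat = patterns[source.id]
            own = share_in(pat, source.precursor_mz)
            bleed = share_in(pat, target.precursor_mz)
            if bleed > 0 and own > 0:
                out.setdefault(target.id, []).append((source.id, bleed / own))
    return out


def quantify_stream(
    stream: ScanStream,
    registry: CompoundRegistry,
    tol_ppm: float = 5.0,
    max_shift: float = 0.5,
    boundary_fraction: float = 0.02,
    rt_halfwidth: float = 1.0,
    interference_correction: bool = True,
    isotope_threshold: float = 5e-3,
    ms_level: int = 1,
) -> pd.DataFrame:
    """Integrate every measurable registry compound in one scan stream.

    Returns a DataFrame with compound, area, apex_rt, points_across_peak,
    detected.  Compounds whose extraction window holds no scans get a
    not-detected row (area 0) so downstream statistics see a complete grid.

    With ``interference_correction`` (default on) the predicted isotopologue
    cross-talk of coeluting compounds is subtracted — essential for +2-labeled
    internal standards, whose extraction window receives the analyte's
    two-13C isotopologue.

    ``ms_level=2`` quantifies in the MS2 dimension instead: the chromatogram
    is the summed fragment intensity of the MS2 scans triggered for each
    compound (the triple-quadrupole-style alternative to MS1 areas).
    """
    if ms_level not in (1, 2):
        raise ValueError("ms_level must be 1 or 2")
    rows = []
    for rec in registry.measurable():
        window = (rec.rt_min - rt_halfwidth, rec.rt_min + rt_halfwidth)
        if ms_level == 2:
            pts = [
                (s.rt_min, float(s.intensity.sum()))
                for s in stream.ms2(rec.id)
                if window[0] <= s.rt_min <= window[1]
            ]
            # MS2 scans can share a retention time with their MS1 trigger
            pts = sorted({rt: i for rt, i in pts}.items())
            if not pts:
                rows.append((rec.id, rec.is_internal_standard, 0.0, rec.rt_min, 0, False))
                continue
            xic = XIC(rec.id, np.array([p[0] for p in pts]),
                      np.array([p[1] for p in pts]), rec.precursor_mz, tol_ppm)
        else:
            try:
                xic = extract_xic(stream, rec.precursor_mz, tol_ppm, window,
                                  polarity=rec.polarity, compound_id=rec.id)
            except EmptyXICError:
                rows.append((rec.id, rec.is_internal_standard, 0.0, rec.rt_min, 0, False))
                continue
        peak = integrate_peak(xic, rec.rt_min, max_shift, boundary_fraction)
        rows.append((rec.id, rec.is_internal_standard, peak.area, peak.apex_rt,
                     peak.points_across_peak, peak.detected))
    df = pd.DataFrame(
        rows,
        columns=["compound", "is_internal_standard", "area", "apex_rt",
                 "points_across_peak", "detected"],
    )
    if interference_correction and ms_level == 1:
        shares = isotopologue_crosstalk_shares(registry, tol_ppm, isotope_threshold)
        raw = dict(zip(df["compound"], df["area"]))
        for target, sources in shares.items():
            if target not in raw:
                continue
            corrected = raw[target] - sum(raw.get(src, 0.0) * s for src, s in sources)
            df.loc[df["compound"] == target, "area"] = max(corrected, 0.0)
    return df


def calibrate_study(
    areas: pd.DataFrame,
    registry: CompoundRegistry,
    weighting: str = "1/x",
    cal_replicate: int = 1,
) -> Tuple[Dict[str, CalibrationCurve], pd.DataFrame]:
    """Fit per-analyte calibration curves and back-calculate the QC replicates.

    One replicate (``cal_replicate``) serves as the calibration curve; all
    other replicates are treated as unknowns and back-calculated at every
    level.  Returns ``(curves, concs)`` where ``concs`` has columns
    replicate_id, level_ngL, compound, conc_ngL.
    """
    req = {"replicate_id", "level_ngL", "compound", "area"}
    if not req <= set(areas.columns):
        raise ValueError(f"area table must have columns {sorted(req)}")
    wide = areas.pivot_table(index=["replicate_id", "level_ngL"],
                             columns="compound", values="area")
    curves: Dict[str, CalibrationCurve] = {}
    conc_rows = []
    for rec in registry.analytes:
        if rec.id not in wide.columns:
            continue
        is_id = rec.surrogate_is
        if is_id not in wide.columns:
            warnings.warn(f"{rec.id}: internal standard {is_id} absent from area table")
            continue
        ratio = wide[rec.id] / wide[is_id]
        cal = ratio.loc[cal_replicate]
        pairs = [(lvl, r) for lvl, r in cal.items() if np.isfinite(r)]
        dropped = len(cal) - len(pairs)
        if dropped:
            warnings.warn(f"{rec.id}: dropped {dropped} pair(s) with zero IS area")
        curve = fit_calibration(pairs, weighting, rec.id, is_id)
        curves[rec.id] = curve
        qc = ratio.drop(index=cal_replicate, level=0)
        for (rep, lvl), r in qc.items():
            if np.isfinite(r):
                conc_rows.append((rep, lvl, rec.id, back_calculate(curve, r)))
    concs = pd.DataFrame(conc_rows,
                         columns=["replicate_id", "level_ngL", "compound", "conc_ngL"])
    return curves, concs


def cross_validate_calibration(
    areas: pd.DataFrame,
    registry: CompoundRegistry,
    weighting: str = "1/x",
) -> pd.DataFrame:
    """Rotate the choice of calibration replicate and report the fit spread.

    Any replicate could serve as "the" calibration curve; this fits one curve
    per candidate replicate and summarizes, per analyte, the spread of slope
    and R² across choices (columns: compound, n_replicates, slope_mean,
    slope_rsd_pct, r2_min, r2_max).
    """
    reps = sorted(areas["replicate_id"].unique())
    records: Dict[str, List[CalibrationCurve]] = {}
    for rep in reps:
        curves, _ = calibrate_study(areas, registry, weighting, cal_replicate=rep)
        for cid, curve in curves.items():
            records.setdefault(cid, []).append(curve)
    rows = []
    for cid, curves_ in sorted(records.items()):
        slopes = np.array([c.slope for c in curves_])
        r2s = np.array([c.r_squared for c in curves_])
        rows.append((cid, len(curves_), slopes.mean(),
                     100 * slopes.std(ddof=1) / slopes.mean() if len(slopes) > 1 else 0.0,
                     r2s.min(), r2s.max()))
    return pd.DataFrame(rows, columns=["compound", "n_replicates", "slope_mean",
                                       "slope_rsd_pct", "r2_min", "r2_max"])
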