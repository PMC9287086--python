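"""Synthetic instrument: replicate calibration studies and centroided scan streams.

This module stands in for the LC-MS instrument.  It produces two kinds of
output, both with full ground truth recorded for parameter recovery:

* peak-area tables for replicate calibration studies (the input to
  calibration and the EPA-style validation statistics), and
* centroided MS1/MS2 scan streams with inclusion-list triggering, dynamic
  exclusion, a timed positive-polarity window for the zwitterions, and
  Gaussian / exponentially-modified-Gaussian / bimodal "breakthrough"
  chromatographic peak shapes.

Area noise is multiplicative lognormal (areas stay positive and the relative
spread is concentration-independent), optionally with an additive floor that
dominates at the lowest levels.  Analyte and internal-standard noise can be
correlated: ratio calibration cancels the shared part, which is exactly the
mechanism that makes a well-chosen surrogate internal standard work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chem
from .registry import CompoundRegistry, CompoundRecord

__all__ = [
    "StudyDesign",
    "ResponseModel",
    "NoiseModel",
    "PeakShape",
    "PeakModel",
    "Scan",
    "ScanStream",
    "AcquisitionConfig",
    "InclusionEntry",
    "simulate_replicate_study",
    "simulate_scan_stream",
    "make_surrogate_scenario",
    "default_peak_models",
]

AREA_COLUMNS = ["replicate_id", "level_ngL", "compound", "is_internal_standard", "area"]


@dataclass(frozen=True)
class StudyDesign:
    """Replicate calibration study layout and sample-preparation arithmetic.

    Calibrator and internal-standard working solutions are mixed 9:1 by
    volume (900 µL + 100 µL), so every analyte is diluted by 0.9 and the
    internal standard by 0.1 before the 100 µL injection.  ``pg on column``
    is therefore ``conc[ng/L] x 0.9 x 1e-4 L x 1000 pg/ng = conc x 0.09``
    under the defaults.
    """

    levels_ngL: Tuple[float, ...] = (2.0, 5.0, 10.0, 50.0, 100.0, 500.0, 1000.0, 2000.0)
    n_replicates: int = 10
    is_conc_ngL: float = 10_000.0
    vol_calibrator_uL: float = 900.0
    vol_is_uL: float = 100.0
    injection_volume_uL: float = 100.0
    qc_level_ngL: float = 500.0

    def __post_init__(self) -> None:
        lv = self.levels_ngL
        if not lv or any(b <= a for a, b in zip(lv, lv[1:])) or lv[0] <= 0:
            raise ValueError("calibration levels must be positive and strictly increasing")
        if self.n_replicates < 8:
            raise ValueError("need >= 8 replicates (one curve + >=7 QC replicates)")
        if not (0 < self.dilution_factor < 1):
            raise ValueError("dilution factor must lie in (0, 1)")

    @property
    def dilution_factor(self) -> float:
        return self.vol_calibrator_uL / (self.vol_calibrator_uL + self.vol_is_uL)

    @property
    def is_dilution_factor(self) -> float:
        return self.vol_is_uL / (self.vol_calibrator_uL + self.vol_is_uL)

    def on_column_pg(self, conc_ngL: float) -> float:
        """Injected analyte mass for a pre-mix calibrator concentration."""
        return conc_ngL * self.dilution_factor * self.injection_volume_uL * 1e-6 * 1000.0

    def is_on_column_pg(self) -> float:
        return self.is_conc_ngL * self.is_dilution_factor * self.injection_volume_uL * 1e-6 * 1000.0


@dataclass
class ResponseModel:
    """Per-compound detector response and analyte-IS noise co-variation.

    ``correlation`` maps each analyte to the correlation between its area
    noise and its assigned internal standard's (factor construction, always
    a valid joint distribution).  Alternatively ``corr_matrix`` gives a full
    compound-by-compound correlation matrix (used by the surrogate-scenario
    generator, where every analyte-IS pair has its own correlation).
    """

    response_factors: Dict[str, float]
    saturation: Dict[str, float] = field(default_factory=dict)
    correlation: Dict[str, float] = field(default_factory=dict)
    corr_matrix: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        for cid, rf in self.response_factors.items():
            if rf <= 0:
                raise ValueError(f"response factor for {cid} must be positive")
        for cid, rho in self.correlation.items():
            if not (0.0 <= rho <= 1.0):
                raise ValueError(f"correlation for {cid} must lie in [0, 1]")

    def rf(self, cid: str) -> float:
        return self.response_factors[cid]

    @classmethod
    def flat(cls, registry: CompoundRegistry, rf: float = 1000.0, rho: float = 0.0) -> "ResponseModel":
        comps = registry.measurable()
        return cls(
            response_factors={r.id: rf for r in comps},
            correlation={r.id: rho for r in comps if r.role == "analyte"},
        )


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic imperfections applied by the synthetic instrument."""

    area_cv: float = 0.05            # proportional (lognormal) area CV
    area_floor: float = 0.0          # additive area noise sd, area units
    mz_jitter_ppm: float = 1.0       # centroid mass error sd
    baseline_peaks_per_scan: float = 20.0
    baseline_intensity: float = 50.0  # mean of exponential baseline intensities
    rt_jitter_sd_min: float = 0.0

    def __post_init__(self) -> None:
        for name in ("area_cv", "area_floor", "mz_jitter_ppm",
                     "baseline_peaks_per_scan", "baseline_intensity", "rt_jitter_sd_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class PeakShape(Enum):
    GAUSSIAN = "gaussian"
    EMG = "emg"
    BIMODAL = "bimodal"


@dataclass(frozen=True)
class PeakModel:
    """Chromatographic elution profile with unit area.

    BIMODAL models injection-bolus "breakthrough" of hydrophilic early
    eluters: a minimally retained satellite peak ``delta_rt`` ahead of the
    retained peak carrying ``split_fraction`` of the analyte.
    """

    apex_rt: float
    width_sd: float = 0.05
    shape: PeakShape = PeakShape.GAUSSIAN
    emg_tau: float = 0.08
    split_fraction: float = 0.3
    delta_rt: float = 0.15

    def __post_init__(self) -> None:
        if self.width_sd <= 0:
            raise ValueError("peak width must be positive")
        if self.shape is PeakShape.BIMODAL and not (0 < self.split_fraction < 1):
            raise ValueError("bimodal split fraction must lie in (0, 1)")

    def profile(self, t: np.ndarray) -> np.ndarray:
        """Unit-area intensity profile evaluated at times ``t`` (minutes)."""
        t = np.asarray(t, dtype=float)
        s = self.width_sd
        if self.shape is PeakShape.GAUSSIAN:
            return np.exp(-0.5 * ((t - self.apex_rt) / s) ** 2) / (s * math.sqrt(2 * math.pi))
        if self.shape is PeakShape.EMG:
            from scipy.stats import exponnorm  # EMG with tail constant K*scale
            return exponnorm.pdf(t, self.emg_tau / s, loc=self.apex_rt, scale=s)
        # bimodal: breakthrough satellite + retained main peak
        g = lambda mu: np.exp(-0.5 * ((t - mu) / s) ** 2) / (s * math.sqrt(2 * math.pi))
        return self.split_fraction * g(self.apex_rt - self.delta_rt) + (
            1 - self.split_fraction
        ) * g(self.apex_rt)


def default_peak_models(registry: CompoundRegistry, width_sd: float = 0.05) -> Dict[str, PeakModel]:
    """Gaussian peaks everywhere except registry-flagged early eluters (bimodal)."""
    models = {}
    for rec in registry.measurable():
        shape = PeakShape.BIMODAL if rec.early_eluter else PeakShape.GAUSSIAN
        models[rec.id] = PeakModel(apex_rt=rec.rt_min, width_sd=width_sd, shape=shape)
    return models


def _noise_transform(z: np.ndarray, cv: float) -> np.ndarray:
    """Map standard-normal draws to mean-1 lognormal factors with RSD ~= cv."""
    if cv == 0:
        return np.ones_like(z)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(sigma * z - 0.5 * sigma * sigma)


def _draw_correlated(rng: np.random.Generator, comps: Sequence[CompoundRecord],
                     response: ResponseModel, n: int) -> np.ndarray:
    """n draws of a standard-normal vector over compounds with the configured correlation."""
    ids = [c.id for c in comps]
    k = len(ids)
    if response.corr_matrix is not None:
        corr = response.corr_matrix.loc[ids, ids].to_numpy()
        lower = np.linalg.cholesky(corr + 1e-10 * np.eye(k))
        return rng.standard_normal((n, k)) @ lower.T
    # factor construction: each IS is its own factor; analytes load on their IS
    idx = {cid: i for i, cid in enumerate(ids)}
    z = rng.standard_normal((n, k))
    out = np.empty_like(z)
    for i, c in enumerate(comps):
        if c.role == "analyte" and c.surrogate_is in idx:
            rho = response.correlation.get(c.id, 0.0)
            j = idx[c.surrogate_is]
            out[:, i] = rho * z[:, j] + math.sqrt(max(0.0, 1 - rho * rho)) * z[:, i]
        else:
            out[:, i] = z[:, i]
    return out


def simulate_replicate_study(
    design: StudyDesign,
    registry: CompoundRegistry,
    response: ResponseModel,
    noise: NoiseModel,
    seed: int,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a replicate calibration study as a peak-area table.

    Returns ``(areas, truth)``.  ``areas`` has one row per
    (replicate, level, compound) with columns replicate_id, level_ngL,
    compound, is_internal_standard, area.  ``truth`` additionally records the
    pre-dilution concentration, the injected on-column amount (pg) and the
    noiseless area.  Deterministic for a fixed seed.
    """
    comps = registry.measurable()
    missing = [
        c.id for c in comps
        if c.role == "analyte" and (not c.surrogate_is or c.surrogate_is not in registry)
    ]
    if missing:
        raise ValueError(f"analytes without an assigned internal standard: {missing}")
    absent_rf = [c.id for c in comps if c.id not in response.response_factors]
    if absent_rf:
        raise ValueError(f"compounds without a response factor: {absent_rf}")

    rng = np.random.default_rng(seed)
    rows: List[tuple] = []
    truth_rows: List[tuple] = []
    n_cells = design.n_replicates * len(design.levels_ngL)
    z_all = _draw_correlated(rng, comps, response, n_cells)
    floor_all = (
        rng.normal(0.0, noise.area_floor, size=(n_cells, len(comps)))
        if noise.area_floor > 0
        else np.zeros((n_cells, len(comps)))
    )
    cell = 0
    for rep in range(1, design.n_replicates + 1):
        for level in design.levels_ngL:
            factors = _noise_transform(z_all[cell], noise.area_cv)
            for i, c in enumerate(comps):
                is_is = c.role == "internal_standard"
                conc = design.is_conc_ngL if is_is else level
                pg = design.is_on_column_pg() if is_is else design.on_column_pg(level)
                clean = response.rf(c.id) * pg
                cap = response.saturation.get(c.id)
                if cap is not None:
                    clean = min(clean, cap)
                area = max(clean * factors[i] + floor_all[cell, i], 0.0)
                rows.append((rep, level, c.id, is_is, area))
                truth_rows.append((rep, level, c.id, is_is, conc, pg, clean))
            cell += 1
    areas = pd.DataFrame(rows, columns=AREA_COLUMNS)
    truth = pd.DataFrame(
        truth_rows,
        columns=AREA_COLUMNS[:4] + ["conc_ngL", "on_column_pg", "noiseless_area"],
    )
    return areas, truth


def make_surrogate_scenario(
    registry: CompoundRegistry,
    base_rf: float,
    decay_rate: float,
    seed: int,
    rf_spread_cv: float = 0.3,
) -> ResponseModel:
    """Response model whose analyte-IS noise correlation decays with ΔF.

    Every pair of compounds ``i, j`` gets noise correlation
    ``rho_ij = exp(-decay_rate * |F_i - F_j|)`` where ``F`` is the fluorine
    count: an exponential (Ornstein-Uhlenbeck) kernel over the fluorine axis,
    which is positive semi-definite for any non-negative rate.  Calibration
    R² then degrades with fluorine-count mismatch between analyte and
    internal standard.  Response factors are drawn lognormally around
    ``base_rf`` so compounds differ in sensitivity.
    """
    if decay_rate < 0:
        raise ValueError("decay rate must be non-negative")
    comps = registry.measurable()
    ids = [c.id for c in comps]
    fl = np.array([c.fluorines if c.fluorines is not None else 0 for c in comps], dtype=float)
    corr = np.exp(-decay_rate * np.abs(fl[:, None] - fl[None, :]))
    rng = np.random.default_rng(seed)
    rfs = base_rf * _noise_transform(rng.standard_normal(len(ids)), rf_spread_cv)
    return ResponseModel(
        response_factors=dict(zip(ids, rfs)),
        corr_matrix=pd.DataFrame(corr, index=ids, columns=ids),
    )


# ---------------------------------------------------------------------------
# scan streams


@dataclass
class Scan:
    """One centroided scan."""

    rt_min: float
    polarity: str  # "+" or "-"
    ms_level: int  # 1 or 2
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    trigger_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz)
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]


@dataclass
class ScanStream:
    """Time-ordered centroided MS1/MS2 scans with trigger provenance."""

    scans: List[Scan] = field(default_factory=list)
    positive_window: Tuple[float, float] = (9.5, 11.5)

    def __post_init__(self) -> None:
        rts = [s.rt_min for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be non-decreasing")
        lo, hi = self.positive_window
        for s in self.scans:
            if s.polarity == "+" and not (lo <= s.rt_min <= hi):
                raise ValueError(
                    f"positive-polarity scan at {s.rt_min:.3f} min outside window [{lo}, {hi}]"
                )

    def __iter__(self):
        return iter(self.scans)

    def __len__(self) -> int:
        return len(self.scans)

    def ms1(self, polarity: Optional[str] = None) -> List[Scan]:
        return [
            s for s in self.scans
            if s.ms_level == 1 and (polarity is None or s.polarity == polarity)
        ]

    def ms2(self, trigger_id: Optional[str] = None) -> List[Scan]:
        return [
            s for s in self.scans
            if s.ms_level == 2 and (trigger_id is None or s.trigger_id == trigger_id)
        ]

    @property
    def rt_span(self) -> Tuple[float, float]:
        if not self.scans:
            raise ValueError("empty scan stream")
        return self.scans[0].rt_min, self.scans[-1].rt_min


@dataclass(frozen=True)
class InclusionEntry:
    """One targeted-mass-filter entry: detect this m/z in MS1, trigger MS2."""

    compound_id: str
    mz: float
    tol_ppm: float = 10.0
    polarity: str = "-"


@dataclass(frozen=True)
class AcquisitionConfig:
    """Scan-scheduling parameters of the synthetic instrument."""

    ms1_period_s: float = 1.0
    inclusion_list: Tuple[InclusionEntry, ...] = ()
    trigger_threshold: float = 1e4
    dynamic_exclusion_min: float = 0.0  # 0 disables dynamic exclusion
    positive_window: Tuple[float, float] = (9.5, 11.5)
    ms1_range: Tuple[float, float] = (50.0, 1500.0)
    ms2_base_intensity: float = 1e5
    ms2_noise_cv: float = 0.02
    gradient_span: Tuple[float, float] = (0.0, 20.0)

    @classmethod
    def from_registry(cls, registry: CompoundRegistry, tol_ppm: float = 10.0,
                      **kwargs) -> "AcquisitionConfig":
        entries = tuple(
            InclusionEntry(r.id, r.precursor_mz, tol_ppm, r.polarity)
            for r in registry.measurable()
        )
        return cls(inclusion_list=entries, **kwargs)


def simulate_scan_stream(
    registry: CompoundRegistry,
    amounts_pg: Dict[str, float],
    response: ResponseModel,
    peak_models: Dict[str, PeakModel],
    noise: NoiseModel,
    acq: AcquisitionConfig,
    seed: int,
    isotope_threshold: float = 5e-3,
) -> ScanStream:
    """Simulate one injection as a centroided scan stream.

    MS1 scans carry each visible compound's isotope envelope scaled by its
    chromatographic profile (total XIC area = response factor x on-column
    amount), plus random baseline centroids.  After an MS1 scan, every
    inclusion-list entry whose extraction window holds signal above the
    trigger threshold schedules an MS2 scan (fragment template, abundances
    independent of concentration) unless dynamically excluded.  Positive-mode
    scan events run only inside ``acq.positive_window``.  Compounds whose ion
    lies outside ``acq.ms1_range`` are invisible to both MS1 and triggering.
    """
    rng = np.random.default_rng(seed)
    t0, t1 = acq.gradient_span
    period_min = acq.ms1_period_s / 60.0
    lo_r, hi_r = acq.ms1_range

    visible: List[tuple] = []  # (record, pattern mzs, pattern abunds, total_area, model)
    for rec in registry.measurable():
        pg = amounts_pg.get(rec.id, 0.0)
        if pg <= 0:
            continue
        model = peak_models.get(rec.id)
        if model is None:
            continue
        if not (t0 <= rec.rt_min <= t1):
            import warnings
            warnings.warn(f"{rec.id}: retention time outside gradient span; skipped")
            continue
        if not (lo_r <= rec.precursor_mz <= hi_r):
            continue
        f = rec.element_counts
        if f is not None:
            pat = chem.isotope_pattern(f, threshold=isotope_threshold,
                                       charge_species=rec.ion_species)
            mzs = np.array(pat.mz)
            abund = np.array(pat.abundance)
            abund = abund / abund.sum()  # split total area across the envelope
        else:
            mzs = np.array([rec.precursor_mz])
            abund = np.array([1.0])
        if noise.rt_jitter_sd_min > 0:
            model = PeakModel(
                apex_rt=model.apex_rt + rng.normal(0.0, noise.rt_jitter_sd_min),
                width_sd=model.width_sd, shape=model.shape, emg_tau=model.emg_tau,
                split_fraction=model.split_fraction, delta_rt=model.delta_rt,
            )
        total_area = response.rf(rec.id) * pg
        visible.append((rec, mzs, abund, total_area, model))

    incl = [e for e in acq.inclusion_list]
    last_trigger: Dict[str, float] = {}
    scans: List[Scan] = []
    by_id = {rec.id: i for i, (rec, *_rest) in enumerate(visible)}

    def ms1_scan(t: float, polarity: str) -> Scan:
        mz_parts, int_parts = [], []
        for rec, mzs, abund, area, model in visible:
            if rec.polarity != polarity:
                continue
            # outside ~8 sigma (plus EMG tail / breakthrough offset) the
            # profile is numerically zero; skip the evaluation entirely
            reach = 8 * model.width_sd + model.delta_rt + 10 * model.emg_tau
            if abs(t - model.apex_rt) > reach:
                continue
            inten = area * model.profile(np.array([t]))[0]
            if inten <= 0:
                continue
            vals = inten * abund
            jit = 1 + rng.normal(0.0, noise.mz_jitter_ppm * 1e-6, size=mzs.size)
            mz_parts.append(mzs * jit)
            int_parts.append(vals)
        n_base = rng.poisson(noise.baseline_peaks_per_scan)
        if n_base:
            mz_parts.append(rng.uniform(lo_r, hi_r, n_base))
            int_parts.append(rng.exponential(noise.baseline_intensity, n_base))
        if mz_parts:
            mz = np.concatenate(mz_parts)
            inten = np.concatenate(int_parts)
        else:
            mz = np.empty(0)
            inten = np.empty(0)
        return Scan(t, polarity, 1, mz, inten)

    def maybe_trigger(scan: Scan, t: float) -> List[Scan]:
        out = []
        for entry in incl:
            if entry.polarity != scan.polarity:
                continue
            if not (lo_r <= entry.mz <= hi_r):
                continue
            if acq.dynamic_exclusion_min > 0:
                last = last_trigger.get(entry.compound_id)
                if last is not None and t - last < acq.dynamic_exclusion_min:
                    continue
            lo, hi = chem.mz_window(entry.mz, entry.tol_ppm)
            mask = (scan.mz >= lo) & (scan.mz <= hi)
            if scan.intensity[mask].sum() < acq.trigger_threshold:
                continue
            rec = registry[entry.compound_id]
            if not rec.fragments:
                continue
            fr_mz = np.array([m for m, _ in rec.fragments])
            fr_ab = np.array([a for _, a in rec.fragments])
            inten = acq.ms2_base_intensity * fr_ab * _noise_transform(
                rng.standard_normal(fr_ab.size), acq.ms2_noise_cv
            )
            jit = 1 + rng.normal(0.0, noise.mz_jitter_ppm * 1e-6, size=fr_mz.size)
            out.append(Scan(t, scan.polarity, 2, fr_mz * jit, inten,
                            precursor_mz=entry.mz, trigger_id=entry.compound_id))
            last_trigger[entry.compound_id] = t
        return out

    pos_lo, pos_hi = acq.positive_window
    t = t0
    while t <= t1 + 1e-9:
        neg = ms1_scan(t, "-")
        scans.append(neg)
        scans.extend(maybe_trigger(neg, t))
        if pos_lo <= t <= pos_hi:
            tp = t + period_min / 2
            if pos_lo <= tp <= pos_hi:
                pos = ms1_scan(tp, "+")
                scans.append(pos)
                scans.extend(maybe_trigger(pos, tp))
        t += period_min
    return ScanStream(scans, positive_window=acq.positive_window)
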