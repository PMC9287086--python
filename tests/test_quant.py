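"""XIC extraction, integration, spectral scores and ratio calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfasquant import chem, synth
from pfasquant.chem import IonSpecies, isotope_pattern, parse_formula
from pfasquant.quant import (
    XIC,
    CalibrationError,
    EmptyXICError,
    back_calculate,
    extract_xic,
    fit_calibration,
    integrate_peak,
    quantify_stream,
    score_dotp,
    score_idotp,
)
from pfasquant.registry import load_default_registry
from pfasquant.synth import (
    AcquisitionConfig,
    NoiseModel,
    ResponseModel,
    Scan,
    ScanStream,
    simulate_scan_stream,
)


def make_stream(scans):
    return ScanStream(scans, positive_window=(9.5, 11.5))


class TestExtractXic:
    def test_single_gaussian_apex_near_truth(self):
        reg = load_default_registry()
        resp = ResponseModel.flat(reg, rf=1e5)
        noise = NoiseModel(area_cv=0, baseline_peaks_per_scan=0, mz_jitter_ppm=0)
        acq = AcquisitionConfig.from_registry(reg, gradient_span=(8.0, 9.0), ms1_period_s=0.5)
        stream = simulate_scan_stream(
            reg, {"6:2 FTS": 0.9}, resp, synth.default_peak_models(reg), noise, acq, seed=1
        )
        xic = extract_xic(stream, 426.9674, 5.0, (8.0, 9.0))
        apex_rt = xic.rt_min[np.argmax(xic.intensity)]
        assert apex_rt == pytest.approx(8.5, abs=0.5 / 60 / 2 + 1e-9)

    def test_coeluting_near_isobar_excluded_at_3ppm(self):
        # two coeluting centroids 3.98 ppm apart: tight window keeps only one
        mz_a, mz_b = 426.9674, 426.9657
        scans = [
            Scan(8.0 + i * 0.01, "-", 1, np.array([mz_b, mz_a]), np.array([500.0, 1000.0]))
            for i in range(5)
        ]
        stream = make_stream(scans)
        tight = extract_xic(stream, mz_a, 3.0, (7.9, 8.1))
        loose = extract_xic(stream, mz_a, 5.0, (7.9, 8.1))
        assert np.allclose(tight.intensity, 1000.0)
        assert np.allclose(loose.intensity, 1500.0)

    def test_no_matching_centroids_gives_zero_trace(self):
        scans = [Scan(1.0 + i * 0.1, "-", 1, np.array([100.0]), np.array([5.0])) for i in range(4)]
        xic = extract_xic(make_stream(scans), 400.0, 5.0, (0.9, 1.5))
        assert np.allclose(xic.intensity, 0.0)
        assert len(xic) == 4

    def test_other_polarity_and_ms2_skipped(self):
        scans = [
            Scan(10.0, "-", 1, np.array([400.0]), np.array([10.0])),
            Scan(10.0, "+", 1, np.array([400.0]), np.array([99.0])),
            Scan(10.0, "-", 2, np.array([400.0]), np.array([99.0]), precursor_mz=400.0),
            Scan(10.1, "-", 1, np.array([400.0]), np.array([20.0])),
        ]
        xic = extract_xic(make_stream(scans), 400.0, 5.0, (9.9, 10.2))
        assert np.allclose(xic.intensity, [10.0, 20.0])

    def test_empty_window_raises(self):
        scans = [Scan(1.0, "-", 1, np.array([100.0]), np.array([5.0]))]
        with pytest.raises(EmptyXICError):
            extract_xic(make_stream(scans), 400.0, 5.0, (5.0, 6.0))

    def test_additive_over_disjoint_windows(self):
        rng = np.random.default_rng(0)
        scans = [
            Scan(1.0 + 0.01 * i, "-", 1, np.sort(rng.uniform(99.9, 100.1, 20)),
                 rng.uniform(1, 10, 20))
            for i in range(10)
        ]
        stream = make_stream(scans)
        whole = extract_xic(stream, 100.0, 1000.0, (0.9, 1.2))
        lo_half = [s.intensity[s.mz < 100.0].sum() for s in scans]
        hi_half = [s.intensity[s.mz >= 100.0].sum() for s in scans]
        assert np.allclose(whole.intensity, np.array(lo_half) + np.array(hi_half))


class TestIntegratePeak:
    def test_rectangle_trapezoid(self):
        k, h, dt = 8, 5.0, 0.01
        xic = XIC("x", np.arange(k) * dt + 1.0, np.full(k, h), 400.0, 5.0)
        peak = integrate_peak(xic, 1.035, max_shift=0.5)
        assert peak.area == pytest.approx(h * (k - 1) * dt)

    def test_noiseless_gaussian_closed_form(self):
        amp, sigma, rt0 = 1000.0, 0.05, 5.0
        t = np.arange(rt0 - 4 * sigma, rt0 + 4 * sigma, sigma / 2)  # 16 pts across ±4σ
        y = amp * np.exp(-0.5 * ((t - rt0) / sigma) ** 2)
        peak = integrate_peak(XIC("x", t, y, 400.0, 5.0), rt0, boundary_fraction=0.001)
        assert peak.area == pytest.approx(amp * sigma * math.sqrt(2 * math.pi), rel=5e-3)

    def test_linearity_in_intensity(self):
        t = np.linspace(4.5, 5.5, 60)
        y = 100 * np.exp(-0.5 * ((t - 5.0) / 0.06) ** 2)
        a1 = integrate_peak(XIC("x", t, y, 400.0, 5.0), 5.0).area
        a2 = integrate_peak(XIC("x", t, 2 * y, 400.0, 5.0), 5.0).area
        assert a2 == pytest.approx(2 * a1, rel=1e-12)

    def test_zero_apex_flagged_not_detected(self):
        t = np.linspace(1.0, 2.0, 11)
        peak = integrate_peak(XIC("x", t, np.zeros_like(t), 400.0, 5.0), 1.5)
        assert peak.area == 0.0 and not peak.detected

    def test_bimodal_integrated_across_valley(self):
        m = synth.PeakModel(5.0, 0.04, synth.PeakShape.BIMODAL,
                            split_fraction=0.4, delta_rt=0.2)
        t = np.linspace(4.4, 5.6, 400)
        y = 1e4 * m.profile(t)
        peak = integrate_peak(XIC("x", t, y, 400.0, 5.0), 5.0, boundary_fraction=0.02)
        assert peak.area == pytest.approx(1e4, rel=0.01)  # both modes captured
        assert peak.rt_lo < 4.85 < 5.0 < peak.rt_hi


class TestSpectrumScores:
    def test_idotp_self_match(self):
        pat = isotope_pattern(parse_formula("C8H5F13O3S"))
        assert score_idotp(pat.abundance, pat) == pytest.approx(1.0)

    def test_idotp_orthogonal(self):
        pat = isotope_pattern(parse_formula("C8H5F13O3S"))
        obs = np.zeros(len(pat))
        obs[-1] = 1.0
        assert score_idotp(obs, pat) < 0.1

    def test_idotp_hand_arithmetic(self):
        pat = chem.IsotopePattern(((100.0, 1.0), (101.0, 0.09)))
        got = score_idotp([1.0, 0.18], pat)
        expected = (1 + 0.0162) / (math.sqrt(1.0081) * math.sqrt(1.0324))
        assert got == pytest.approx(expected, abs=1e-6)
        assert got == pytest.approx(0.996, abs=5e-4)

    def test_idotp_all_zero_flagged(self):
        pat = chem.IsotopePattern(((100.0, 1.0), (101.0, 0.09)))
        with pytest.warns(UserWarning):
            assert score_idotp([0.0, 0.0], pat) == 0.0

    def test_dotp_self_match(self):
        tmpl = [(79.9568, 1.0), (98.9553, 0.5)]
        assert score_dotp([79.9568, 98.9553], [1.0, 0.5], tmpl) == pytest.approx(1.0)

    def test_dotp_no_matches(self):
        tmpl = [(79.9568, 1.0), (98.9553, 0.5)]
        assert score_dotp([500.0], [1.0], tmpl) == 0.0

    def test_dotp_two_equal_fragments_one_observed(self):
        tmpl = [(100.0, 1.0), (200.0, 1.0)]
        got = score_dotp([100.0], [123.0], tmpl)
        assert got == pytest.approx(1 / math.sqrt(2), abs=1e-9)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scores_scale_invariant(self, c):
        pat = chem.IsotopePattern(((100.0, 1.0), (101.0, 0.09), (102.0, 0.05)))
        obs = np.array([1.0, 0.11, 0.03])
        assert score_idotp(c * obs, pat) == pytest.approx(score_idotp(obs, pat), abs=1e-12)
        tmpl = [(100.0, 1.0), (150.0, 0.4)]
        a = score_dotp([100.0, 150.0], [2.0 * c, 0.9 * c], tmpl)
        b = score_dotp([100.0, 150.0], [2.0, 0.9], tmpl)
        assert a == pytest.approx(b, abs=1e-12)


class TestCalibration:
    def test_exact_line(self):
        pairs = [(lvl, 0.002 * lvl) for lvl in (2, 5, 10, 50, 100)]
        for w in ("none", "1/x", "1/x^2"):
            c = fit_calibration(pairs, weighting=w)
            assert c.slope == pytest.approx(0.002, abs=1e-15)
            assert c.intercept == pytest.approx(0.0, abs=1e-15)
            assert c.r_squared == pytest.approx(1.0)

    def test_single_level_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration([(10.0, 0.1), (10.0, 0.11)])

    def test_matches_statsmodels_wls(self):
        """Slope/intercept/R² reproduce an independent WLS oracle to 1e-10."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        x = np.array([2.0, 5, 10, 50, 100, 500, 1000, 2000])
        y = 0.003 * x + 0.01 + rng.normal(0, 0.02 * x)
        for weighting, w in [("none", np.ones_like(x)), ("1/x", 1 / x), ("1/x^2", 1 / x**2)]:
            mine = fit_calibration(list(zip(x, y)), weighting=weighting)
            fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
            assert mine.intercept == pytest.approx(fit.params[0], abs=1e-10)
            assert mine.slope == pytest.approx(fit.params[1], abs=1e-10)
            assert mine.r_squared == pytest.approx(fit.rsquared, abs=1e-10)

    def test_back_calculate_inverse(self):
        pairs = [(lvl, 0.01 * lvl + 0.5) for lvl in (2, 10, 100, 1000)]
        curve = fit_calibration(pairs, weighting="1/x")
        for lvl, ratio in pairs:
            assert back_calculate(curve, ratio) == pytest.approx(lvl, rel=1e-9)
        assert back_calculate(curve, curve.intercept) == pytest.approx(0.0, abs=1e-12)

    def test_zero_slope_rejected(self):
        curve = fit_calibration([(1.0, 5.0), (2.0, 5.0)], weighting="none")
        assert curve.slope == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(CalibrationError):
            back_calculate(curve, 1.0)


class TestEndToEndLinearity:
    def test_doubling_concentration_doubles_ratios(self, registry):
        design = synth.StudyDesign(levels_ngL=(10.0, 100.0), n_replicates=8)
        resp = ResponseModel.flat(registry, rf=500.0)
        noise = NoiseModel(area_cv=0.0)
        a1, _ = synth.simulate_replicate_study(design, registry, resp, noise, seed=1)
        design2 = synth.StudyDesign(levels_ngL=(20.0, 200.0), n_replicates=8)
        a2, _ = synth.simulate_replicate_study(design2, registry, resp, noise, seed=1)
        w1 = a1.pivot_table(index=["replicate_id", "level_ngL"], columns="compound", values="area")
        w2 = a2.pivot_table(index=["replicate_id", "level_ngL"], columns="compound", values="area")
        r1 = (w1["PFOA"] / w1["M-PFOA"]).to_numpy()
        r2 = (w2["PFOA"] / w2["M-PFOA"]).to_numpy()
        assert np.allclose(r2, 2 * r1)


class TestQuantifyStream:
    def test_noiseless_stream_area_matches_truth(self):
        """Trapezoidal XIC area ~ analytic Gaussian area (monoisotopic share)."""
        reg = load_default_registry()
        rf, pg = 1e5, 0.9
        resp = ResponseModel.flat(reg, rf=rf)
        noise = NoiseModel(area_cv=0, baseline_peaks_per_scan=0, mz_jitter_ppm=0)
        acq = AcquisitionConfig.from_registry(reg, gradient_span=(8.0, 9.0), ms1_period_s=0.5)
        stream = simulate_scan_stream(
            reg, {"6:2 FTS": pg}, resp, synth.default_peak_models(reg), noise, acq, seed=1
        )
        pat = isotope_pattern(reg["6:2 FTS"].element_counts, threshold=5e-3)
        mono_share = pat.abundance[0] / sum(pat.abundance)
        target = rf * pg * mono_share
        # trapezoidal integral with near-zero boundary cutoff: within 0.5%
        xic = extract_xic(stream, 426.9674, 5.0, (8.0, 9.0))
        full = integrate_peak(xic, 8.5, boundary_fraction=1e-4)
        assert full.area == pytest.approx(target, rel=5e-3)
        # default 2% boundary fraction clips the Gaussian tails slightly
        table = quantify_stream(stream, reg, tol_ppm=5.0)
        row = table[table.compound == "6:2 FTS"].iloc[0]
        assert row.detected
        assert row.area == pytest.approx(target, rel=0.012)
        undetected = table[table.compound == "PFOA"].iloc[0]
        assert not undetected.detected and undetected.area == 0.0

    def test_crosstalk_correction_for_plus2_labeled_standard(self):
        """A 13C2 standard's window receives the analyte's two-13C isotopologue;
        the predicted-share subtraction removes it exactly in a noiseless run."""
        from pfasquant.quant import isotopologue_crosstalk_shares

        reg = load_default_registry()
        shares = isotopologue_crosstalk_shares(reg)
        bleed = dict(shares.get("M-PFTeDA", []))
        assert "PFTeDA" in bleed
        assert 0.005 < bleed["PFTeDA"] < 0.015  # ~C(14,2) p13C^2 share

        resp = ResponseModel.flat(reg, rf=1e5)
        noise = NoiseModel(area_cv=0, baseline_peaks_per_scan=0, mz_jitter_ppm=0)
        acq = AcquisitionConfig.from_registry(reg, gradient_span=(13.0, 14.2),
                                              ms1_period_s=0.5)
        amounts = {"PFTeDA": 180.0, "M-PFTeDA": 100.0}  # top calibrator vs IS
        stream = simulate_scan_stream(
            reg, amounts, resp, synth.default_peak_models(reg), noise, acq, seed=9
        )
        raw = quantify_stream(stream, reg, interference_correction=False)
        fixed = quantify_stream(stream, reg, interference_correction=True)
        is_raw = raw[raw.compound == "M-PFTeDA"].area.iloc[0]
        is_fixed = fixed[fixed.compound == "M-PFTeDA"].area.iloc[0]
        an_fixed = fixed[fixed.compound == "PFTeDA"].area.iloc[0]
        assert is_raw > is_fixed  # contamination removed
        # corrected ratio = amount ratio x ratio of monoisotopic envelope
        # shares (a constant factor that calibration later cancels)
        def mono_share(cid):
            rec = reg[cid]
            pat = isotope_pattern(rec.element_counts, threshold=5e-3,
                                  charge_species=rec.ion_species)
            lo, hi = chem.mz_window(rec.precursor_mz, 5.0)
            own = sum(ab for mz, ab in pat.peaks if lo <= mz <= hi)
            return own / sum(pat.abundance)

        expected = (180.0 / 100.0) * mono_share("PFTeDA") / mono_share("M-PFTeDA")
        assert an_fixed / is_fixed == pytest.approx(expected, rel=1e-6)

    def test_ms2_dimension_quantitation(self):
        """MS2-route areas integrate the triggered fragment chromatograms."""
        reg = load_default_registry()
        resp = ResponseModel.flat(reg, rf=1e5)
        noise = NoiseModel(area_cv=0, baseline_peaks_per_scan=0, mz_jitter_ppm=0)
        acq = AcquisitionConfig.from_registry(
            reg, trigger_threshold=1e3, gradient_span=(8.0, 9.0), ms1_period_s=1.0
        )
        stream = simulate_scan_stream(
            reg, {"6:2 FTS": 0.9, "M-6:2 FTS": 100.0}, resp,
            synth.default_peak_models(reg), noise, acq, seed=4
        )
        table = quantify_stream(stream, reg, ms_level=2)
        row = table[table.compound == "6:2 FTS"].iloc[0]
        assert row.detected and row.area > 0
        assert row.points_across_peak >= 3
        absent = table[table.compound == "PFOA"].iloc[0]
        assert not absent.detected


class TestCrossValidation:
    def test_rotating_calibration_replicate_reports_spread(self, registry, noiseless_study):
        from pfasquant.quant import cross_validate_calibration

        _design, areas, _ = noiseless_study
        cv = cross_validate_calibration(areas, registry)
        assert len(cv) == 45
        assert (cv["n_replicates"] == 10).all()
        # noiseless study: every replicate yields the identical curve
        assert np.allclose(cv["slope_rsd_pct"], 0.0, atol=1e-8)
        assert np.allclose(cv["r2_min"], 1.0)
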