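# Methods

`pfasquant` implements a targeted, high-resolution accurate-mass (HRAM)
quantitation workflow for per- and polyfluoroalkyl substances (PFAS) and the
EPA Method 537.1-style statistics used to validate such a method, together
with a synthetic instrument that generates the replicate calibration data the
statistics consume. This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Quantitation model

Each compound is a neutral molecular formula observed as a singly charged
ion: `[M-H]-` for most PFAS, `[M+H]+` for the three zwitterionic
sulfonamido-amines (which only ionize in positive mode), and `[M-CO2-H]-`
for ether acids such as HFPO-DA and PEPA that decarboxylate in-source.

**Mass convention.** Ion m/z uses the *neutral hydrogen atom* mass with the
electron mass ignored: `[M-H]- = M − 1.007825`. This is the convention most
targeted small-molecule software prints; for 6:2 FTS (C8H5F13O3S) it gives
426.9674 at 4 decimals, whereas the physically exact proton convention gives
426.9679. The exact convention is available via `electron_correction=True`
in `chem.ion_mz`; default off. The atomic mass and isotope-abundance table
is a packaged IUPAC snapshot (6+ decimals), cross-checked in the tests
against the independent table shipped with pyteomics.

**Isotope patterns** are computed by per-element convolution of natural
isotope distributions, with stable-isotope label positions (n13C, n2H) fixed
at their heavy mass. Peaks within 0.01 Da are merged (far below the peak
width at 60k resolving power, far above any fine structure that matters
here) and the envelope is truncated at a relative-abundance threshold
(default 5e-3 where spectra are generated or predicted). A brute-force
isotopologue-enumeration oracle in the tests pins the convolution to 1e-4
relative abundance.

**XIC extraction and integration.** The extracted ion chromatogram sums
centroid intensities inside a ppm window (default 5 ppm) around the
theoretical precursor m/z, per MS1 scan of the matching polarity; there is
no zero-filling across polarity gaps. Peaks are integrated trapezoidally
from the apex (the maximum within ±0.5 min of the expected retention time)
outward until the trace falls below 2% of the apex; a valley above that
threshold is crossed, so bimodal "breakthrough" peaks integrate as one. An
apex of zero yields a flagged not-detected area of 0 rather than a missing
value, so the validation statistics always see a complete replicate grid.
The 2% boundary clips ~0.5–1% of a Gaussian peak's tails; because the clip
is a constant multiplicative factor it cancels in the ratio calibration.

**Isotopologue cross-talk correction.** A +2-Da 13C2-labeled internal
standard elutes with its analyte and sits exactly where the analyte's
two-13C isotopologue falls (both are +2×1.003355 Da), so the standard's
extraction window is contaminated by roughly `C(nC,2)·p13C²` of the analyte
signal — ~0.9% for a C14 analyte, which biases recovery by >1% at the top of
the calibration range. `quant.quantify_stream` therefore subtracts, for
every ordered pair of coeluting same-polarity compounds, the predicted
envelope share of the source inside the target's window (default on). The
correction uses the same theoretical patterns as the predictor, so it is
exact on noiseless synthetic data and first-order correct on real spectra.

**Calibration.** Area ratio (analyte / assigned internal standard) is
regressed on concentration by weighted least squares; weighting `1/x` by
default, since the calibration range spans three decades (2–2000 ng/L) and
unweighted fits let the top levels dominate; `none` and `1/x²` are
available. R² is computed on the weighted fit. One replicate (by default
replicate 1) serves as the calibration curve; all others are back-calculated
as unknowns, `conc = (ratio − intercept)/slope`, negative values reported
as-is for the validation layer to judge.

**Qualitative verification.** `dotp` scores an observed MS2 spectrum against
the registry fragment template as a cosine on square-root-transformed
intensities (the Skyline library-match convention; the plain-intensity
cosine is a flag away), with observed centroids matched to template m/z
within a ppm tolerance and unmatched template entries contributing zeros.
`idotp` is the plain cosine between the observed and predicted MS1 isotope
envelopes.

## Validation statistics

With back-calculated QC replicate concentrations per level
(`s` = sample standard deviation, `N` = replicates, df = N−1):

- `HR_PIR = s · t(df, 1−α/2) · √(1 + 1/N)` with α = 0.01 — the half range of
  the prediction interval of results;
- PIR recovery: `(mean ± HR_PIR)/actual × 100` must satisfy upper ≤ 150%
  and lower ≥ 50%, both bounds inclusive;
- MRL = the lowest calibration level passing both criteria (levels with
  fewer than 7 replicates are excluded; if nothing passes, the MRL is
  reported undefined and flagged);
- `DL = s · t(df, 1−α/2)` at the MRL level — note the identity
  `DL = HR_PIR/√(1+1/N)`;
- IDP = replicate RSD and IDA = mean recovery, both at the 500 ng/L
  mid-level.

**Sidedness.** The HR_PIR/DL formulas are implemented with the two-sided
quantile `t(df, 1−α/2)` by default; EPA 537.1's one-sided `t(df, 1−α)`
variant is a config switch (`sided="one"`). Both conventions circulate; the
package keeps the discrepancy explicit instead of resolving it silently.

**Replicate selection.** All available QC replicates are used by default (no
outlier rejection). An optional trimming rule (`trim_replicates`: drop the
largest |deviation from the mean| until 7 remain) is provided because "use
at least seven" admits several readings; it is never applied implicitly.

**Units.** Limits are reported both as ng/L of the calibration stock and as
pg on column: `pg = ng/L × 0.9 × 1e-4 L × 1000` under the default design
(900 µL calibrator + 100 µL internal-standard working solution, 100 µL
injected), i.e. `pg = 0.09 × ng/L`. The internal standard (10 000 ng/L
working solution, diluted ×0.1) contributes a constant 100 pg per injection.

## The synthetic instrument

The generator's defaults are the study conditions: 8 calibration levels
{2, 5, 10, 50, 100, 500, 1000, 2000} ng/L (the printed limits span 2–500 and
the mid level is 500; the exact level list is not published, so this is a
configurable choice), 10 replicate curves, one treated as the calibration
curve and ≥7 of the rest as QC replicates.

**Area noise** is multiplicative lognormal with mean 1 and a configurable
CV, plus an optional additive floor: areas stay positive and the relative
spread is concentration-independent, which is the dominant behavior of
electrospray peak areas. Analyte and internal-standard noise share a
correlation ρ: with ρ = 1 and equal CVs the ratio is noiseless; with ρ = 0
its RSD approaches √2 × CV (both limits are Monte-Carlo-tested). In the
surrogate scenario the whole compound set gets the pairwise correlation
`ρ_ij = exp(−rate·|F_i − F_j|)` over fluorine counts — an exponential
(Ornstein–Uhlenbeck) kernel, positive semi-definite for any rate, so one
consistent joint distribution gives every analyte–standard pair its own
fluorine-distance correlation.

**Scan streams.** MS1 scans are generated on a fixed period across the
0–20 min gradient; each carries every visible compound's isotope envelope
scaled by its chromatographic profile plus Poisson-count exponential
baseline centroids and ppm-scale Gaussian m/z jitter. Profiles are
unit-area Gaussian, exponentially modified Gaussian, or bimodal: early
eluting hydrophilic compounds (registry-flagged; PFBA, PFMOAA) get a
breakthrough satellite 0.15 min ahead carrying 30% of the analyte, emulating
partial non-retention of the injection bolus. An inclusion list triggers an
MS2 scan (registry fragment template, abundances independent of
concentration) after any MS1 scan where an entry's window exceeds the
trigger threshold, unless dynamically excluded; a dynamic-exclusion window
of twice the peak width yields exactly one MS2 trigger per peak. Positive
polarity scan events run only in the 9.5–11.5 min window that captures the
zwitterions. The dual MS1 mass-range behavior is modeled as a visibility
filter only, not as a sensitivity scaling.

**What the generator does not emulate:** matrix effects and suppression,
mass-calibration drift, carryover, detector saturation shapes beyond a hard
cap, chromatographic drift across runs, and real fragment chemistry (the
fragment templates are synthetic plausible PFAS fragments). Tests passing
on this generator demonstrate the correctness of the arithmetic and the
statistics, and qualitative behaviors (trend shapes, triggering logic) —
not instrument-level performance on real extracts.

## The packaged registry

45 analytes, 23 stable isotope-labeled internal standards, and one
mass-only reference entry (Hydro-EVE, deprotonated m/z 426.9657, the near
isobar 3.98 ppm below 6:2 FTS, for which no public molecular formula
exists). Molecular formulas were compiled from systematic names; retention
times are synthetic placeholders spread over the gradient (zwitterions
inside the positive window); surrogate standards for analytes without a
matched label were assigned by fluorine-count similarity. Each row carries a
provenance note. Expected retention times and fragment templates are inputs,
not claims about any particular instrument.

## Numerical choices and degenerate inputs

- t quantiles come from `scipy.stats.t.ppf`; the tests pin them to an
  independent incomplete-beta inversion to 1e-6 over df 2–30.
- Weighted-least-squares fits require ≥2 distinct levels; pairs with a zero
  internal-standard area are dropped with a warning; a zero slope makes
  back-calculation a hard error.
- `determine_mrl` never raises on an all-failing profile; it returns an
  undefined-MRL flag so a report can still be built.
- Isotope-pattern merging uses an intensity-weighted centroid; the envelope
  base peak is renormalized to 1 after merging.
- Desk-scale problem sizes used by the test suite: end-to-end stream studies
  run 8 replicates × 8 levels with a 2 s MS1 period and 0.1 min peak width
  (≥ 18 points across a peak); trend-recovery suites use 50 seeded runs.

## Known limitations

- Coeluting exact-mass isobars are not deconvolved; "mixed isomers" entries
  quantify as summed peaks.
- The cross-talk correction is single-pass (light→heavy direction); chains
  of mutual contamination would need iteration, and none occur in this
  panel.
- mzML is read but not written; the native scan-stream format is the
  documented JSON-lines dialect.
- Charge states beyond ±1 and adducts beyond ±H / −CO2−H are out of scope
  (the panel's salts dissociate in solution).
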