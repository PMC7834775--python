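# Methods

## The quantification model

The assay is ratio-metric internal-standard qNMR. For analyte *u* and the
dichloromethane (DCM) internal standard *s* in the same tube, the integral of
a fully relaxed signal is proportional to proton moles, so

    Au/As = (n_u · mol_u · f_u) / (n_s · mol_s · f_s)

with `n` the number of equivalent protons behind the quantitative signal
(1 for each flavonoid, 2 for DCM) and `f` the steady-state saturation factor
below. Quantification proceeds by external calibration of Au/As against
concentration (OLS over a stated linear range) followed by inverse
prediction — exactly what routine practice does, and what makes every
concentration-independent multiplicative bias (finite-window tail
truncation, unequal saturation) cancel. A single-point purity-equation route
(`purity_concentration`) is provided as a cross-check; it must be corrected
explicitly for those two biases, and the package computes both corrections
analytically from the analyte specification.

## Steady-state saturation and the D1 plateau

A repeated single-pulse acquisition with flip angle θ and repetition time
TR = D1 + AQ drives longitudinal magnetization to the fixed point of
`M⁺ = M·cosθ·E + (1−E)`, `E = exp(−TR/T1)`, giving the signal fraction

    f = (1−E)·sinθ / (1−E·cosθ)  →  sinθ  as TR → ∞.

`f` is monotone in TR and reaches 99% of its asymptote by TR = 5·T1 for any
θ ≤ 90°, which is the classical "D1 > 5·T1" rule. The Au/As ratio is biased
whenever `f_u ≠ f_s`, and the bias decays as D1 grows; `d1_plateau` reports
the smallest D1 on a scan grid whose ratio sits within a relative tolerance
(default 1%) of the longest-delay ratio, flagging the scan when only the last
grid point qualifies.

Default T1 values: 2.0 s (liquiritin), 1.6 s (isoliquiritin), 1.2 s
(liquiritigenin) and 4.0 s for DCM — a small, symmetric molecule relaxes
slowly, and it is precisely the T1 mismatch between the analytes and the
internal standard that makes the simulated 5/10/20/30/40 s scan keep moving
at 5 s and flatten at 10 s under a 30° acquisition, the behaviour the method
development observed. All T1 values are user-overridable per analyte.

## The synthetic-data generator

`synthetic_data` emulates a processed (frequency-domain, phased) 600 MHz ¹H
spectrum on a descending ppm grid:

* **Lineshape** — every line is an area-normalized Lorentzian with FWHM
  0.4 Hz (a well-shimmed 600 MHz linewidth). Each flavonoid's quantitative
  signal is modelled as a doublet whose splitting (4.5–5 Hz) keeps both
  components inside the published integration window; the true multiplet
  patterns are not critical for integral-based quantification and are
  exposed in `AnalyteSpec.multiplet`.
* **Amounts** — the total multiplet area is
  `1000 · mmol_in_tube · n_protons · f(T1, TR, θ)` arbitrary-units·ppm; the
  single global scale guarantees that integral ratios equal proton-mole
  ratios when saturation factors are equal.
* **Acquisition defaults** — 600 MHz, 11904 Hz sweep, AQ 3.78 s, D1 10 s,
  30° flip, 16 scans, 298 K.
* **Sample prep defaults** — 30 mg extract in a 0.5 mL tube containing
  1.06 mg/mL DCM (20 µL of a 26.5 mg/mL stock, itself 100 µL DCM at
  1.325 g/mL in 5 mL DMSO-d₆).
* **Baseline and noise** — a low-order polynomial in ppm (default
  `0.8·ppm + 4`, small relative to peak heights of order 10³) plus i.i.d.
  Gaussian noise per grid point (default SD 1.0, i.e. single-line SNR of a
  few hundred at 1 mg/mL — routine for 16 scans at 600 MHz). Noise is drawn
  from `numpy.random.default_rng(seed)`; identical configs give bit-identical
  spectra, and replicate/spike/series helpers derive child seeds
  deterministically via `SeedSequence`.
* **Grid** — default 131072 points over 0–10 ppm (0.046 Hz per point,
  finer than the nominal acquisition grid, standing in for zero-filled
  processing). Quadrature error of trapezoidal window integrals at this
  resolution is far below every stated tolerance; the test suite runs at
  2¹⁵–2¹⁶ points where nothing finer is needed.

When `make_calibration_series` is given a target response line, per-level
analyte areas are solved in closed form against one-off noiseless probe
integrations — including the Lorentzian-tail leakage between the analyte and
IS windows — so the noiseless measured Au/As follows the supplied line to
machine precision.

**What the generator does not emulate:** J-coupling evolution, ¹³C
satellites, solvent-suppression artifacts, field-inhomogeneity lineshape
distortion, chemical-shift drift between samples, and real matrix
interferences (overlapping resonances from the extract). Passing tests
therefore demonstrate the correctness of the *analysis* — integration,
calibration, validation statistics and their plumbing — not robustness of
peak integration against crowded real extracts, which the underlying method
addresses by choosing resolved windows.

## Numerical and design choices

* ppm windows are **closed** intervals; integration is trapezoidal on the
  native grid, reported as positive area on the descending axis.
* Baseline correction fits one global polynomial (default order 1) to
  user-declared signal-free regions (defaults δ 9.5–9.0 and 3.5–3.0 in
  simulated scenarios) and subtracts it; per-region baselines were rejected
  to keep the correction a linear operator on the spectrum.
* Calibration needs ≥ 3 distinct levels; `residual_sigma` uses the n−2
  denominator; σ in LOD/LOQ defaults to that residual SD with a blank-SD
  override, and reports round limits to 3 decimals.
* Inverse prediction never refuses: out-of-range (including negative)
  concentrations are returned flagged `extrapolated`, and the CLI exits
  nonzero on extrapolation unless overridden.
* RSD is 100·(sample SD, n−1)/mean, reported to 2 decimals; recovery is
  100·(found_spiked − found_base)/added with a triplicate, double-amount
  (multiplier 2) standard-addition design by default.
* The method comparison is descriptive (per-pair differences, mean
  difference, max absolute relative difference); no hypothesis test is
  attached because none is part of the validated method.
* Herb-basis contents require an explicit extract yield fraction; the
  example scenarios use 0.115 g extract per g dried herb, a realistic yield
  for the sequential reflux/partition extract that also keeps the
  herb-basis and extract-basis reporting scales mutually consistent. The
  package never invents a yield: without one, only extract-basis content is
  reported.
* The stability scenario uses six equally spaced replicates as a stand-in
  for unspecified sampling times within 12 h; with noise-only replication
  precision, repeatability and stability are statistically identical in the
  simulator, and are reported separately only to mirror the validation
  panel's structure.

## Known limitations

* Synthetic RSDs are set by integration noise alone (tenths of a percent at
  default SNR) and are smaller than wet-lab RSDs, which include weighing and
  preparation variance; the validation machinery is exercised, not the
  error budget of a real laboratory.
* The purity-equation cross-check relies on knowing T1 and the lineshape;
  on real data with unknown T1 it should only be used with D1 ≫ 5·T1.
* JCAMP-DX support covers uncompressed AFFN `##XYDATA` and `##XYPOINTS`
  1D blocks; packed/DIFDUP compression and nD data are out of scope.
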