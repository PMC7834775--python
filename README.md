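# qnmr

Internal-standard ¹H quantitative NMR (qNMR) of the licorice flavonoids
**liquiritin**, **isoliquiritin** and **liquiritigenin**, implemented as a
tested, desk-scale pipeline: spectrum simulation with known ground truth,
baseline correction and window integration, external calibration with inverse
prediction, LOD/LOQ, content percentages, and the full analytical
method-validation panel (precision/repeatability/stability RSD, spiked
recovery, relaxation-delay plateau, two-method comparison).

## The method

qNMR exploits the fact that a ¹H signal's integral is proportional to the
molar amount of protons behind it. Each analyte is quantified from the ratio
of its quantitative signal integral to that of a dichloromethane internal
standard (the singlet at δ 5.75 ppm, 2 protons) measured in the same tube:

    Au/As = s·c + b          (external calibration, OLS)
    c     = (Au/As − b) / s  (inverse prediction)

with quantitative windows δ 4.891–4.878 ppm (liquiritin), δ 8.187–8.172 ppm
(isoliquiritin) and δ 6.790–6.776 ppm (liquiritigenin). Detection and
quantitation limits follow LOD = 3.3 σ/s and LOQ = 10 σ/s with σ the
calibration residual SD. Contents are reported as percent of the weighed
extract, and of the dried herb when the extract yield fraction is known.

Because signal integrals are biased when the inter-scan repetition time
TR = D1 + AQ is short relative to T1, the simulator models the steady-state
(Ernst) magnetization of a repeated 30° pulse,
`f = (1−E)·sinθ / (1−E·cosθ)`, `E = exp(−TR/T1)`, and the validation module
locates the minimal sufficient D1 from a scan of Au/As ratios.

There is no public deposit of the original spectra, so the `synthetic_data`
module generates 600 MHz spectra with the statistical structure the analysis
assumes — Lorentzian multiplets in the quantitative windows, the DCM singlet,
polynomial baseline drift, Gaussian noise, and partial saturation — and every
stage of the pipeline is tested against those known truths.

## Worked example

Quantify a simulated tube containing 1.20 mg/mL liquiritin against a
calibration fitted from a noiseless synthetic series:

```python
from dataclasses import replace
from qnmr import *
from qnmr.synthetic_data import LIQUIRITIN, DICHLOROMETHANE

truth = SampleTruth(concentrations={"liquiritin": 1.20}, extract_yield_fraction=0.115)
cfg = SimConfig(seed=7)
spectrum = simulate_spectrum([LIQUIRITIN], truth, cfg)
corrected = baseline_correct(spectrum)

clean = replace(cfg, noise_sd=0.0, baseline_poly=())
series = make_calibration_series(LIQUIRITIN, (0.25, 0.5, 1.0, 1.5, 2.0), clean)
ratios = [peak_ratio(s, LIQUIRITIN.window, DICHLOROMETHANE.window) for _, s in series]
model = fit_calibration([c for c, _ in series], ratios, "liquiritin")
print(f"calibration: Au/As = {model.slope:.4f} c + {model.intercept:.4f}  (R^2 = {model.r_squared:.6f})")

ratio = peak_ratio(corrected, LIQUIRITIN.window, DICHLOROMETHANE.window)
conc, extrapolated = invert(model, ratio)
q = content_percent("liquiritin", conc, 0.5, 30.0, 0.115, ratio=ratio)
print(f"Au/As = {ratio:.4f} -> {conc:.4f} mg/mL (extrapolated: {extrapolated})")
print(f"content: {q.content_extract_pct:.2f}% of extract, {q.content_herb_pct:.3f}% of herb")
```

prints

```
calibration: Au/As = 0.0918 c + 0.0000  (R^2 = 1.000000)
Au/As = 0.1102 -> 1.2011 mg/mL (extrapolated: False)
content: 2.00% of extract, 0.230% of herb
```

The fitted slope 0.0918 is the physical response of the simulator's amount
model (per-proton molar areas with saturation factors); the tube's 1.20 mg/mL
truth is recovered to 0.1% despite noise and baseline drift, and converted to
2.00% of the 30 mg extract weighed into the 0.5 mL tube.

The same stages are available from the shell via a YAML config:

```sh
qnmr simulate --config run.yaml --outdir spectra/
qnmr quantify --config run.yaml --outdir results/ spectra/*.jdx
qnmr validate --config run.yaml --outdir report/
```

## Layout

| module | contents |
| --- | --- |
| `qnmr.spectrum_model` | `Spectrum1D`, acquisition metadata, peak windows, JCAMP-DX / xy-text I/O |
| `qnmr.synthetic_data` | analyte specs, Lorentzian lineshapes, steady-state saturation, scenario generators |
| `qnmr.processing` | baseline correction, window integration, Au/As ratios |
| `qnmr.quantification` | OLS calibration, inverse prediction, LOD/LOQ, content %, purity-equation cross-check |
| `qnmr.validation` | RSD, recovery, D1 plateau, method comparison, full validation run |
| `qnmr.cli` | `qnmr simulate / quantify / validate` over a YAML config |

See `docs/methods.md` for the model assumptions, defaults and limitations.
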