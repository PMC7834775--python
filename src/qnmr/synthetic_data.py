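"""Synthetic 600 MHz 1H spectra with known ground truth.

This module replaces the spectrometer for every test and study scenario. It
produces frequency-domain spectra containing the quantitative signals of the
three licorice flavonoids (liquiritin, isoliquiritin, liquiritigenin), the
dichloromethane internal-standard singlet at δ 5.75 ppm, a low-order polynomial
baseline, i.i.d. Gaussian noise, and the partial-saturation bias of a
short-relaxation-delay 30° acquisition.

The physical model is deliberately minimal but quantitative:

* every resonance line is a Lorentzian;
* the area of an analyte's quantitative multiplet is
  ``AREA_PER_MMOL_PROTON * mmol_in_tube * n_protons * steady_state_factor``,
  with a single global per-proton molar scale, so integral ratios equal
  theoretical proton-mole ratios whenever saturation factors are equal;
* partial saturation follows the steady-state (Ernst) magnetization of a
  repeated single-pulse experiment with repetition time TR = D1 + AQ.

Not modelled (documented non-goals): J-coupling evolution, 13C satellites,
solvent suppression artifacts, field-inhomogeneity lineshape distortion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .spectrum_model import AcquisitionMeta, PeakWindow, Spectrum1D, SpectrumValidationError

__all__ = [
    "AnalyteSpec",
    "SimConfig",
    "SampleTruth",
    "SimulationConfigError",
    "AREA_PER_MMOL_PROTON",
    "LIQUIRITIN",
    "ISOLIQUIRITIN",
    "LIQUIRITIGENIN",
    "DICHLOROMETHANE",
    "default_analytes",
    "lorentzian",
    "steady_state_factor",
    "window_capture_fraction",
    "simulate_spectrum",
    "make_calibration_series",
    "make_replicates",
    "make_spiked_pair",
]

#: Global area scale: spectrum area (intensity·ppm) per mmol of protons at full
#: relaxation. Arbitrary units — every quantification is ratio-metric.
AREA_PER_MMOL_PROTON = 1000.0


class SimulationConfigError(ValueError):
    """Inconsistent simulation scenario (overlapping windows, bad parameters)."""


@dataclass(frozen=True)
class AnalyteSpec:
    """A quantifiable compound: identity, quantitative signal, relaxation.

    ``multiplet`` lists the Lorentzian components of the quantitative signal as
    ``(ppm_center, relative_intensity, fwhm_hz)``; relative intensities must sum
    to 1 and all centers must lie inside the integration window.
    """

    name: str
    molar_mass: float  # g/mol
    window: PeakWindow
    multiplet: tuple[tuple[float, float, float], ...]
    t1_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "multiplet", tuple(tuple(c) for c in self.multiplet))
        if self.molar_mass <= 0:
            raise SpectrumValidationError(f"{self.name}: molar_mass must be positive")
        if self.t1_s <= 0:
            raise SpectrumValidationError(f"{self.name}: t1_s must be positive")
        if not self.multiplet:
            raise SpectrumValidationError(f"{self.name}: multiplet must be non-empty")
        total = sum(rel for _, rel, _ in self.multiplet)
        if abs(total - 1.0) > 1e-9:
            raise SpectrumValidationError(
                f"{self.name}: multiplet relative intensities sum to {total}, expected 1"
            )
        for center, rel, fwhm in self.multiplet:
            if rel < 0:
                raise SpectrumValidationError(f"{self.name}: negative component intensity")
            if fwhm <= 0:
                raise SpectrumValidationError(f"{self.name}: component fwhm must be positive")
            if not self.window.contains(center):
                raise SpectrumValidationError(
                    f"{self.name}: multiplet component at {center} ppm lies outside "
                    f"window [{self.window.ppm_low}, {self.window.ppm_high}]"
                )


def _doublet(center: float, j_hz: float, fwhm_hz: float, freq_mhz: float = 600.0):
    half = 0.5 * j_hz / freq_mhz
    return ((center - half, 0.5, fwhm_hz), (center + half, 0.5, fwhm_hz))


# Default analyte constants. Molar masses from the molecular formulas
# (liquiritin and isoliquiritin C21H22O9, liquiritigenin C15H12O4, DCM CH2Cl2);
# each quantitative window spans ~0.013-0.015 ppm, a single-proton signal;
# dichloromethane contributes a 2-proton singlet. T1 values are defaults a user
# can override: 1-2 s for the flavonoids and 4 s for dichloromethane (a small
# symmetric molecule relaxes slowly), which is what makes the analyte/IS ratio
# keep creeping between D1 = 5 s and 10 s before flattening.
LIQUIRITIN = AnalyteSpec(
    name="liquiritin",
    molar_mass=418.39,
    window=PeakWindow("liquiritin", ppm_high=4.891, ppm_low=4.878, n_protons=1),
    multiplet=_doublet(4.8845, j_hz=4.5, fwhm_hz=0.4),
    t1_s=2.0,
)
ISOLIQUIRITIN = AnalyteSpec(
    name="isoliquiritin",
    molar_mass=418.39,
    window=PeakWindow("isoliquiritin", ppm_high=8.187, ppm_low=8.172, n_protons=1),
    multiplet=_doublet(8.1795, j_hz=5.0, fwhm_hz=0.4),
    t1_s=1.6,
)
LIQUIRITIGENIN = AnalyteSpec(
    name="liquiritigenin",
    molar_mass=256.25,
    window=PeakWindow("liquiritigenin", ppm_high=6.790, ppm_low=6.776, n_protons=1),
    multiplet=_doublet(6.783, j_hz=4.5, fwhm_hz=0.4),
    t1_s=1.2,
)
DICHLOROMETHANE = AnalyteSpec(
    name="dichloromethane",
    molar_mass=84.93,
    window=PeakWindow("dichloromethane", ppm_high=5.80, ppm_low=5.70, n_protons=2),
    multiplet=((5.75, 1.0, 0.4),),
    t1_s=4.0,
)


def default_analytes() -> tuple[AnalyteSpec, AnalyteSpec, AnalyteSpec]:
    """The three licorice flavonoids with their default quantitative signals."""
    return (LIQUIRITIN, ISOLIQUIRITIN, LIQUIRITIGENIN)


@dataclass(frozen=True)
class SimConfig:
    """Grid, noise, baseline and acquisition settings of one simulation.

    ``baseline_poly`` holds polynomial coefficients in ppm, highest degree
    first (``numpy.polyval`` convention); an empty tuple means no baseline.
    Defaults give ~7.6e-5 ppm (0.046 Hz) digital resolution over 0-10 ppm,
    fine enough that trapezoidal window integrals track the analytic line
    areas to well under 1%.
    """

    grid_points: int = 131_072
    ppm_min: float = 0.0
    ppm_max: float = 10.0
    noise_sd: float = 1.0
    baseline_poly: tuple[float, ...] = (0.8, 4.0)
    seed: int = 0
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        object.__setattr__(self, "baseline_poly", tuple(self.baseline_poly))
        if self.grid_points < 2:
            raise SimulationConfigError("grid_points must be >= 2")
        if not self.ppm_max > self.ppm_min:
            raise SimulationConfigError("ppm_max must exceed ppm_min")
        if self.noise_sd < 0:
            raise SimulationConfigError("noise_sd must be >= 0")

    def grid(self) -> np.ndarray:
        """The descending ppm grid."""
        return np.linspace(self.ppm_max, self.ppm_min, self.grid_points)


@dataclass(frozen=True)
class SampleTruth:
    """Ground-truth composition of one NMR tube plus prep bookkeeping.

    Concentrations are mg/mL in the tube. The default prep mirrors the study
    design: 30 mg extract dissolved in 480 uL DMSO-d6 plus 20 uL of a
    26.5 mg/mL dichloromethane internal-standard solution, i.e. 1.06 mg/mL
    DCM in a 0.5 mL tube.
    """

    concentrations: Mapping[str, float]
    internal_standard_conc: float = 26.5 * 0.020 / 0.500  # mg/mL in tube
    tube_volume_ml: float = 0.5
    extract_mass_mg: float = 30.0
    herb_mass_g: float | None = None
    extract_yield_fraction: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations", dict(self.concentrations))
        for name, c in self.concentrations.items():
            if c < 0:
                raise SpectrumValidationError(f"negative concentration for {name}")
        if self.internal_standard_conc < 0:
            raise SpectrumValidationError("internal_standard_conc must be >= 0")
        if self.tube_volume_ml <= 0 or self.extract_mass_mg < 0:
            raise SpectrumValidationError("tube_volume_ml must be > 0, extract_mass_mg >= 0")
        if self.herb_mass_g is not None and self.herb_mass_g < 0:
            raise SpectrumValidationError("herb_mass_g must be >= 0")
        if self.extract_yield_fraction is not None and not 0 < self.extract_yield_fraction <= 1:
            raise SpectrumValidationError("extract_yield_fraction must lie in (0, 1]")

    def mmol_in_tube(self, analyte: AnalyteSpec) -> float:
        conc = self.concentrations.get(analyte.name, 0.0)
        return conc * self.tube_volume_ml / analyte.molar_mass

    def scaled(self, factor: float) -> "SampleTruth":
        """Same prep with all analyte concentrations multiplied by ``factor``."""
        return replace(
            self, concentrations={k: v * factor for k, v in self.concentrations.items()}
        )


# ---------------------------------------------------------------------------
# elementary signal physics


def lorentzian(
    ppm_grid: np.ndarray,
    center: float,
    fwhm_hz: float,
    area: float,
    freq_mhz: float,
) -> np.ndarray:
    """Area-normalized Lorentzian line evaluated on a ppm grid.

    ``L(ppm) = (area/pi) * gamma / ((ppm - center)^2 + gamma^2)`` with
    half-width at half-maximum ``gamma = fwhm_hz / (2 * freq_mhz)`` in ppm.
    Integrated over an interval extending >= 50 gamma each side the numeric
    area matches ``area`` to within 2% (the arctan tail mass).
    """
    if fwhm_hz <= 0:
        raise ValueError("fwhm_hz must be positive")
    if freq_mhz <= 0:
        raise ValueError("freq_mhz must be positive")
    gamma = fwhm_hz / (2.0 * freq_mhz)
    x = np.asarray(ppm_grid, dtype=float)
    return (area / math.pi) * gamma / ((x - center) ** 2 + gamma**2)


def steady_state_factor(t1_s: float, repetition_time_s: float, flip_angle_deg: float) -> float:
    """Steady-state transverse signal fraction of a repeated single-pulse scan.

    ``f = (1 - E) sin(theta) / (1 - E cos(theta))`` with
    ``E = exp(-TR / T1)``. This is the fixed point of the longitudinal Bloch
    recurrence ``M+ = M cos(theta) E + (1 - E)`` multiplied by ``sin(theta)``.
    Monotone increasing in TR; tends to ``sin(theta)`` as TR -> infinity, so a
    relaxation delay of several T1 makes integrals amount-proportional.
    """
    if t1_s <= 0 or repetition_time_s <= 0:
        raise ValueError("t1_s and repetition_time_s must be positive")
    if not 0 < flip_angle_deg <= 90:
        raise ValueError("flip_angle_deg must lie in (0, 90]")
    theta = math.radians(flip_angle_deg)
    e = math.exp(-repetition_time_s / t1_s)
    return (1.0 - e) * math.sin(theta) / (1.0 - e * math.cos(theta))


def window_capture_fraction(spec: AnalyteSpec, freq_mhz: float = 600.0) -> float:
    """Analytic fraction of the multiplet's total area inside its window.

    Closed form per Lorentzian component:
    ``(1/pi) [arctan((hi - c)/gamma) - arctan((lo - c)/gamma)]``. Finite
    integration windows truncate Lorentzian tails; this factor lets the
    proton-ratio (purity-equation) route correct for the truncation, which the
    external-calibration route cancels automatically.
    """
    frac = 0.0
    for center, rel, fwhm in spec.multiplet:
        gamma = fwhm / (2.0 * freq_mhz)
        lo, hi = spec.window.ppm_low, spec.window.ppm_high
        frac += rel / math.pi * (
            math.atan((hi - center) / gamma) - math.atan((lo - center) / gamma)
        )
    return frac


# ---------------------------------------------------------------------------
# spectrum assembly


def _check_disjoint(specs: Sequence[AnalyteSpec]) -> None:
    for i, a in enumerate(specs):
        for b in specs[i + 1 :]:
            if a.window.overlaps(b.window):
                raise SimulationConfigError(
                    f"integration windows of {a.name!r} and {b.name!r} overlap; "
                    "the method assumes fully resolved quantitative signals"
                )


def _multiplet_profile(grid: np.ndarray, spec: AnalyteSpec, area: float, freq_mhz: float) -> np.ndarray:
    y = np.zeros_like(grid)
    for center, rel, fwhm in spec.multiplet:
        if rel > 0:
            y += lorentzian(grid, center, fwhm, area * rel, freq_mhz)
    return y


def simulate_spectrum(
    analytes: Sequence[AnalyteSpec],
    truth: SampleTruth,
    cfg: SimConfig,
    internal_standard: AnalyteSpec = DICHLOROMETHANE,
    area_overrides: Mapping[str, float] | None = None,
) -> Spectrum1D:
    """Simulate one tube: analyte multiplets + IS singlet + baseline + noise.

    Areas follow the amount model described in the module docstring unless
    ``area_overrides`` pins an analyte's total multiplet area directly (used by
    the calibration-series generator to realize a prescribed response line).
    Identical inputs (including ``cfg.seed``) give bit-identical spectra.
    """
    all_specs = list(analytes) + [internal_standard]
    _check_disjoint(all_specs)
    grid = cfg.grid()
    freq = cfg.meta.spectrometer_freq_mhz
    tr = cfg.meta.repetition_time_s
    theta = cfg.meta.flip_angle_deg
    y = np.zeros_like(grid)
    overrides = dict(area_overrides or {})

    for spec in analytes:
        if spec.name in overrides:
            area = overrides[spec.name]
        else:
            area = (
                AREA_PER_MMOL_PROTON
                * truth.mmol_in_tube(spec)
                * spec.window.n_protons
                * steady_state_factor(spec.t1_s, tr, theta)
            )
        if area != 0.0:
            y += _multiplet_profile(grid, spec, area, freq)

    is_mmol = truth.internal_standard_conc * truth.tube_volume_ml / internal_standard.molar_mass
    is_area = overrides.get(
        internal_standard.name,
        AREA_PER_MMOL_PROTON
        * is_mmol
        * internal_standard.window.n_protons
        * steady_state_factor(internal_standard.t1_s, tr, theta),
    )
    if is_area != 0.0:
        y += _multiplet_profile(grid, internal_standard, is_area, freq)

    if cfg.baseline_poly:
        y += np.polyval(cfg.baseline_poly, grid)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        y += rng.normal(0.0, cfg.noise_sd, size=grid.size)
    return Spectrum1D(ppm_axis=grid, intensity=y, meta=cfg.meta)


def _noise_free(cfg: SimConfig) -> SimConfig:
    return replace(cfg, noise_sd=0.0, baseline_poly=())


def _unit_response(spec: AnalyteSpec, window: PeakWindow, cfg: SimConfig) -> float:
    """Trapezoidal integral over ``window`` of the multiplet at unit total area."""
    grid = cfg.grid()
    y = _multiplet_profile(grid, spec, 1.0, cfg.meta.spectrometer_freq_mhz)
    mask = (grid >= window.ppm_low) & (grid <= window.ppm_high)
    return float(np.trapezoid(y[mask][::-1], grid[mask][::-1]))


ResponseLine = Callable[[float], float] | tuple[float, float]


def make_calibration_series(
    analyte: AnalyteSpec,
    concentrations: Sequence[float],
    cfg: SimConfig,
    model: ResponseLine | None = None,
    internal_standard: AnalyteSpec = DICHLOROMETHANE,
    truth_template: SampleTruth | None = None,
) -> list[tuple[float, Spectrum1D]]:
    """One spectrum per calibration level for a single analyte.

    Without ``model`` the areas follow the physical amount model. With
    ``model`` — a ``(slope, intercept)`` pair or a callable ``conc -> Au/As``
    — each level's analyte area is solved against one-off noiseless probe
    integrations (including the Lorentzian-tail leakage between the analyte
    and IS windows) so the noiseless measured response follows the supplied
    line exactly, letting a downstream OLS fit recover a prescribed
    calibration to machine precision. Per-level noise seeds derive
    deterministically from ``cfg.seed``.
    """
    if len(concentrations) == 0:
        raise ValueError("concentrations must be non-empty")
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be >= 0")
    template = truth_template or SampleTruth(concentrations={})

    line: Callable[[float], float] | None
    if model is None:
        line = None
    elif callable(model):
        line = model
    else:
        slope, intercept = model
        line = lambda c: slope * c + intercept  # noqa: E731

    solve_area: Callable[[float], float] | None = None
    if line is not None:
        probe_cfg = _noise_free(cfg)
        tr = probe_cfg.meta.repetition_time_s
        theta = probe_cfg.meta.flip_angle_deg
        is_area = (
            AREA_PER_MMOL_PROTON
            * template.internal_standard_conc
            * template.tube_volume_ml
            / internal_standard.molar_mass
            * internal_standard.window.n_protons
            * steady_state_factor(internal_standard.t1_s, tr, theta)
        )
        # measured Au = a*u_aa + I*u_ia ; measured As = I*u_ii + a*u_ai, where
        # u_xy is compound x's unit-area integral over window y; solving
        # Au/As = L gives a exactly, tail leakage included
        u_aa = _unit_response(analyte, analyte.window, probe_cfg)
        u_ai = _unit_response(analyte, internal_standard.window, probe_cfg)
        u_ii = _unit_response(internal_standard, internal_standard.window, probe_cfg)
        u_ia = _unit_response(internal_standard, analyte.window, probe_cfg)

        def solve_area(conc: float, _L=line) -> float:
            target = _L(conc)
            denom = u_aa - target * u_ai
            if denom <= 0:
                raise SimulationConfigError(
                    "response line is unreachable with these windows/lineshapes"
                )
            return is_area * (target * u_ii - u_ia) / denom

    seeds = _derive_seeds(cfg.seed, len(concentrations))
    series: list[tuple[float, Spectrum1D]] = []
    for conc, seed in zip(concentrations, seeds):
        truth = replace(template, concentrations={analyte.name: float(conc)})
        level_cfg = replace(cfg, seed=seed)
        overrides = {analyte.name: solve_area(float(conc))} if solve_area else None
        s = simulate_spectrum([analyte], truth, level_cfg, internal_standard, overrides)
        series.append((float(conc), s))
    return series


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2**31) from one parent seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(v % (2**31)) for v in state]


def make_replicates(
    truth: SampleTruth,
    cfg: SimConfig,
    n: int,
    analytes: Sequence[AnalyteSpec] | None = None,
    internal_standard: AnalyteSpec = DICHLOROMETHANE,
) -> list[Spectrum1D]:
    """``n`` spectra of the same tube differing only in the noise realization."""
    if n < 2:
        raise ValueError("replicate count must be >= 2")
    specs = list(analytes) if analytes is not None else list(default_analytes())
    return [
        simulate_spectrum(specs, truth, replace(cfg, seed=s), internal_standard)
        for s in _derive_seeds(cfg.seed, n)
    ]


def make_spiked_pair(
    truth: SampleTruth,
    spike_multiplier: float,
    cfg: SimConfig,
    analytes: Sequence[AnalyteSpec] | None = None,
    internal_standard: AnalyteSpec = DICHLOROMETHANE,
) -> tuple[Spectrum1D, Spectrum1D, dict[str, float]]:
    """A base spectrum and a standard-addition spectrum for recovery studies.

    The spiked tube carries ``(1 + spike_multiplier)`` times each analyte's base
    amount (the study design doubles the amounts: multiplier 2). ``added``
    reports the spiked mass per analyte in mg, exactly.
    """
    if spike_multiplier <= 0:
        raise ValueError("spike_multiplier must be > 0")
    specs = list(analytes) if analytes is not None else list(default_analytes())
    seed_base, seed_spiked = _derive_seeds(cfg.seed, 2)
    base = simulate_spectrum(specs, truth, replace(cfg, seed=seed_base), internal_standard)
    spiked_truth = truth.scaled(1.0 + spike_multiplier)
    spiked = simulate_spectrum(
        specs, spiked_truth, replace(cfg, seed=seed_spiked), internal_standard
    )
    added = {
        spec.name: spike_multiplier
        * truth.concentrations.get(spec.name, 0.0)
        * truth.tube_volume_ml
        for spec in specs
    }
    return base, spiked, added
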