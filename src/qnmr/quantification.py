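"""Calibration, inverse prediction, LOD/LOQ and content arithmetic.

The method is external calibration of the internal-standard ratio: for each
analyte an ordinary least-squares line ``Au/As = s * conc + b`` is fitted over
a stated linear range, unknowns are inverse-predicted from their measured
ratio, and detection/quantitation limits follow the 3.3σ/s and 10σ/s rules
with σ the calibration residual standard deviation (a blank-SD alternative can
be supplied). Contents are reported as mass percentages of the weighed extract
and, when an extract yield fraction is known, of the dried herb.

A single-point proton-ratio (purity-equation) route is provided as a
cross-check: moles of analyte from the proton-normalized ratio times the known
internal-standard moles. On clean simulated data, corrected for window
truncation and partial saturation, it must agree with the calibration route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .spectrum_model import AcquisitionMeta
from .synthetic_data import AnalyteSpec, steady_state_factor, window_capture_fraction

__all__ = [
    "CalibrationModel",
    "QuantResult",
    "InverseResult",
    "DegenerateDesignError",
    "fit_calibration",
    "invert",
    "lod_loq",
    "internal_standard_conc",
    "content_percent",
    "purity_concentration",
]


class DegenerateDesignError(ValueError):
    """Calibration design cannot support a straight-line fit."""


@dataclass(frozen=True)
class CalibrationModel:
    """One analyte's straight-line response: ratio = slope * conc + intercept.

    ``residual_sigma`` is sqrt(SSE / (n - 2)), the response-scale noise used by
    the LOD/LOQ rules; ``conc_range`` is the fitted concentration span (mg/mL)
    outside which inverse predictions are flagged extrapolated.
    """

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    residual_sigma: float
    conc_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be nonzero")
        if not self.conc_range[0] < self.conc_range[1]:
            raise ValueError("conc_range must be (low, high) with low < high")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.residual_sigma < 0:
            raise ValueError("residual_sigma must be >= 0")

    def predict(self, conc: float) -> float:
        return self.slope * conc + self.intercept


class InverseResult(NamedTuple):
    conc: float
    extrapolated: bool


@dataclass(frozen=True)
class QuantResult:
    """Quantification of one analyte in one tube, on both reporting bases."""

    analyte: str
    ratio: float
    conc_tube: float  # mg/mL
    mass_in_tube: float  # mg
    content_extract_pct: float
    content_herb_pct: float | None
    extrapolated: bool


def fit_calibration(
    concs: Sequence[float], ratios: Sequence[float], analyte: str
) -> CalibrationModel:
    """Ordinary least squares of Au/As against concentration.

    Requires at least three distinct concentration levels. ``r_squared`` is the
    coefficient of determination and ``residual_sigma = sqrt(SSE / (n - 2))``.
    """
    x = np.asarray(concs, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concs and ratios must be 1-D sequences of equal length")
    if np.unique(x).size < 3:
        raise DegenerateDesignError(
            f"{analyte}: calibration needs >= 3 distinct concentrations, "
            f"got {np.unique(x).size}"
        )
    if np.var(x) == 0:
        raise DegenerateDesignError(f"{analyte}: zero concentration variance")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    sse = float(np.dot(resid, resid))
    sigma = math.sqrt(sse / (x.size - 2))
    return CalibrationModel(
        analyte=analyte,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        residual_sigma=sigma,
        conc_range=(float(np.min(x)), float(np.max(x))),
    )


def invert(model: CalibrationModel, ratio: float) -> InverseResult:
    """Inverse prediction ``conc = (ratio - intercept) / slope``.

    Concentrations outside the fitted range (including negative ones) are
    returned as-is but flagged ``extrapolated``.
    """
    conc = (ratio - model.intercept) / model.slope
    lo, hi = model.conc_range
    return InverseResult(conc=conc, extrapolated=not lo <= conc <= hi)


def lod_loq(model: CalibrationModel, sigma: float | None = None) -> tuple[float, float]:
    """Detection and quantitation limits: LOD = 3.3 σ/s, LOQ = 10 σ/s (mg/mL).

    σ defaults to the model's calibration residual standard deviation; pass
    ``sigma`` to use a blank-response SD instead. LOQ/LOD is 10/3.3 by
    construction. Values are returned unrounded; reports render 3 decimals.
    """
    if model.slope <= 0:
        raise ValueError("LOD/LOQ require a positive slope")
    s = model.residual_sigma if sigma is None else float(sigma)
    if s < 0:
        raise ValueError("sigma must be >= 0")
    return 3.3 * s / model.slope, 10.0 * s / model.slope


def internal_standard_conc(volume_is_ml: float, density_g_per_ml: float, total_volume_ml: float) -> float:
    """Concentration (mg/mL) of an IS stock made by diluting a neat liquid.

    ``1000 * volume_is * density / total_volume`` — e.g. 0.1 mL dichloromethane
    (1.325 g/mL) in 5 mL DMSO-d6 gives 26.5 mg/mL.
    """
    if volume_is_ml <= 0 or density_g_per_ml <= 0 or total_volume_ml <= 0:
        raise ValueError("volumes and density must be positive")
    return 1000.0 * volume_is_ml * density_g_per_ml / total_volume_ml


def content_percent(
    analyte: str,
    conc_tube: float,
    tube_volume_ml: float,
    extract_mass_mg: float,
    extract_yield_fraction: float | None = None,
    ratio: float = float("nan"),
    extrapolated: bool = False,
) -> QuantResult:
    """Contents from a tube concentration and the sample-prep bookkeeping.

    ``content_extract_pct = 100 * conc * tube_volume / extract_mass``; the
    herb-basis content is that times the extract yield fraction (mass of
    extract per mass of dried herb) and is reported only when a yield is
    supplied — the yield is never invented.
    """
    if tube_volume_ml <= 0 or extract_mass_mg <= 0:
        raise ValueError("tube_volume_ml and extract_mass_mg must be positive")
    if extract_yield_fraction is not None and not 0 < extract_yield_fraction <= 1:
        raise ValueError("extract_yield_fraction must lie in (0, 1]")
    mass = conc_tube * tube_volume_ml
    extract_pct = 100.0 * mass / extract_mass_mg
    herb_pct = (
        extract_pct * extract_yield_fraction if extract_yield_fraction is not None else None
    )
    return QuantResult(
        analyte=analyte,
        ratio=ratio,
        conc_tube=conc_tube,
        mass_in_tube=mass,
        content_extract_pct=extract_pct,
        content_herb_pct=herb_pct,
        extrapolated=extrapolated,
    )


def purity_concentration(
    ratio: float,
    analyte: AnalyteSpec,
    internal_standard: AnalyteSpec,
    is_conc_tube: float,
    meta: AcquisitionMeta | None = None,
    correct_truncation: bool = True,
) -> float:
    """Single-point proton-ratio concentration (mg/mL) — calibration cross-check.

    From the qNMR purity relation, moles scale as the proton-normalized window
    integrals::

        conc_a = ratio * (n_is / n_a) * (M_a / M_is) * conc_is * k

    where ``k`` corrects for unequal partial saturation (from T1 and the
    acquisition metadata, when given) and for the finite integration windows'
    Lorentzian tail truncation (when ``correct_truncation``). With both
    corrections the route agrees with external calibration on clean simulated
    spectra.
    """
    if is_conc_tube <= 0:
        raise ValueError("is_conc_tube must be positive")
    k = 1.0
    if meta is not None:
        f_is = steady_state_factor(internal_standard.t1_s, meta.repetition_time_s, meta.flip_angle_deg)
        f_a = steady_state_factor(analyte.t1_s, meta.repetition_time_s, meta.flip_angle_deg)
        k *= f_is / f_a
    if correct_truncation:
        freq = meta.spectrometer_freq_mhz if meta is not None else 600.0
        k *= window_capture_fraction(internal_standard, freq) / window_capture_fraction(
            analyte, freq
        )
    return (
        ratio
        * (internal_standard.window.n_protons / analyte.window.n_protons)
        * (analyte.molar_mass / internal_standard.molar_mass)
        * is_conc_tube
        * k
    )
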