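"""Method-validation statistics and the full synthetic validation run.

Covers the classical analytical-validation panel: relative standard deviation
(precision / repeatability / stability), spiked recovery, LOD/LOQ, the
relaxation-delay (D1) plateau scan, and a descriptive two-method comparison.
`validate_method` chains the whole package on a synthetic design and returns a
structured :class:`ValidationReport`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from . import processing, quantification
from .spectrum_model import PeakWindow, Spectrum1D
from .synthetic_data import (
    AnalyteSpec,
    DICHLOROMETHANE,
    SampleTruth,
    SimConfig,
    _derive_seeds,
    default_analytes,
    make_calibration_series,
    make_replicates,
    make_spiked_pair,
    simulate_spectrum,
)

__all__ = [
    "AnalytePanel",
    "MethodComparison",
    "PlateauResult",
    "ValidationDesign",
    "ValidationReport",
    "rsd",
    "recovery",
    "d1_plateau",
    "compare_methods",
    "validate_method",
]


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in %: 100 * sample SD (n-1) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = float(np.mean(v))
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return 100.0 * float(np.std(v, ddof=1)) / mean


def recovery(found_spiked: float, found_base: float, added: float) -> float:
    """Spiked recovery in %: 100 * (found_spiked - found_base) / added."""
    if added <= 0:
        raise ValueError("added amount must be positive")
    return 100.0 * (found_spiked - found_base) / added


class PlateauResult(NamedTuple):
    d1_s: float
    plateau_found: bool


def d1_plateau(
    d1_values: Sequence[float], ratios: Sequence[float], rel_tol: float = 0.01
) -> PlateauResult:
    """Minimal sufficient relaxation delay from a D1 scan of Au/As ratios.

    Returns the smallest D1 whose ratio lies within ``rel_tol`` (relative) of
    the longest-delay ratio. If only the final grid point itself qualifies
    there is no evidence of a plateau inside the grid: the longest D1 is
    returned with ``plateau_found=False``.
    """
    d1 = np.asarray(d1_values, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if d1.shape != r.shape or d1.ndim != 1:
        raise ValueError("d1_values and ratios must be paired 1-D sequences")
    if d1.size < 3:
        raise ValueError("D1 scan needs at least 3 points")
    if not np.all(np.diff(d1) > 0):
        raise ValueError("d1_values must be strictly ascending")
    if rel_tol < 0:
        raise ValueError("rel_tol must be >= 0")
    ref = r[-1]
    if ref == 0:
        raise ValueError("reference ratio at the longest D1 is zero")
    within = np.abs(r / ref - 1.0) <= rel_tol
    first = int(np.argmax(within))  # last point is always within tol
    if first == d1.size - 1:
        return PlateauResult(d1_s=float(d1[-1]), plateau_found=False)
    return PlateauResult(d1_s=float(d1[first]), plateau_found=True)


@dataclass(frozen=True)
class MethodComparison:
    """Descriptive paired comparison of two measurement methods.

    Differences are method_b - method_a per pair; no hypothesis test is
    performed — the summary is descriptive.
    """

    differences: tuple[float, ...]
    mean_difference: float
    max_abs_relative_difference: float


def compare_methods(pairs: Sequence[tuple[float, float]]) -> MethodComparison:
    """Per-sample paired differences between two methods (b - a)."""
    if len(pairs) < 2:
        raise ValueError("method comparison needs at least 2 paired samples")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    diffs = b - a
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(diffs) / np.abs(a)
    rel = rel[np.isfinite(rel)]
    return MethodComparison(
        differences=tuple(float(d) for d in diffs),
        mean_difference=float(np.mean(diffs)),
        max_abs_relative_difference=float(np.max(rel)) if rel.size else math.nan,
    )


# ---------------------------------------------------------------------------
# full synthetic validation run


@dataclass(frozen=True)
class ValidationDesign:
    """Replicate counts and scan grids of the synthetic validation study.

    Defaults mirror the study design: 6-fold precision/repeatability, six
    stability time points inside 12 h, triplicate double-amount (multiplier 2)
    standard addition, and a D1 grid of 5/10/20/30/40 s.
    """

    calibration_concs: tuple[float, ...] = (0.25, 0.5, 1.0, 1.5, 2.0)
    n_precision: int = 6
    n_repeatability: int = 6
    n_stability: int = 6
    n_recovery: int = 3
    spike_multiplier: float = 2.0
    d1_grid_s: tuple[float, ...] = (5.0, 10.0, 20.0, 30.0, 40.0)
    d1_rel_tol: float = 0.01


@dataclass(frozen=True)
class AnalytePanel:
    """Validation figures of merit for one analyte."""

    analyte: str
    precision_rsd: float
    repeatability_rsd: float
    stability_rsd: float
    recoveries: tuple[float, ...]
    recovery_rsd: float
    lod: float
    loq: float
    calibration: quantification.CalibrationModel


@dataclass(frozen=True)
class ValidationReport:
    """Full validation panel: per-analyte figures, D1 plateau, method comparison."""

    panels: Mapping[str, AnalytePanel]
    d1_plateau_s: float
    d1_plateau_found: bool
    comparison: Mapping[str, MethodComparison] = field(default_factory=dict)


def _quantified_mass(
    s: Spectrum1D,
    model: quantification.CalibrationModel,
    analyte_window: PeakWindow,
    is_window: PeakWindow,
    tube_volume_ml: float,
    regions,
) -> float:
    corrected = processing.baseline_correct(s, regions)
    ratio = processing.peak_ratio(corrected, analyte_window, is_window)
    conc = quantification.invert(model, ratio).conc
    return conc * tube_volume_ml


def validate_method(
    truth: SampleTruth,
    cfg: SimConfig,
    design: ValidationDesign = ValidationDesign(),
    analytes: Sequence[AnalyteSpec] | None = None,
    internal_standard: AnalyteSpec = DICHLOROMETHANE,
    signal_free_regions=processing.DEFAULT_SIGNAL_FREE_REGIONS,
    comparison_pairs: Mapping[str, Sequence[tuple[float, float]]] | None = None,
) -> ValidationReport:
    """Run the complete synthetic validation study and collect the report.

    Per analyte: fit a calibration from a noiseless synthetic series, then
    compute precision/repeatability/stability RSDs from noisy replicate sets,
    triplicate spiked recoveries, and LOD/LOQ from the calibration residuals of
    a noisy series. A D1 scan of the first analyte's Au/As ratio locates the
    minimal sufficient relaxation delay. ``comparison_pairs`` (e.g. contents by
    an orthogonal method) are summarized descriptively when provided.
    """
    specs = list(analytes) if analytes is not None else list(default_analytes())
    is_w = internal_standard.window
    stage_seeds = _derive_seeds(cfg.seed, 4 * len(specs) + 1)
    panels: dict[str, AnalytePanel] = {}

    for i, spec in enumerate(specs):
        # calibration from a noiseless series; LOD/LOQ sigma from a noisy refit
        clean_cfg = replace(cfg, noise_sd=0.0, baseline_poly=())
        series = make_calibration_series(
            spec, design.calibration_concs, clean_cfg, internal_standard=internal_standard
        )
        ratios = [processing.peak_ratio(s, spec.window, is_w) for _, s in series]
        model = quantification.fit_calibration(
            [c for c, _ in series], ratios, analyte=spec.name
        )
        noisy_series = make_calibration_series(
            spec,
            design.calibration_concs,
            replace(cfg, seed=stage_seeds[4 * i]),
            internal_standard=internal_standard,
        )
        noisy_ratios = [
            processing.peak_ratio(
                processing.baseline_correct(s, signal_free_regions), spec.window, is_w
            )
            for _, s in noisy_series
        ]
        noisy_model = quantification.fit_calibration(
            [c for c, _ in noisy_series], noisy_ratios, analyte=spec.name
        )
        lod, loq = quantification.lod_loq(noisy_model)

        def replicate_masses(seed: int, n: int) -> list[float]:
            reps = make_replicates(
                truth, replace(cfg, seed=seed), n, analytes=specs,
                internal_standard=internal_standard,
            )
            return [
                _quantified_mass(
                    s, model, spec.window, is_w, truth.tube_volume_ml, signal_free_regions
                )
                for s in reps
            ]

        precision = rsd(replicate_masses(stage_seeds[4 * i + 1], design.n_precision))
        repeatability = rsd(replicate_masses(stage_seeds[4 * i + 2], design.n_repeatability))
        stability = rsd(replicate_masses(stage_seeds[4 * i + 3], design.n_stability))

        recoveries: list[float] = []
        rec_seeds = _derive_seeds(stage_seeds[4 * i + 1] ^ 0x5EED, design.n_recovery)
        for rs in rec_seeds:
            base, spiked, added = make_spiked_pair(
                truth, design.spike_multiplier, replace(cfg, seed=rs),
                analytes=specs, internal_standard=internal_standard,
            )
            m_base = _quantified_mass(
                base, model, spec.window, is_w, truth.tube_volume_ml, signal_free_regions
            )
            m_spiked = _quantified_mass(
                spiked, model, spec.window, is_w, truth.tube_volume_ml, signal_free_regions
            )
            recoveries.append(recovery(m_spiked, m_base, added[spec.name]))

        panels[spec.name] = AnalytePanel(
            analyte=spec.name,
            precision_rsd=precision,
            repeatability_rsd=repeatability,
            stability_rsd=stability,
            recoveries=tuple(recoveries),
            recovery_rsd=rsd(recoveries),
            lod=lod,
            loq=loq,
            calibration=model,
        )

    # D1 scan on the first analyte, clean spectra (the plateau is a saturation
    # property, not a noise property)
    scan_spec = specs[0]
    scan_ratios = []
    for d1 in design.d1_grid_s:
        meta = replace(cfg.meta, relaxation_delay_s=float(d1))
        scfg = replace(cfg, noise_sd=0.0, baseline_poly=(), meta=meta)
        s = simulate_spectrum(specs, truth, scfg, internal_standard)
        scan_ratios.append(processing.peak_ratio(s, scan_spec.window, is_w))
    plateau = d1_plateau(design.d1_grid_s, scan_ratios, design.d1_rel_tol)

    comparison = {
        name: compare_methods(pairs) for name, pairs in (comparison_pairs or {}).items()
    }
    return ValidationReport(
        panels=panels,
        d1_plateau_s=plateau.d1_s,
        d1_plateau_found=plateau.plateau_found,
        comparison=comparison,
    )
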