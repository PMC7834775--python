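"""Baseline correction and window integration: spectrum -> Au/As ratios.

The quantitative primitive of the whole method is the ratio of two trapezoidal
window integrals on a baseline-corrected spectrum: the analyte's quantitative
signal (Au) over the internal-standard signal (As). Integration runs on the
native grid, no resampling — at fine digital resolution this matches the
integral-region behaviour of standard NMR processing software. Windows are
assumed resolved; overlap is a configuration error upstream, not a fitting
problem, and no deconvolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectrum_model import PeakWindow, Spectrum1D

__all__ = [
    "IntegrationResult",
    "MissingInternalStandardError",
    "DEFAULT_SIGNAL_FREE_REGIONS",
    "baseline_correct",
    "integrate_window",
    "peak_ratio",
]

#: Signal-free ppm intervals used for baseline fitting in the simulated
#: scenarios (no signals are placed there). Real-data users must supply their own.
DEFAULT_SIGNAL_FREE_REGIONS: tuple[tuple[float, float], ...] = ((9.0, 9.5), (3.0, 3.5))


class MissingInternalStandardError(ValueError):
    """The internal-standard window integrates to a non-positive area."""


@dataclass(frozen=True)
class IntegrationResult:
    """One window integral (intensity·ppm), positive by convention."""

    window: PeakWindow
    area: float
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.area):
            raise ValueError(f"non-finite area for window {self.window.name!r}")


def baseline_correct(
    s: Spectrum1D,
    signal_free_regions: Sequence[tuple[float, float]] = DEFAULT_SIGNAL_FREE_REGIONS,
    order: int = 1,
) -> Spectrum1D:
    """Subtract a polynomial baseline fitted to signal-free points.

    ``signal_free_regions`` are (low, high) ppm intervals known to contain no
    signal; at least two intervals with at least three grid points each are
    required so the fit is constrained away from the peaks. A polynomial of
    the given order (default 1, i.e. offset + linear drift) is least-squares
    fitted to those points and subtracted from the whole spectrum, leaving the
    mean residual in the signal-free regions at ~0.
    """
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    regions = [tuple(sorted(r)) for r in signal_free_regions]
    if len(regions) < 2:
        raise ValueError("need >= 2 signal-free regions to anchor the baseline")
    masks = []
    for lo, hi in regions:
        m = (s.ppm_axis >= lo) & (s.ppm_axis <= hi)
        if int(m.sum()) < 3:
            raise ValueError(
                f"signal-free region ({lo}, {hi}) ppm covers {int(m.sum())} grid "
                "points; >= 3 required"
            )
        masks.append(m)
    mask = np.logical_or.reduce(masks)
    coeffs = np.polyfit(s.ppm_axis[mask], s.intensity[mask], deg=order)
    corrected = s.intensity - np.polyval(coeffs, s.ppm_axis)
    return s.with_intensity(corrected)


def integrate_window(s: Spectrum1D, w: PeakWindow, baseline_corrected: bool = False) -> IntegrationResult:
    """Trapezoidal integral of intensity over the closed window [ppm_low, ppm_high].

    Computed on the stored descending axis and reported as a positive area.
    The window must overlap the spectrum's ppm range and contain at least two
    grid points.
    """
    if w.ppm_high < s.ppm_axis[-1] or w.ppm_low > s.ppm_axis[0]:
        raise ValueError(
            f"window {w.name!r} [{w.ppm_low}, {w.ppm_high}] lies outside the "
            f"spectrum range [{s.ppm_axis[-1]}, {s.ppm_axis[0]}]"
        )
    mask = s.window_mask(w)
    npts = int(mask.sum())
    if npts < 2:
        raise ValueError(
            f"window {w.name!r} contains {npts} grid point(s); >= 2 required "
            "(digital resolution too coarse)"
        )
    # trapezoid on the descending axis yields a negative value; negate to report
    # the conventional positive area
    area = -float(np.trapezoid(s.intensity[mask], s.ppm_axis[mask]))
    return IntegrationResult(window=w, area=area, baseline_corrected=baseline_corrected)


def peak_ratio(s: Spectrum1D, analyte_window: PeakWindow, is_window: PeakWindow) -> float:
    """Au/As: analyte window integral over internal-standard window integral.

    Both integrals come from the same spectrum (baseline-correct it first),
    which makes the ratio invariant to global intensity scaling. A
    non-positive internal-standard area means the IS signal is absent and
    raises :class:`MissingInternalStandardError`.
    """
    au = integrate_window(s, analyte_window).area
    as_ = integrate_window(s, is_window).area
    if as_ <= 0:
        raise MissingInternalStandardError(
            f"internal-standard window {is_window.name!r} integrates to {as_:.4g}"
        )
    return au / as_
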