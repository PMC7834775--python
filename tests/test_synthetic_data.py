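"""Generator physics: lineshape areas, steady-state saturation, amount model."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from qnmr import (
    SampleTruth,
    SimConfig,
    lorentzian,
    make_calibration_series,
    make_replicates,
    make_spiked_pair,
    simulate_spectrum,
    steady_state_factor,
)
from qnmr.processing import integrate_window, peak_ratio
from qnmr.quantification import fit_calibration, DegenerateDesignError
from qnmr.spectrum_model import SpectrumValidationError
from qnmr.synthetic_data import (
    AnalyteSpec,
    AREA_PER_MMOL_PROTON,
    DICHLOROMETHANE,
    LIQUIRITIN,
    SimulationConfigError,
    window_capture_fraction,
)


class TestLorentzian:
    def test_zero_area_gives_zero_vector(self):
        x = np.linspace(10, 0, 101)
        assert np.all(lorentzian(x, 5.0, 1.0, 0.0, 600.0) == 0)

    def test_area_doubles_pointwise(self):
        x = np.linspace(10, 0, 101)
        one = lorentzian(x, 5.0, 1.0, 1.0, 600.0)
        np.testing.assert_allclose(lorentzian(x, 5.0, 1.0, 2.0, 600.0), 2 * one)

    def test_integral_over_100_gamma_matches_arctan_mass(self):
        """Closed-form oracle: mass within ±100γ is (2/π)·arctan(100) ≈ 0.9937."""
        fwhm, freq = 1.0, 600.0
        gamma = fwhm / (2 * freq)
        x = np.linspace(5 + 100 * gamma, 5 - 100 * gamma, 200_001)
        y = lorentzian(x, 5.0, fwhm, 1.0, freq)
        got = -np.trapezoid(y, x)
        assert got == pytest.approx(2 / math.pi * math.atan(100), rel=1e-4)
        assert got == pytest.approx(0.9937, abs=5e-4)

    def test_wide_interval_recovers_nominal_area_within_2pct(self):
        gamma = 0.4 / (2 * 600.0)
        x = np.linspace(5 + 200 * gamma, 5 - 200 * gamma, 100_001)
        got = -np.trapezoid(lorentzian(x, 5.0, 0.4, 3.0, 600.0), x)
        assert got == pytest.approx(3.0, rel=0.02)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            lorentzian(np.linspace(1, 0, 5), 0.5, 0.0, 1.0, 600.0)


def _bloch_fixed_point(t1, tr, theta_deg, iters=400):
    """Independent oracle: iterate M+ = M·cosθ·E + (1−E) to its fixed point."""
    e = math.exp(-tr / t1)
    c = math.cos(math.radians(theta_deg))
    m = 1.0
    for _ in range(iters):
        m = m * c * e + (1 - e)
    return m * math.sin(math.radians(theta_deg))


class TestSteadyState:
    def test_full_relaxation_limit_is_sin_theta(self):
        assert steady_state_factor(1.0, 1e6, 30.0) == pytest.approx(0.5, abs=1e-12)

    def test_ninety_degrees_tr_equals_t1(self):
        assert steady_state_factor(1.0, 1.0, 90.0) == pytest.approx(1 - math.e**-1, abs=1e-12)

    @pytest.mark.parametrize("t1,tr,theta", [(2.0, 3.0, 30.0), (1.5, 0.7, 90.0), (4.0, 13.78, 30.0)])
    def test_matches_bloch_recurrence_oracle(self, t1, tr, theta):
        assert steady_state_factor(t1, tr, theta) == pytest.approx(
            _bloch_fixed_point(t1, tr, theta), abs=1e-12
        )

    def test_five_t1_reaches_99pct_of_asymptote_for_any_flip(self):
        """The >5·T1 full-relaxation rule, scanned over a flip-angle grid."""
        for theta in np.linspace(5, 90, 18):
            f = _bloch_fixed_point(1.0, 5.0, theta)
            assert f / math.sin(math.radians(theta)) >= 0.99

    @given(st.floats(0.5, 8.0), st.floats(5.0, 89.0))
    def test_monotone_increasing_in_repetition_time(self, t1, theta):
        trs = np.linspace(0.2, 50, 40)
        vals = [steady_state_factor(t1, tr, theta) for tr in trs]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            steady_state_factor(0.0, 1.0, 30.0)
        with pytest.raises(ValueError):
            steady_state_factor(1.0, 1.0, 120.0)


class TestSimulateSpectrum:
    def test_same_seed_bit_identical(self, analytes, mixed_truth, noisy_cfg):
        a = simulate_spectrum(analytes, mixed_truth, noisy_cfg)
        b = simulate_spectrum(analytes, mixed_truth, noisy_cfg)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_different_seed_differs(self, analytes, mixed_truth, noisy_cfg):
        a = simulate_spectrum(analytes, mixed_truth, noisy_cfg)
        b = simulate_spectrum(analytes, mixed_truth, replace(noisy_cfg, seed=99))
        assert not np.array_equal(a.intensity, b.intensity)

    def test_zero_concentrations_leave_analyte_windows_empty(self, analytes, clean_cfg):
        truth = SampleTruth(concentrations={})
        s = simulate_spectrum(analytes, truth, clean_cfg)
        dcm_area = integrate_window(s, DICHLOROMETHANE.window).area
        assert dcm_area > 0
        for spec in analytes:
            # only the far tail of the IS singlet reaches the analyte windows
            assert integrate_window(s, spec.window).area <= 1e-5 * dcm_area + 1e-4

    def test_integral_ratio_equals_proton_mole_ratio_for_equal_t1(self, clean_cfg):
        """Noiseless, equal T1: Au/As = (mol_a·n_a)/(mol_is·n_is), hand-computed.

        Same-T1 analyte and IS cancel saturation; window truncation of the
        Lorentzian tails is corrected analytically, leaving pure mole ratios.
        """
        liq = replace(LIQUIRITIN, t1_s=DICHLOROMETHANE.t1_s)
        truth = SampleTruth(concentrations={"liquiritin": 1.0})
        s = simulate_spectrum([liq], truth, clean_cfg)
        ratio = peak_ratio(s, liq.window, DICHLOROMETHANE.window)
        mol_liq = 1.0 * truth.tube_volume_ml / liq.molar_mass
        mol_dcm = truth.internal_standard_conc * truth.tube_volume_ml / DICHLOROMETHANE.molar_mass
        expected = (mol_liq * 1) / (mol_dcm * 2)
        capture = window_capture_fraction(liq) / window_capture_fraction(DICHLOROMETHANE)
        assert ratio == pytest.approx(expected * capture, rel=2e-3)

    def test_noiseless_window_integral_matches_analytic_area_within_1pct(self, clean_cfg):
        """Each window integral equals its analytic (truncated-arctan) target."""
        truth = SampleTruth(concentrations={"liquiritin": 1.2})
        s = simulate_spectrum([LIQUIRITIN], truth, clean_cfg)
        f = steady_state_factor(LIQUIRITIN.t1_s, clean_cfg.meta.repetition_time_s, 30.0)
        nominal = AREA_PER_MMOL_PROTON * truth.mmol_in_tube(LIQUIRITIN) * f
        target = nominal * window_capture_fraction(LIQUIRITIN)
        assert integrate_window(s, LIQUIRITIN.window).area == pytest.approx(target, rel=0.01)

    def test_overlapping_windows_rejected(self, clean_cfg, mixed_truth):
        clash = replace(
            LIQUIRITIN,
            name="clash",
            window=replace(DICHLOROMETHANE.window, name="clash"),
            multiplet=((5.75, 1.0, 0.4),),
        )
        with pytest.raises(SimulationConfigError, match="overlap"):
            simulate_spectrum([clash], mixed_truth, clean_cfg)

    def test_multiplet_center_outside_window_rejected(self):
        with pytest.raises(SpectrumValidationError, match="outside"):
            AnalyteSpec(
                name="bad", molar_mass=100.0, window=LIQUIRITIN.window,
                multiplet=((6.0, 1.0, 0.4),), t1_s=1.0,
            )

    def test_multiplet_intensities_must_sum_to_one(self):
        with pytest.raises(SpectrumValidationError, match="sum"):
            AnalyteSpec(
                name="bad", molar_mass=100.0, window=LIQUIRITIN.window,
                multiplet=((4.88, 0.5, 0.4),), t1_s=1.0,
            )


class TestCalibrationSeries:
    def test_printed_line_generator_reproduces_line_exactly(self, clean_cfg):
        series = make_calibration_series(
            LIQUIRITIN, [0.25, 0.5, 1.0, 1.5, 2.0], clean_cfg, model=(3.9428, 0.0289)
        )
        for conc, s in series:
            ratio = peak_ratio(s, LIQUIRITIN.window, DICHLOROMETHANE.window)
            assert ratio == pytest.approx(3.9428 * conc + 0.0289, abs=1e-9)

    def test_doubling_concentrations_doubles_linear_responses(self, clean_cfg):
        concs = [0.5, 1.0, 2.0]
        through_origin = (2.0, 0.0)
        lo = make_calibration_series(LIQUIRITIN, concs, clean_cfg, model=through_origin)
        hi = make_calibration_series(
            LIQUIRITIN, [2 * c for c in concs], clean_cfg, model=through_origin
        )
        for (_, a), (_, b) in zip(lo, hi):
            ra = peak_ratio(a, LIQUIRITIN.window, DICHLOROMETHANE.window)
            rb = peak_ratio(b, LIQUIRITIN.window, DICHLOROMETHANE.window)
            assert rb == pytest.approx(2 * ra, rel=1e-9)

    def test_single_concentration_refused_downstream(self, clean_cfg):
        series = make_calibration_series(LIQUIRITIN, [1.0], clean_cfg)
        ratios = [peak_ratio(s, LIQUIRITIN.window, DICHLOROMETHANE.window) for _, s in series]
        with pytest.raises(DegenerateDesignError):
            fit_calibration([c for c, _ in series], ratios, "liquiritin")

    def test_empty_concentration_list_rejected(self, clean_cfg):
        with pytest.raises(ValueError):
            make_calibration_series(LIQUIRITIN, [], clean_cfg)


class TestReplicatesAndSpikes:
    def test_noiseless_replicates_identical(self, analytes, mixed_truth, clean_cfg):
        reps = make_replicates(mixed_truth, clean_cfg, 3, analytes=analytes)
        for r in reps[1:]:
            np.testing.assert_array_equal(r.intensity, reps[0].intensity)

    def test_noisy_replicates_distinct_and_deterministic(self, analytes, mixed_truth, noisy_cfg):
        reps = make_replicates(mixed_truth, noisy_cfg, 3, analytes=analytes)
        again = make_replicates(mixed_truth, noisy_cfg, 3, analytes=analytes)
        assert not np.array_equal(reps[0].intensity, reps[1].intensity)
        for a, b in zip(reps, again):
            np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_replicate_count_must_be_at_least_two(self, mixed_truth, noisy_cfg):
        with pytest.raises(ValueError):
            make_replicates(mixed_truth, noisy_cfg, 1)

    def test_replicate_rsd_matches_noise_propagation_oracle(self, mixed_truth):
        """Empirical ratio RSD across replicates matches the analytic
        propagation of i.i.d. grid noise through the trapezoid weights."""
        cfg = SimConfig(grid_points=2**14, ppm_min=4.0, ppm_max=9.0, noise_sd=0.5,
                        baseline_poly=(), seed=5)
        reps = make_replicates(mixed_truth, cfg, 200, analytes=[LIQUIRITIN])
        ratios = [peak_ratio(s, LIQUIRITIN.window, DICHLOROMETHANE.window) for s in reps]
        clean = simulate_spectrum([LIQUIRITIN], mixed_truth, replace(cfg, noise_sd=0.0))
        au = integrate_window(clean, LIQUIRITIN.window).area
        as_ = integrate_window(clean, DICHLOROMETHANE.window).area

        def integral_sd(window):
            mask = clean.window_mask(window)
            x = clean.ppm_axis[mask]
            w = np.zeros(x.size)
            dx = np.abs(np.diff(x))
            w[:-1] += dx / 2
            w[1:] += dx / 2
            return cfg.noise_sd * math.sqrt(float(np.sum(w**2)))

        pred_rsd = 100 * math.sqrt(
            (integral_sd(LIQUIRITIN.window) / au) ** 2
            + (integral_sd(DICHLOROMETHANE.window) / as_) ** 2
        )
        emp_rsd = 100 * np.std(ratios, ddof=1) / np.mean(ratios)
        assert emp_rsd == pytest.approx(pred_rsd, rel=0.25)

    def test_spiked_pair_reports_added_mass_exactly(self, mixed_truth, clean_cfg):
        _, _, added = make_spiked_pair(mixed_truth, 0.5, clean_cfg)
        for name, conc in mixed_truth.concentrations.items():
            assert added[name] == pytest.approx(0.5 * conc * mixed_truth.tube_volume_ml)

    def test_spike_multiplier_must_be_positive(self, mixed_truth, clean_cfg):
        with pytest.raises(ValueError):
            make_spiked_pair(mixed_truth, 0.0, clean_cfg)


def test_sim_config_validation():
    with pytest.raises(SimulationConfigError):
        SimConfig(grid_points=1)
    with pytest.raises(SimulationConfigError):
        SimConfig(ppm_min=5.0, ppm_max=5.0)
    with pytest.raises(SimulationConfigError):
        SimConfig(noise_sd=-0.1)


def test_sample_truth_validation():
    with pytest.raises(SpectrumValidationError):
        SampleTruth(concentrations={"x": -1.0})
    with pytest.raises(SpectrumValidationError):
        SampleTruth(concentrations={}, extract_yield_fraction=1.5)
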