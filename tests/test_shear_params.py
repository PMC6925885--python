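"""Displacement tracking and the four shear-wave parameter estimators."""

import numpy as np
import pytest
from conftest import gaussian_pulse_field

from swqus import (
    DisplacementField,
    PushPeakRecord,
    RFFrame,
    SequenceConfig,
    TissueModel,
    estimate_dispersion_slope,
    estimate_elasticity,
    estimate_shear_absorption,
    estimate_shear_attenuation,
    make_push_peak_record,
    simulate_sequence,
    simulate_shear_wavefield,
    track_displacement,
    voigt_phase_velocity,
)
from swqus.errors import (
    DegeneratePropagationError,
    EstimationError,
    InsufficientDataError,
    InvalidSignalError,
)

FS = 4.0e7
C = 1540.0


def _rf(signal, n_beams=2):
    n = signal.size
    depth = 0.02 + np.arange(n) * C / (2.0 * FS)
    return RFFrame(np.tile(signal, (n_beams, 1)), depth, 3.5e6, FS)


def _rf_pulse(n=512, center=256.0, width=10.0):
    t = np.arange(n, dtype=float)
    return np.exp(-0.5 * ((t - center) / width) ** 2) * np.cos(0.55 * (t - center))


class TestTrackDisplacement:
    def test_identical_frames_give_zero(self):
        f = _rf(_rf_pulse())
        field = track_displacement([f, f, f], kernel_length=128)
        assert np.all(field.displacement == 0.0)

    def test_integer_shift_maps_through_round_trip_convention(self):
        sig = _rf_pulse()
        shifted = np.roll(sig, 3)
        field = track_displacement([_rf(sig), _rf(shifted)], kernel_length=128)
        expected = 3.0 * (C / 2.0) / FS
        tol = 0.02 * (C / 2.0) / FS  # 0.02 sample
        assert np.all(np.abs(field.displacement[:, 1] - expected) < tol)

    def test_subsample_shift_recovered(self):
        """0.25-sample Fourier shift recovered within 0.05 samples by the
        parabolic peak refinement."""
        sig = _rf_pulse()
        spec = np.fft.rfft(sig)
        k = np.fft.rfftfreq(sig.size)
        shifted = np.fft.irfft(spec * np.exp(-2j * np.pi * k * 0.25), sig.size)
        field = track_displacement([_rf(sig), _rf(shifted)], kernel_length=128)
        in_samples = field.displacement[0, 1] / ((C / 2.0) / FS)
        assert in_samples == pytest.approx(0.25, abs=0.05)

    def test_kernel_longer_than_frame_rejected(self):
        f = _rf(_rf_pulse(n=64))
        with pytest.raises(ValueError):
            track_displacement([f, f], kernel_length=128)

    def test_single_frame_rejected(self):
        with pytest.raises(InsufficientDataError):
            track_displacement([_rf(_rf_pulse())], kernel_length=64)


class TestElasticity:
    def test_unit_speed_gives_three_kpa(self):
        """c = 1 m/s, rho = 1 g/cm^3: E = 3 rho c^2 = 3 kPa exactly."""
        field = gaussian_pulse_field(speed=1.0)
        assert estimate_elasticity(field, rho=1.0) == pytest.approx(3.0, rel=1e-6)

    def test_default_density_is_liver(self):
        import inspect

        sig = inspect.signature(estimate_elasticity)
        assert sig.parameters["rho"].default == 1.0

    def test_zerdine_stiffness_recovered(self, seq):
        """Noiseless 24 kPa elastic phantom recovered within 5%."""
        tissue = TissueModel(
            elasticity_E=24.0, shear_viscosity_gamma=0.0, shear_atten_alpha=74.8
        )
        field = simulate_shear_wavefield(tissue, seq, 0)
        assert estimate_elasticity(field, rho=1.0) == pytest.approx(24.0, rel=0.05)

    def test_flat_profile_rejected(self):
        d = np.arange(5) * 1e-3
        t = np.arange(100) * 1e-4
        disp = np.tile(np.exp(-0.5 * ((t - 5e-3) / 1e-3) ** 2), (5, 1))
        with pytest.raises(DegeneratePropagationError):
            estimate_elasticity(DisplacementField(disp, d, t, 0))


class TestDispersionSlope:
    def test_default_band(self):
        import inspect

        sig = inspect.signature(estimate_dispersion_slope)
        assert sig.parameters["band"].default == (50.0, 300.0)

    def test_nondispersive_slope_is_zero(self, elastic_tissue, seq):
        field = simulate_shear_wavefield(elastic_tissue, seq, 0)
        assert abs(estimate_dispersion_slope(field)) < 1e-8

    def test_voigt_slope_matches_closed_form(self, voigt_tissue, seq):
        """SDS of the simulated Voigt field matches the slope of a linear
        fit to the closed-form v(f) on 50-300 Hz within 10%."""
        from swqus import phase_velocity_spectrum

        field = simulate_shear_wavefield(voigt_tissue, seq, 0)
        est = estimate_dispersion_slope(field)
        freqs, _ = phase_velocity_spectrum(field)
        v_cf = voigt_phase_velocity(freqs, voigt_tissue.shear_modulus_pa, 1.5, 1000.0)
        oracle = np.polyfit(freqs, v_cf, 1)[0]
        assert est == pytest.approx(oracle, rel=0.10)
        assert est > 0

    def test_all_pairs_excluded_raises(self):
        # a field whose beams are pure uncorrelated noise yields unphysical
        # velocities; feed a deliberately reversed-propagation field instead
        field = gaussian_pulse_field(speed=2.0)
        reversed_field = DisplacementField(
            field.displacement[::-1].copy(),
            field.beam_distances,
            field.time_axis,
            0,
        )
        with pytest.raises(EstimationError):
            estimate_dispersion_slope(reversed_field)


class TestShearAttenuation:
    def test_equal_maxima_give_zero(self):
        field = gaussian_pulse_field(alpha=0.0)
        assert estimate_shear_attenuation(field) == pytest.approx(0.0, abs=1e-9)

    def test_exact_exponential_maxima(self):
        """Maxima exp(-175 d_i) recover alpha = 175 to numerical precision,
        cross-checked against the closed-form two-point log ratio."""
        field = gaussian_pulse_field(speed=2.0, alpha=175.0)
        est = estimate_shear_attenuation(field, near_region_beams=5)
        d = field.beam_distances
        peaks = np.exp(-175.0 * d)
        two_point = -np.log(peaks[4] / peaks[0]) / (d[4] - d[0])
        assert est == pytest.approx(two_point, rel=1e-9)
        assert est == pytest.approx(175.0, rel=1e-6)

    def test_cohort_mean_regime_recovered(self, seq):
        """alpha_true = 175.2 Neper/m (cohort-mean regime) recovered within
        5% on a noiseless simulated field."""
        tissue = TissueModel(shear_viscosity_gamma=0.0, shear_atten_alpha=175.2)
        field = simulate_shear_wavefield(tissue, seq, 0)
        assert estimate_shear_attenuation(field) == pytest.approx(175.2, rel=0.05)

    def test_monotone_in_true_alpha(self, seq):
        ests = []
        for alpha in (50.0, 120.0, 200.0, 300.0):
            tissue = TissueModel(shear_viscosity_gamma=0.5, shear_atten_alpha=alpha)
            field = simulate_shear_wavefield(tissue, seq, 0)
            ests.append(estimate_shear_attenuation(field))
        assert np.all(np.diff(ests) > 0)

    def test_near_region_bounds_checked(self):
        field = gaussian_pulse_field()
        with pytest.raises(ValueError):
            estimate_shear_attenuation(field, near_region_beams=2)
        with pytest.raises(ValueError):
            estimate_shear_attenuation(field, near_region_beams=99)

    def test_nonpositive_maximum_rejected(self):
        d = np.arange(4) * 1e-3
        t = np.arange(50) * 1e-4
        disp = np.zeros((4, 50))
        disp[:3, 10] = 1.0  # last beam all-zero
        with pytest.raises(InvalidSignalError):
            estimate_shear_attenuation(
                DisplacementField(disp, d, t, 0), near_region_beams=4
            )


class TestShearAbsorption:
    @staticmethod
    def _records(y_values, depths=(0.03, 0.04, 0.05)):
        return [
            PushPeakRecord(
                focus_depth=x, max_displacement=y, voltage=90.0, intensity_proxy=1.0
            )
            for x, y in zip(depths, y_values)
        ]

    def test_equal_compensated_maxima_give_zero(self):
        assert estimate_shear_absorption(self._records([1.0, 1.0, 1.0])) == 0.0

    def test_exact_exponential_recovery(self):
        """y = exp(-2*58.9*x) at the three default foci gives sigma = 58.9
        to machine precision (two-point closed-form oracle)."""
        x = np.array([0.03, 0.04, 0.05])
        y = np.exp(-2.0 * 58.9 * x)
        est = estimate_shear_absorption(self._records(y))
        two_point = -np.log(y[-1] / y[0]) / (2.0 * (x[-1] - x[0]))
        assert est == pytest.approx(two_point, rel=1e-12)
        assert est == pytest.approx(58.9, rel=1e-12)

    def test_default_focus_depths(self, seq):
        assert seq.push_focus_depths == [0.03, 0.04, 0.05]

    def test_end_to_end_from_simulated_pushes(self, seq):
        tissue = TissueModel(shear_absorption_sigma=58.9, shear_viscosity_gamma=1.0)
        fields = simulate_sequence(tissue, seq)
        records = [make_push_peak_record(f, seq) for f in fields]
        assert estimate_shear_absorption(records) == pytest.approx(58.9, rel=0.05)

    def test_proxy_scaling_invariance(self):
        x = np.array([0.03, 0.04, 0.05])
        y = np.exp(-2.0 * 40.0 * x)
        base = self._records(y)
        scaled = [
            PushPeakRecord(r.focus_depth, r.max_displacement, r.voltage, 3.7)
            for r in base
        ]
        assert estimate_shear_absorption(base) == pytest.approx(
            estimate_shear_absorption(scaled), rel=1e-12
        )

    def test_single_depth_rejected(self):
        recs = self._records([1.0, 1.0], depths=(0.03, 0.03))
        with pytest.raises(InsufficientDataError):
            estimate_shear_absorption(recs)


class TestRecoverySweep:
    def test_random_tissue_recovery(self, seq):
        """50 random tissue models, noiseless: median relative errors of
        (E, alpha, sigma) within (10, 5, 5)% and SDS sign matches the
        viscosity sign."""
        rng = np.random.default_rng(42)
        errs_e, errs_a, errs_s = [], [], []
        sign_ok = 0
        for _ in range(50):
            tissue = TissueModel(
                elasticity_E=rng.uniform(6.0, 30.0),
                shear_viscosity_gamma=rng.uniform(0.0, 2.5),
                shear_atten_alpha=rng.uniform(50.0, 300.0),
                shear_absorption_sigma=rng.uniform(20.0, 100.0),
            )
            fields = simulate_sequence(tissue, seq)
            e_hat = np.mean([estimate_elasticity(f) for f in fields])
            a_hat = np.mean([estimate_shear_attenuation(f) for f in fields])
            s_hat = estimate_shear_absorption(
                [make_push_peak_record(f, seq) for f in fields]
            )
            sds = np.mean([estimate_dispersion_slope(f) for f in fields])
            errs_e.append(abs(e_hat - tissue.elasticity_E) / tissue.elasticity_E)
            errs_a.append(
                abs(a_hat - tissue.shear_atten_alpha) / tissue.shear_atten_alpha
            )
            errs_s.append(
                abs(s_hat - tissue.shear_absorption_sigma)
                / tissue.shear_absorption_sigma
            )
            if (sds > 0) == (tissue.shear_viscosity_gamma > 0):
                sign_ok += 1
        assert np.median(errs_e) <= 0.10
        assert np.median(errs_a) <= 0.05
        assert np.median(errs_s) <= 0.05
        assert sign_ok >= 45
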