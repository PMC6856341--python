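"""Evaluation metrics: VAF, spectra, harmonic matching, phases, PCA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import koopgait as kg
from koopgait.metrics import HARMONIC_VISIBILITY, SpectrumTable


class TestVAFAndError:
    def test_perfect_reconstruction(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert kg.vaf(x, x) == 1.0
        assert kg.reconstruction_error(x, x) == 0.0

    def test_zero_reconstruction(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert kg.vaf(x, np.zeros_like(x)) == pytest.approx(0.0)

    def test_half_energy(self):
        theta = np.eye(2)
        theta_hat = np.array([[1.0, 0.0], [0.0, 0.0]])
        assert kg.vaf(theta, theta_hat) == pytest.approx(0.5)

    def test_vaf_can_be_negative(self):
        x = np.ones((2, 3))
        assert kg.vaf(x, -x) == pytest.approx(-3.0)

    def test_all_zero_original_rejected(self):
        with pytest.raises(ValueError):
            kg.vaf(np.zeros((2, 2)), np.ones((2, 2)))

    def test_mean_absolute_error_values(self):
        ones = np.ones((2, 3))
        assert kg.reconstruction_error(ones, np.zeros_like(ones)) == 1.0
        theta_hat = ones.copy()
        theta_hat[0, 0] += 0.6
        assert kg.reconstruction_error(ones, theta_hat) == pytest.approx(0.1)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_vaf_one_iff_zero_error(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(3, 5))
        noise = rng.normal(size=(3, 5)) * rng.choice([0.0, 0.1])
        same = kg.vaf(x, x + noise) == pytest.approx(1.0)
        zero = kg.reconstruction_error(x, x + noise) == pytest.approx(0.0)
        assert same == zero


class TestSpectra:
    def test_single_real_mode_at_dc(self):
        result = kg.DMDResult(
            np.array([1.0 + 0j]),
            np.array([[1.0 + 0j]]),
            np.array([2.0 + 0j]),
            np.array([0j]),
            1,
            "exact",
            0.01,
        )
        spec = kg.dmd_spectrum(result, result.modes)
        np.testing.assert_array_equal(spec.frequency, [0.0])
        np.testing.assert_allclose(spec.magnitude, [2.0])

    def test_conjugate_pair_collapses_to_one_point(self):
        result, _, pair = kg.row_type_hankel_dmd(_tone(1.0), 200, 100, 2)
        obs = kg.row_type_observable_modes(result, pair)
        spec = kg.dmd_spectrum(
            kg.observable_result(result, obs, result.modes[0, :]), obs
        )
        assert spec.frequency.size == 1
        assert spec.frequency[0] == pytest.approx(1.0, abs=1e-3)

    def test_gait_spectrum_peaks_at_harmonics(self, clean_gait, gait_params):
        T, f0, _ = gait_params
        result, obs, _ = kg.column_type_hankel_dmd(clean_gait, T, T, 20)
        spec = kg.dmd_spectrum(kg.observable_result(result, obs), obs)
        top5 = np.sort(spec.frequency[np.argsort(spec.magnitude)[-5:]])
        np.testing.assert_allclose(top5, f0 * np.arange(1, 6), atol=1e-3)

    def test_fourier_pure_tone_single_bin(self):
        dt = 0.01
        t = np.arange(200) * dt  # integer number of 1 Hz periods
        series = kg.AngleSeries(np.cos(2 * np.pi * t)[None, :], dt)
        spec = kg.fourier_spectrum(series)
        peak = np.argmax(spec.magnitude)
        assert spec.frequency[peak] == pytest.approx(1.0)
        assert spec.magnitude[peak] == pytest.approx(1.0, rel=1e-10)
        rest = np.delete(spec.magnitude, peak)
        assert rest.max() < 1e-10

    def test_fourier_constant_only_dc(self):
        series = kg.AngleSeries(np.full((1, 64), 2.5), 0.01)
        spec = kg.fourier_spectrum(series)
        assert spec.magnitude[0] == pytest.approx(2.5)
        assert spec.magnitude[1:].max() < 1e-12

    def test_fourier_channel_averaging_is_linear(self):
        dt = 0.01
        t = np.arange(200) * dt
        x = np.cos(2 * np.pi * t)
        two = kg.fourier_spectrum(kg.AngleSeries(np.vstack([x, 3 * x]), dt))
        one = kg.fourier_spectrum(kg.AngleSeries(x[None, :], dt))
        assert two.magnitude.max() == pytest.approx(2 * one.magnitude.max())

    def test_normalize_and_rescale(self):
        spec = SpectrumTable(np.array([0.8, 1.6]), np.array([4.0, 2.0]))
        rel = kg.normalize_and_rescale_spectrum(spec, 0.8)
        np.testing.assert_allclose(rel.frequency, [1.0, 2.0])
        np.testing.assert_allclose(rel.magnitude, [1.0, 0.5])
        assert rel.normalized and rel.relative
        again = kg.normalize_and_rescale_spectrum(rel, 1.0)
        np.testing.assert_allclose(again.magnitude, rel.magnitude)

    def test_normalize_rejects_zero_spectrum(self):
        spec = SpectrumTable(np.array([1.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            kg.normalize_and_rescale_spectrum(spec, 1.0)


def _tone(freq, dt=0.01, n=600):
    t = np.arange(n) * dt
    return kg.AngleSeries(np.cos(2 * np.pi * freq * t)[None, :], dt)


def _result_with_freqs(freqs_hz, mags=None):
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    p = freqs_hz.size
    lam = np.exp(1j * 2 * np.pi * freqs_hz * 0.01)
    mags = np.ones(p) if mags is None else np.asarray(mags, dtype=float)
    return kg.DMDResult(
        lam,
        mags[None, :].astype(complex),
        np.ones(p, dtype=complex),
        0.0 + 1j * freqs_hz,
        p,
        "synthetic",
        0.01,
    )


class TestHarmonicDeviation:
    def test_exact_harmonics_zero_deviation(self):
        result = _result_with_freqs([1.0, 2.0, 3.0])
        np.testing.assert_allclose(
            kg.harmonic_deviation(result, 1.0, 3), np.zeros(3)
        )

    def test_deviation_arithmetic(self):
        result = _result_with_freqs([1.02, 2.04, 3.06])
        np.testing.assert_allclose(
            kg.harmonic_deviation(result, 1.0, 3), [0.02, 0.02, 0.02]
        )

    def test_out_of_window_harmonic_missing(self):
        result = _result_with_freqs([1.0, 2.0, 3.0])
        dev = kg.harmonic_deviation(result, 1.0, 4)
        assert np.isnan(dev[3]) and np.isfinite(dev[:3]).all()

    def test_each_eigenvalue_used_once(self):
        # one eigenvalue cannot serve two harmonics
        result = _result_with_freqs([1.5])
        dev = kg.harmonic_deviation(result, 1.0, 2)
        assert np.isfinite(dev).sum() == 1

    def test_invisible_modes_excluded(self):
        result = _result_with_freqs([1.0, 2.0], mags=[1.0, 0.01])
        dev = kg.harmonic_deviation(
            result,
            1.0,
            2,
            magnitudes=np.abs(result.modes[0]),
            min_rel_magnitude=HARMONIC_VISIBILITY,
        )
        assert np.isfinite(dev[0]) and np.isnan(dev[1])


class TestFourierAverage:
    def test_complex_exponential_recovered(self):
        dt, f = 0.01, 1.0
        t = np.arange(400) * dt
        series = kg.AngleSeries(np.cos(2 * np.pi * f * t)[None, :], dt)
        phi = kg.fourier_average_eigenfunction(series, f)
        # real tone demodulates to half amplitude; phase ramps at f
        np.testing.assert_allclose(np.abs(phi), 0.5, atol=1e-12)
        slope = np.mean(np.diff(np.unwrap(np.angle(phi))))
        assert slope == pytest.approx(2 * np.pi * f * dt, abs=1e-12)

    def test_absent_frequency_cancels(self):
        dt, f = 0.01, 1.0
        t = np.arange(500) * dt  # integer periods of both 1 and 2 Hz
        series = kg.AngleSeries(np.cos(2 * np.pi * f * t)[None, :], dt)
        with pytest.raises(ValueError, match="not present"):
            kg.fourier_average_eigenfunction(series, 2.0)

    def test_constant_signal_at_zero_frequency(self):
        series = kg.AngleSeries(np.full((1, 50), 1.7), 0.01)
        phi = kg.fourier_average_eigenfunction(series, 0.0)
        np.testing.assert_allclose(phi, 1.7)


class TestPhaseDifference:
    def test_identical_series(self):
        theta = np.linspace(0, 3, 40)
        mean_abs, per_s = kg.phase_difference(theta, theta, 0.01)
        assert mean_abs == 0.0 and per_s == 0.0

    def test_constant_offset_removed(self):
        theta = kg.wrap_phase(np.linspace(0, 12, 100))
        mean_abs, _ = kg.phase_difference(theta, theta - np.pi / 4, 0.01)
        assert mean_abs == pytest.approx(0.0, abs=1e-12)

    def test_linear_drift_closed_form(self):
        t = np.arange(100)
        a = 0.01 * t
        b = np.zeros(100)
        mean_abs, per_s = kg.phase_difference(a, b, 0.01)
        assert mean_abs == pytest.approx(0.495)  # mean |0.01 t|, t=0..99
        assert per_s == pytest.approx(0.495 / 0.99)

    def test_nan_frames_excluded(self):
        a = np.array([0.0, np.nan, 0.2, 0.3])
        b = np.zeros(4)
        mean_abs, _ = kg.phase_difference(a, b, 1.0)
        assert mean_abs == pytest.approx(np.mean([0.0, 0.2, 0.3]))

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            kg.phase_difference([np.nan, np.nan], [0.0, 0.0], 1.0)


class TestSVDBaseline:
    def test_planar_data_fully_explained(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(2, 200))
        basis = np.linalg.qr(rng.normal(size=(4, 2)))[0]
        series = kg.AngleSeries(basis @ coords, 0.01)
        _, _, explained = kg.svd_baseline(series, 2)
        assert explained.sum() == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_noise_spreads_evenly(self):
        rng = np.random.default_rng(1)
        series = kg.AngleSeries(rng.normal(size=(3, 20000)), 0.01)
        _, _, explained = kg.svd_baseline(series, 3)
        np.testing.assert_allclose(explained, 1 / 3, atol=0.02)

    def test_rank_one_temporal_matches_waveform(self):
        t = np.linspace(0, 2 * np.pi, 100)
        wave = np.sin(t)
        series = kg.AngleSeries(np.outer([1.0, 2.0, 0.5], wave), 0.01)
        basis, temporal, explained = kg.svd_baseline(series, 1)
        assert explained[0] == pytest.approx(1.0, abs=1e-12)
        corr = np.corrcoef(temporal[0], wave)[0, 1]
        assert abs(corr) > 1 - 1e-10

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(2)
        series = kg.AngleSeries(rng.normal(size=(3, 50)), 0.01)
        basis, _, _ = kg.svd_baseline(series, 3)
        for j in range(3):
            assert basis[np.argmax(np.abs(basis[:, j])), j] > 0

    def test_k_too_large_rejected(self):
        series = kg.AngleSeries(np.random.default_rng(3).normal(size=(3, 9)), 1.0)
        with pytest.raises(ValueError):
            kg.svd_baseline(series, 4)


class TestPlanarDeviation:
    def test_in_plane_trajectory_is_zero(self):
        basis = np.eye(4)[:, :3]
        traj = basis[:, :2] @ np.random.default_rng(0).normal(size=(2, 30))
        assert kg.planar_deviation(traj, basis) == pytest.approx(0.0, abs=1e-12)

    def test_pc3_excursion_measured(self):
        basis = np.eye(3)
        traj = np.zeros((3, 10))
        traj[2, 4] = 0.2
        assert kg.planar_deviation(traj, basis) == pytest.approx(0.2)

    def test_non_orthonormal_basis_rejected(self):
        basis = np.eye(3)
        basis[0, 1] = 0.5
        with pytest.raises(ValueError, match="orthonormal"):
            kg.planar_deviation(np.zeros((3, 5)), basis)

    def test_harmonic_reconstruction_suppresses_off_plane_noise(self, gait_params):
        # planar 3-channel limit cycle + noise injected only off-plane:
        # the Hankel harmonic reconstruction should stay closer to the
        # plane than the raw noisy data
        T, f0, dt = gait_params
        rng = np.random.default_rng(4)
        t = np.arange(3 * T + 1) * dt
        plane = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        coords = np.vstack(
            [
                np.cos(2 * np.pi * f0 * t) + 0.3 * np.cos(2 * np.pi * 2 * f0 * t),
                np.sin(2 * np.pi * f0 * t),
            ]
        )
        clean = plane[:, :2] @ coords
        noisy = clean + np.outer(plane[:, 2], rng.normal(0, 0.05, t.size))
        series = kg.AngleSeries(noisy, dt)
        result, obs, _ = kg.column_type_hankel_dmd(series, T, T, 8)
        rec = kg.reconstruct(kg.observable_result(result, obs), None, T)
        dev_rec = kg.planar_deviation(rec, plane)
        dev_raw = kg.planar_deviation(noisy[:, :T], plane)
        assert dev_rec < dev_raw


class TestRankedPairMonotonicity:
    def test_vaf_nondecreasing_over_ranked_prefix(self, noisy_gait, gait_params):
        T, _, _ = gait_params
        result, obs, _ = kg.column_type_hankel_dmd(noisy_gait, T, T, 20)
        reduced = kg.observable_result(result, obs)
        original = noisy_gait.values[:, :T]
        groups = kg.rank_conjugate_pairs_by_vaf(reduced, original)
        prev = -np.inf
        chosen = []
        for g in groups[:5]:
            chosen.extend(g)
            score = kg.vaf(original, kg.reconstruct(reduced, chosen, T))
            assert score >= prev - 1e-9
            prev = score
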