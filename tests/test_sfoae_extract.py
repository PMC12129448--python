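"""Extraction chain: artifact excision, averaging, subtraction, LSF spectra,
phase-gradient delays, noise floor, and the exclusion rules."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.interpolate import CubicSpline

from cochleartune.session import SweepSpec, db_spl_to_amplitude
from cochleartune.sfoae_extract import (
    SfoaeSpectrum,
    apply_exclusions,
    average_reps,
    estimate_noise_floor,
    extract_session,
    lsf_spectrum,
    phase_gradient_delay,
    reject_artifacts,
    vector_subtract,
)
from cochleartune.synthetic_ear import EmissionModel, synthesize_session

FS = 50_000.0


class TestRejectArtifacts:
    def test_clean_waveform_untouched(self):
        x = 0.1 * np.sin(np.arange(5000) * 0.01)
        mask, log, dropped = reject_artifacts(x, threshold=0.2, fs=FS)
        assert not mask.any() and log == [] and not dropped

    def test_single_spike_excises_exactly_20ms(self):
        x = np.zeros(100_000)
        x[50_000] = 1.0  # t = 1.0 s
        mask, log, _ = reject_artifacts(x, threshold=0.5, fs=FS)
        assert mask.sum() == 1000  # 20 ms at 50 kHz
        assert log == [(49_500, 50_500)]

    def test_nearby_spikes_merge_to_25ms(self):
        x = np.zeros(100_000)
        x[50_000] = 1.0
        x[50_250] = 1.0  # 5 ms later
        mask, log, _ = reject_artifacts(x, threshold=0.5, fs=FS)
        assert mask.sum() == 1250
        assert log == [(49_500, 50_750)]

    def test_mostly_clipped_rep_is_dropped(self):
        x = np.ones(10_000)
        with pytest.warns(UserWarning, match="dropped"):
            _, _, dropped = reject_artifacts(x, threshold=0.5, fs=FS)
        assert dropped

    @given(
        positions=st.lists(
            st.integers(min_value=600, max_value=99_000), min_size=1, max_size=8
        )
    )
    def test_excision_is_union_of_20ms_windows(self, positions):
        x = np.zeros(100_000)
        for p in positions:
            x[p] = 1.0
        mask, _, _ = reject_artifacts(x, threshold=0.5, fs=FS)
        expected = np.zeros_like(mask)
        for p in positions:
            expected[max(0, p - 500) : p + 500] = True
        assert np.array_equal(mask, expected)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            reject_artifacts(np.zeros(10), threshold=0.0)


class TestAveraging:
    def test_opposite_reps_average_to_zero(self):
        v = np.sin(np.arange(1000) * 0.02)
        mean, n = average_reps(np.vstack([v, -v]))
        assert np.allclose(mean, 0.0)
        assert np.all(n == 2)

    def test_excised_window_averages_remaining_reps(self):
        reps = np.vstack([np.full(100, 1.0), np.full(100, 3.0), np.full(100, 5.0)])
        masks = np.zeros_like(reps, dtype=bool)
        masks[2, 40:60] = True  # third rep excised in a window
        mean, n = average_reps(reps, masks)
        assert np.allclose(mean[:40], 3.0) and np.allclose(mean[60:], 3.0)
        assert np.allclose(mean[40:60], 2.0)  # mean of 1 and 3
        assert np.all(n[40:60] == 2)

    def test_fully_excised_sample_is_interpolated(self):
        reps = np.vstack([np.arange(100.0), np.arange(100.0)])
        masks = np.zeros_like(reps, dtype=bool)
        masks[:, 50] = True
        mean, n = average_reps(reps, masks)
        assert n[50] == 0
        assert mean[50] == pytest.approx(50.0)

    def test_single_rep_rejected(self):
        with pytest.raises(ValueError):
            average_reps(np.zeros((1, 10)))


class TestVectorSubtract:
    def test_linear_session_gives_zero_residual(self):
        rng = np.random.default_rng(0)
        p, s = rng.normal(size=500), rng.normal(size=500)
        assert np.allclose(vector_subtract(p, s, p + s), 0.0)

    def test_additivity_and_homogeneity(self):
        rng = np.random.default_rng(1)
        p, s, e = rng.normal(size=300), rng.normal(size=300), rng.normal(size=300)
        assert np.allclose(vector_subtract(p + e, s, p + s), e)
        r1 = vector_subtract(p, s, p + s + e)
        assert np.allclose(vector_subtract(3 * p, 3 * s, 3 * (p + s + e)), 3 * r1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vector_subtract(np.zeros(10), np.zeros(10), np.zeros(11))


class TestLsfSpectrum:
    SWEEP = SweepSpec(1000.0, 4000.0, 0.4, 40.0, ramp=0.01)

    def test_pure_sweep_amplitude_and_phase(self):
        amp = db_spl_to_amplitude(40.0)
        x = amp * np.cos(self.SWEEP.phase(self.SWEEP.times()))
        spec = lsf_spectrum(x, self.SWEEP)
        assert np.allclose(np.abs(spec.pressure), amp, rtol=10 ** (0.1 / 20) - 1)
        assert np.ptp(spec.phase) < 1e-6

    def test_delayed_sweep_has_linear_phase(self):
        tau = 1e-3
        t = self.SWEEP.times()
        x = np.cos(self.SWEEP.phase(t - tau))
        spec = lsf_spectrum(x, self.SWEEP)
        # phi(f) = -f*tau + const in cycles
        expected = -spec.freq * tau
        fitted = spec.phase - spec.phase[0] + expected[0]
        assert np.allclose(fitted, expected, rtol=0.01)

    def test_zero_input_gives_zero_amplitude(self):
        spec = lsf_spectrum(np.zeros(self.SWEEP.n_samples), self.SWEEP)
        assert np.all(np.abs(spec.pressure) < 1e-15)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError, match="3 cycles"):
            lsf_spectrum(
                np.zeros(self.SWEEP.n_samples), self.SWEEP, window_s=0.002
            )


class TestPhaseGradient:
    def _spectrum(self, freq, phase):
        pressure = 20e-6 * np.exp(1j * 2 * np.pi * phase)
        return SfoaeSpectrum(
            freq=freq,
            pressure=pressure,
            level=np.zeros_like(freq),
            phase=phase,
        )

    def test_linear_phase_identity(self):
        freq = np.linspace(1000, 4000, 301)  # grid contains 2000 Hz exactly
        tau = 1e-3
        delay = phase_gradient_delay(self._spectrum(freq, -freq * tau))
        i = np.argmin(np.abs(freq - 2000.0))
        assert delay.n_sfoae[i] == pytest.approx(2.0, rel=1e-9)
        assert np.allclose(delay.n_sfoae, freq * tau, rtol=1e-9)

    def test_constant_phase_gives_zero_delay(self):
        freq = np.linspace(1000, 4000, 50)
        delay = phase_gradient_delay(self._spectrum(freq, np.full(50, 0.3)))
        assert np.allclose(delay.n_sfoae, 0.0)

    def test_matches_spline_derivative_oracle(self):
        rng = np.random.default_rng(5)
        freq = np.linspace(800, 5000, 400)
        # smooth random phase: a few low-order log-frequency harmonics
        x = np.log(freq / 800.0)
        phase = -(
            2.0 * x + 0.7 * np.sin(1.7 * x) + 0.4 * np.cos(2.3 * x + rng.uniform())
        )
        delay = phase_gradient_delay(self._spectrum(freq, phase))
        oracle = -freq * CubicSpline(freq, phase).derivative()(freq)
        rms = np.sqrt(np.mean((delay.n_sfoae - oracle) ** 2))
        assert rms < 0.02 * np.sqrt(np.mean(oracle**2))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            phase_gradient_delay(
                self._spectrum(np.array([1000.0, 2000.0]), np.zeros(2))
            )


class TestNoiseFloor:
    PROBE = SweepSpec(1000.0, 4000.0, 0.3, 40.0, ramp=0.01)
    SUPP = SweepSpec(1040.0, 4040.0, 0.3, 55.0, ramp=0.01)

    def _floor_and_truth(self, noise_rms, n_reps, seed):
        """Noise-floor estimate and the true noise level of the averaged
        residual (isolated by subtracting the noiseless twin session)."""
        model = EmissionModel.constant_delay(0.5e-3, notches=())
        noisy = synthesize_session(
            model, self.PROBE, self.SUPP, noise_rms=noise_rms, n_reps=n_reps, seed=seed
        )
        clean = synthesize_session(
            model, self.PROBE, self.SUPP, noise_rms=0.0, n_reps=n_reps, seed=seed
        )
        floor = estimate_noise_floor(
            noisy.waveforms["probe"],
            noisy.waveforms["suppressor"],
            noisy.waveforms["both"],
            self.PROBE,
        )
        resid_noise = vector_subtract(
            *(noisy.waveforms[c].mean(axis=0) for c in ("probe", "suppressor", "both"))
        ) - vector_subtract(
            *(clean.waveforms[c].mean(axis=0) for c in ("probe", "suppressor", "both"))
        )
        truth = lsf_spectrum(resid_noise, self.PROBE).level
        return np.median(floor), np.median(truth)

    def test_noiseless_floor_far_below_emission(self):
        ses = synthesize_session(
            EmissionModel.constant_delay(1e-3, level_db=10.0, notches=()),
            self.PROBE,
            self.SUPP,
            noise_rms=0.0,
            n_reps=4,
            seed=0,
        )
        floor = estimate_noise_floor(
            ses.waveforms["probe"],
            ses.waveforms["suppressor"],
            ses.waveforms["both"],
            self.PROBE,
        )
        assert np.median(floor) < 10.0 - 100.0

    def test_floor_tracks_averaged_noise_level(self):
        """Monte Carlo: odd/even floor within 3 dB of the true averaged noise."""
        diffs = []
        for seed in range(100):
            est, truth = self._floor_and_truth(5e-4, 8, seed)
            diffs.append(est - truth)
        assert abs(np.median(diffs)) < 3.0

    def test_doubling_reps_lowers_floor_3db(self):
        d = []
        for seed in range(40):
            f8, _ = self._floor_and_truth(5e-4, 8, seed)
            f16, _ = self._floor_and_truth(5e-4, 16, 1000 + seed)
            d.append(f8 - f16)
        assert 2.0 < np.median(d) < 4.0

    def test_too_few_reps_rejected(self):
        z = np.zeros((2, 100))
        with pytest.raises(ValueError, match="4 repetitions"):
            estimate_noise_floor(z, z, z, self.PROBE)


class TestExclusions:
    def _make(self, level, floor, freq=None):
        n = len(level)
        freq = np.geomspace(1000, 4000, n) if freq is None else freq
        spec = SfoaeSpectrum(
            freq=freq,
            pressure=np.ones(n, complex) * 1e-5,
            level=np.asarray(level, float),
            phase=np.zeros(n),
            noise_floor_level=np.full(n, float(floor)),
        )
        delay = phase_gradient_delay(spec)
        return apply_exclusions(delay, spec)

    def test_point_9db_above_floor_excluded(self):
        level = np.full(50, 15.0)
        level[25] = 9.0
        d = self._make(level, floor=0.0)
        assert not d.valid[25] and d.exclusion_reason[25] == "low_snr"

    def test_point_15db_above_floor_retained(self):
        d = self._make(np.full(50, 15.0), floor=0.0)
        assert d.valid.all()

    def test_deep_notch_excluded_as_trough(self):
        freq = np.geomspace(1000, 6000, 300)
        level = 20.0 - 30.0 * np.exp(-np.log2(freq / 3000.0) ** 2 / (2 * 0.05**2))
        d = self._make(level, floor=-25.0, freq=freq)
        f_min = freq[np.argmin(level)]  # grid point at the notch base
        near = np.abs(np.log2(freq / f_min)) <= 1.0 / 24.0
        assert np.all(~d.valid[near])
        assert np.all(d.exclusion_reason[near] == "trough")
        far = np.abs(np.log2(freq / 3000.0)) > 0.3
        assert d.valid[far].all()

    def test_noise_only_session_mostly_excluded(self):
        """With no emission at all, >= 95% of grid points fail the SNR rule."""
        probe = SweepSpec(1000.0, 4000.0, 0.3, 40.0, ramp=0.01)
        supp = SweepSpec(1040.0, 4040.0, 0.3, 55.0, ramp=0.01)
        ses = synthesize_session(
            EmissionModel.silent(), probe, supp, noise_rms=5e-4, n_reps=8, seed=9
        )
        _, delay = extract_session(ses)
        assert (~delay.valid).mean() >= 0.95


class TestEndToEnd:
    def test_monotone_phase_for_positive_delay(self):
        probe = SweepSpec(1000.0, 4000.0, 0.4, 40.0, ramp=0.01)
        supp = SweepSpec(1040.0, 4040.0, 0.4, 55.0, ramp=0.01)
        ses = synthesize_session(
            EmissionModel.power_law_delay(notches=()),
            probe,
            supp,
            noise_rms=0.0,
            n_reps=4,
            seed=0,
        )
        spec, delay = extract_session(ses)
        assert np.all(np.diff(spec.phase[delay.valid]) < 0)

    def test_window_doubling_changes_delay_under_2pct(self):
        probe = SweepSpec(800.0, 5000.0, 1.0, 40.0, ramp=0.01)
        supp = SweepSpec(840.0, 5040.0, 1.0, 55.0, ramp=0.01)
        ses = synthesize_session(
            EmissionModel.power_law_delay(notches=()),
            probe,
            supp,
            noise_rms=0.0,
            n_reps=4,
            seed=0,
        )
        _, d20 = extract_session(ses, window_s=0.020)
        _, d40 = extract_session(ses, window_s=0.040)
        sel40 = d40.valid & (d40.freq >= 1200) & (d40.freq <= 4500)
        n20 = np.interp(d40.freq[sel40], d20.freq[d20.valid], d20.n_sfoae[d20.valid])
        assert np.max(np.abs(d40.n_sfoae[sel40] / n20 - 1.0)) < 0.02
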