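"""Signal pipeline: Hampel, band-pass, resampling, HMM smoothing, features."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sleeprec.bedsignals import (
    POSTURES,
    RESP_BAND,
    bandpass,
    extract_bed_features,
    hampel,
    preprocess_night,
    resample_1hz,
    simulate_night,
    smooth_posture,
)


def naive_hampel(x, k, n_mad):
    """Per-sample loop oracle, independent of the vectorized path."""
    out = x.copy()
    for i in range(len(x)):
        w = x[max(0, i - k): i + k + 1]
        med = np.median(w)
        mad = np.median(np.abs(w - med))
        if abs(x[i] - med) > n_mad * 1.4826 * mad:
            out[i] = med
    return out


def fft_amplitude(x, fs, freq):
    """Single-bin amplitude of a (whole-period) sinusoid via the DFT."""
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) * 2 / n
    freqs = np.fft.rfftfreq(n, 1 / fs)
    return spec[np.argmin(np.abs(freqs - freq))]


class TestHampel:
    def test_constant_series_unchanged(self):
        x = np.full(50, 3.2)
        np.testing.assert_array_equal(hampel(x), x)

    def test_single_spike_replaced_by_window_median(self, rng):
        x = np.sin(np.linspace(0, 4 * np.pi, 200)) * 0.01
        x[100] = 1.0  # 100x spike
        y = hampel(x, window_half_width=5, n_mad=3.0)
        assert y[100] == np.median(x[95:106])
        np.testing.assert_array_equal(np.delete(y, 100), np.delete(x, 100))

    def test_matches_naive_oracle_on_random_series(self, rng):
        x = rng.normal(size=300)
        x[rng.choice(300, 10, replace=False)] += 20
        np.testing.assert_allclose(hampel(x, 5, 3.0), naive_hampel(x, 5, 3.0))

    def test_idempotent_on_own_output(self, rng):
        """Once spikes are replaced, a second pass changes nothing.

        (Idempotence is a property of the spike-cleaning regime: on a
        smooth signal plus isolated large artifacts the first pass maps
        outliers to local medians, which a second pass cannot flag.)
        """
        t = np.linspace(0, 6 * np.pi, 400)
        x = np.sin(t)
        x[rng.choice(400, 8, replace=False)] += rng.choice([-30, 30], 8)
        once = hampel(x, 5, 3.0)
        np.testing.assert_allclose(hampel(once, 5, 3.0), once)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="longer than series"):
            hampel(np.ones(5), window_half_width=5)


class TestBandpass:
    def test_passband_tone_preserved(self):
        fs, f = 50, 0.3
        t = np.arange(0, 200, 1 / fs)
        x = np.sin(2 * np.pi * f * t)
        y = bandpass(x, fs, *RESP_BAND)
        assert fft_amplitude(y, fs, f) / fft_amplitude(x, fs, f) >= 0.9

    def test_stopband_tone_suppressed(self):
        fs, f = 50, 2.0
        t = np.arange(0, 200, 1 / fs)
        x = np.sin(2 * np.pi * f * t)
        y = bandpass(x, fs, *RESP_BAND)
        assert fft_amplitude(y, fs, f) / fft_amplitude(x, fs, f) <= 0.1

    def test_zero_series_maps_to_zero(self):
        np.testing.assert_allclose(bandpass(np.zeros(500), 50, 0.1, 0.5), 0.0)

    def test_linearity(self, rng):
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        lhs = bandpass(2.0 * x + 3.0 * y, 50, 0.1, 0.5)
        rhs = 2.0 * bandpass(x, 50, 0.1, 0.5) + 3.0 * bandpass(y, 50, 0.1, 0.5)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_band_violating_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.ones(100), fs=1.0, f_low=0.1, f_high=0.6)


class TestResample:
    def test_row_count_equals_night_seconds(self):
        night = simulate_night(0.25, duration_s=70, seed=0)
        assert len(resample_1hz(night)) == 70

    def test_ramp_bin_mean_matches_direct_mean(self):
        night = simulate_night(0.25, duration_s=70, seed=0)
        night.load = np.arange(70 * 50, dtype=float)
        frame = resample_1hz(night, clean_load=False)
        assert frame["load_mean"].iloc[0] == pytest.approx(np.arange(50).mean())
        assert frame["load_mean"].iloc[1] == pytest.approx(np.arange(50, 100).mean())

    def test_constant_streams_give_constant_rows(self):
        night = simulate_night(0.2, duration_s=65, seed=1)
        night.pressure = np.full_like(night.pressure, 2.0)
        frame = resample_1hz(night)
        assert frame["pressure_total"].nunique() == 1

    def test_misaligned_stream_rejected_with_name(self):
        night = simulate_night(0.25, duration_s=70, seed=0)
        night.imu = night.imu[:-5]
        with pytest.raises(ValueError, match="imu"):
            resample_1hz(night)


def brute_force_viterbi(obs, n_states, stickiness, eps):
    """Max over all n_states**T paths of the exact joint log-probability."""
    T = len(obs)
    trans = np.full((n_states, n_states), (1 - stickiness) / (n_states - 1))
    np.fill_diagonal(trans, stickiness)
    emit = np.full((n_states, n_states), eps / (n_states - 1))
    np.fill_diagonal(emit, 1 - eps)
    best, best_lp = None, -np.inf
    for path in itertools.product(range(n_states), repeat=T):
        lp = np.log(1.0 / n_states) + np.log(emit[path[0], obs[0]])
        for t in range(1, T):
            lp += np.log(trans[path[t - 1], path[t]]) + np.log(emit[path[t], obs[t]])
        if lp > best_lp:
            best_lp, best = lp, path
    return np.array(best), best_lp


class TestPostureSmoothing:
    def test_consistent_blocks_decode_to_themselves(self):
        obs = np.repeat([0, 2, 1], 20)
        np.testing.assert_array_equal(smooth_posture(obs), obs)

    def test_single_glitch_removed_at_high_stickiness(self):
        obs = np.zeros(30, dtype=int)
        obs[15] = 3
        decoded = smooth_posture(obs, transition_stickiness=0.95)
        np.testing.assert_array_equal(decoded, np.zeros(30, dtype=int))

    def test_decoded_path_probability_equals_enumeration_max(self, rng):
        """The decoded path attains the exhaustive max over all 4^8 paths.

        Paths (not probabilities) can tie under the symmetric parameters,
        so the oracle comparison is on the joint log-probability.
        """
        def path_lp(path, obs, stickiness, eps):
            n = 4
            trans = np.full((n, n), (1 - stickiness) / (n - 1))
            np.fill_diagonal(trans, stickiness)
            emit = np.full((n, n), eps / (n - 1))
            np.fill_diagonal(emit, 1 - eps)
            lp = np.log(0.25) + np.log(emit[path[0], obs[0]])
            for t in range(1, len(obs)):
                lp += np.log(trans[path[t - 1], path[t]])
                lp += np.log(emit[path[t], obs[t]])
            return lp

        for trial in range(5):
            obs = rng.integers(0, 4, size=8)
            decoded = smooth_posture(obs, 0.9, 0.1)
            _, best_lp = brute_force_viterbi(obs, 4, 0.9, 0.1)
            assert path_lp(decoded, obs, 0.9, 0.1) == pytest.approx(best_lp)

    def test_string_alphabet_accepted_and_unknown_rejected(self):
        obs = np.array(["supine"] * 8 + ["left"] * 8)
        decoded = smooth_posture(obs)
        assert decoded.tolist() == [POSTURES.index(s) for s in obs]
        with pytest.raises(ValueError, match="unknown posture"):
            smooth_posture(np.array(["supine", "sideways"]))

    def test_smoothing_never_adds_flips(self, rng):
        obs = np.repeat(rng.integers(0, 4, size=6), 12)
        flips = rng.random(obs.size) < 0.08
        noisy = obs.copy()
        noisy[flips] = (noisy[flips] + 1) % 4
        decoded = smooth_posture(noisy, transition_stickiness=0.95)
        n_flips = lambda s: int(np.count_nonzero(np.diff(s)))  # noqa: E731
        assert n_flips(decoded) <= n_flips(noisy)


class TestSimulateNight:
    def test_planted_tone_dominates_load_spectrum(self):
        night = simulate_night(0.25, duration_s=120, noise_sd=0.0,
                               n_artifacts=0, seed=0)
        spec = np.abs(np.fft.rfft(night.load))
        freqs = np.fft.rfftfreq(night.load.size, 1 / 50)
        assert freqs[np.argmax(spec)] == pytest.approx(0.25, abs=0.01)

    def test_seed_reproducibility(self):
        a = simulate_night(0.3, duration_s=80, seed=5)
        b = simulate_night(0.3, duration_s=80, seed=5)
        np.testing.assert_array_equal(a.load, b.load)
        np.testing.assert_array_equal(a.pressure, b.pressure)

    def test_artifact_count_as_requested(self):
        night = simulate_night(0.2, duration_s=80, n_artifacts=5, seed=2)
        assert len(night.artifact_positions) == 5

    def test_out_of_band_rate_rejected(self):
        with pytest.raises(ValueError, match="outside band"):
            simulate_night(0.6, duration_s=80)


class TestBedFeatures:
    def test_planted_quarter_hz_gives_15_breaths_per_minute(self):
        night = simulate_night(0.25, duration_s=300, noise_sd=0.2, seed=3)
        _, feats = preprocess_night(night)
        assert feats.respiratory_rate == pytest.approx(15.0, abs=1.0)

    def test_uniform_pressure_entropy_is_log2_cells(self):
        night = simulate_night(0.25, duration_s=120, seed=0)
        frame = resample_1hz(night)
        cells = [c for c in frame.columns
                 if c.startswith("pressure_") and c != "pressure_total"]
        frame[cells] = 1.0
        feats = extract_bed_features(frame)
        assert feats.pressure_entropy == pytest.approx(np.log2(16))

    def test_single_cell_pressure_entropy_is_zero(self):
        night = simulate_night(0.25, duration_s=120, seed=0)
        frame = resample_1hz(night)
        cells = [c for c in frame.columns
                 if c.startswith("pressure_") and c != "pressure_total"]
        frame[cells] = 0.0
        frame[cells[0]] = 5.0
        assert extract_bed_features(frame).pressure_entropy == 0.0

    def test_entropy_bounded_by_log2_cells(self):
        night = simulate_night(0.3, duration_s=150, seed=9)
        _, feats = preprocess_night(night)
        assert 0.0 <= feats.pressure_entropy <= np.log2(16)

    def test_short_frame_rejected(self):
        night = simulate_night(0.25, duration_s=120, seed=0)
        frame = resample_1hz(night)
        with pytest.raises(ValueError, match="60 s"):
            extract_bed_features(frame.iloc[:30])

    def test_posture_transitions_counts_schedule_changes(self):
        night = simulate_night(
            0.25, duration_s=150, posture_flip_prob=0.0,
            posture_schedule=[(0, 0), (50, 2), (100, 1)], seed=1)
        _, feats = preprocess_night(night)
        assert feats.posture_transitions == 2
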