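"""Signal preprocessing and window feature reduction."""

import numpy as np
import pandas as pd
import pytest

from painfusion.features import (
    BAND_DEFINITIONS,
    DataQualityError,
    SchemaError,
    au_session_features,
    band_power,
    bandpass_eeg,
    eeg_session_powers,
    emg_rms,
    heart_rate_from_bvp,
    label_from_vrs,
    mean_slope,
    pupil_velocity_filter,
    respiration_rate,
)
from painfusion.modalities import AU_NAMES, BAND_NAMES

FS_EEG = 500.0


def _sine(freq, fs, seconds, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_stopband_attenuation_at_60hz(self):
        x = _sine(60, FS_EEG, 20)
        y = bandpass_eeg(x, FS_EEG)
        assert np.sqrt(np.mean(y**2)) < 0.1 * np.sqrt(np.mean(x**2))

    def test_passband_flat_at_10hz(self):
        x = _sine(10, FS_EEG, 20)
        y = bandpass_eeg(x, FS_EEG)
        assert np.sqrt(np.mean(y**2)) == pytest.approx(
            np.sqrt(np.mean(x**2)), rel=0.05
        )

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass_eeg(np.zeros(1000), FS_EEG), 0.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            bandpass_eeg(np.ones(100), FS_EEG)


class TestBandPower:
    def test_alpha_power_of_unit_sinusoid_is_half(self):
        # Parseval: variance of a unit sinusoid is 1/2, all inside alpha
        x = _sine(10, FS_EEG, 20)
        p = band_power(x, FS_EEG, BAND_DEFINITIONS["alpha"])
        assert p == pytest.approx(0.5, rel=0.05)

    def test_leakage_into_gamma_is_negligible(self):
        x = _sine(10, FS_EEG, 20)
        assert band_power(x, FS_EEG, BAND_DEFINITIONS["gamma"]) < 0.01

    def test_zero_signal_zero_power(self):
        x = np.zeros(int(20 * FS_EEG))
        for b in BAND_DEFINITIONS.values():
            assert band_power(x, FS_EEG, b) == 0.0

    def test_band_beyond_nyquist_rejected(self):
        from painfusion.features import BandDefinition
        with pytest.raises(ValueError):
            band_power(np.ones(2000), 100.0, BandDefinition("bad", 40, 60))

    def test_band_partition_confines_bandlimited_noise(self):
        # noise confined to one band puts >= 90% of estimated power there
        from scipy import signal as sps
        rng = np.random.default_rng(1)
        sos = sps.butter(6, [8, 13], btype="bandpass", fs=FS_EEG, output="sos")
        x = sps.sosfiltfilt(sos, rng.standard_normal(int(20 * FS_EEG)))
        powers = {b: band_power(x, FS_EEG, BAND_DEFINITIONS[b]) for b in BAND_NAMES}
        assert powers["alpha"] / sum(powers.values()) >= 0.90

    def test_parseval_band_sum_matches_variance(self):
        rng = np.random.default_rng(2)
        x = bandpass_eeg(rng.standard_normal(int(20 * FS_EEG)), FS_EEG)
        total = sum(band_power(x, FS_EEG, BAND_DEFINITIONS[b]) for b in BAND_NAMES)
        assert total == pytest.approx(np.var(x), rel=0.10)


class TestEegSessionPowers:
    def test_shape_and_names(self):
        rng = np.random.default_rng(0)
        window = rng.standard_normal((int(20 * FS_EEG), 8))
        out = eeg_session_powers(window, FS_EEG)
        assert out.shape == (8, 5)
        assert list(out.columns) == list(BAND_NAMES)
        assert out.size == 40

    def test_dc_channel_has_no_band_power(self):
        window = np.full((int(20 * FS_EEG), 1), 42.0)
        out = eeg_session_powers(window, FS_EEG, channels=["Cz"])
        assert (out.to_numpy() < 1e-6).all()

    def test_missing_channel_rejected(self):
        df = pd.DataFrame({"Cz": np.zeros(int(20 * FS_EEG))})
        with pytest.raises(ValueError):
            eeg_session_powers(df, FS_EEG, channels=["Cz", "Pz"])

    def test_doubled_gamma_variance_is_recovered(self):
        # generator-controlled variance ratio: windows rendered with the
        # gamma component's variance doubled show ~2x estimated power
        from painfusion.cohort import GeneratorConfig, render_window

        cfg = GeneratorConfig(eeg_channels=("Pz",), eeg_regions={"Pz": "Parietal"})
        base = {f"eeg.Pz.{b}": np.log(v) for b, v in
                [("delta", 2.0), ("theta", 1.5), ("alpha", 1.8),
                 ("beta", 1.2), ("gamma", 0.8)]}
        doubled = dict(base, **{"eeg.Pz.gamma": np.log(1.6)})
        rng = np.random.default_rng(3)
        est = {"base": [], "doubled": []}
        for _ in range(50):
            for name, latent in [("base", base), ("doubled", doubled)]:
                w = render_window("eeg", latent, cfg, rng)
                p = eeg_session_powers(w, FS_EEG, channels=["Pz"])
                est[name].append(p.loc["Pz", "gamma"])
        ratio = np.mean(est["doubled"]) / np.mean(est["base"])
        assert ratio == pytest.approx(2.0, rel=0.20)


class TestPupilVelocityFilter:
    def test_constant_series_unchanged(self):
        x = np.full(100, 4.0)
        assert np.array_equal(pupil_velocity_filter(x, 50.0), x)

    def test_blink_sample_restored_by_interpolation(self):
        # neighbor velocities 175 mm/s >> 10 mm/s default threshold
        x = np.full(100, 4.0)
        x[50] = 0.5
        out = pupil_velocity_filter(x, 50.0)
        assert out[50] == pytest.approx(4.0)
        assert np.allclose(out, 4.0)

    def test_slow_drift_passes_through(self):
        t = np.arange(1000) / 50.0
        x = 4.0 + 0.01 * t
        assert np.array_equal(pupil_velocity_filter(x, 50.0), x)

    def test_mostly_corrupted_window_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 8, size=200)  # wild jumps everywhere
        with pytest.raises(DataQualityError):
            pupil_velocity_filter(x, 50.0)


class TestPeakRates:
    @pytest.mark.parametrize("period, expected", [(0.8333, 72.0), (1.0, 60.0)])
    def test_heart_rate_from_pulse_train(self, period, expected):
        fs = 2048.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * t / period)
        assert heart_rate_from_bvp(x, fs) == pytest.approx(expected, abs=1.0)

    def test_flat_bvp_rejected(self):
        with pytest.raises(DataQualityError):
            heart_rate_from_bvp(np.zeros(int(20 * 2048)), 2048.0)

    @pytest.mark.parametrize("freq, expected", [(0.25, 15.0), (0.2, 12.0)])
    def test_respiration_rate_from_sinusoid(self, freq, expected):
        fs = 2048.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * freq * t)
        assert respiration_rate(x, fs) == pytest.approx(expected, abs=1.0)

    def test_constant_respiration_rejected(self):
        with pytest.raises(DataQualityError):
            respiration_rate(np.full(int(20 * 2048), 3.0), 2048.0)


class TestScalarSummaries:
    def test_emg_rms_removes_mean(self):
        assert emg_rms(np.full(100, 2.0)) == 0.0
        assert emg_rms(np.zeros(50)) == 0.0

    def test_emg_rms_of_unit_sinusoid(self):
        x = _sine(5, 2048.0, 20)
        assert emg_rms(x) == pytest.approx(1 / np.sqrt(2), rel=1e-3)

    def test_mean_slope_of_exact_line(self):
        fs = 100.0
        t = np.arange(500) / fs
        m, s = mean_slope(3 + 0.05 * t, fs)
        assert s == pytest.approx(0.05, abs=1e-12)
        assert m == pytest.approx(3 + 0.05 * t[-1] / 2, rel=1e-6)

    def test_mean_slope_of_constant(self):
        m, s = mean_slope(np.full(100, 31.5), 10.0)
        assert (m, s) == (31.5, pytest.approx(0.0, abs=1e-12))

    def test_white_noise_slope_statistically_zero(self):
        rng = np.random.default_rng(5)
        fs = 2048.0
        x = rng.standard_normal(40960)
        _, slope = mean_slope(x, fs)
        t = np.arange(x.size) / fs
        se = 1.0 / np.sqrt(np.sum((t - t.mean()) ** 2))
        assert abs(slope) < 3 * se


class TestAuFeatures:
    def test_columnwise_mean(self):
        out = au_session_features(np.full((600, 17), 0.5))
        assert np.allclose(out, 0.5)

    def test_au45_is_last_position(self):
        m = np.zeros((10, 17))
        m[:, AU_NAMES.index("AU45")] = 1.0
        out = au_session_features(m)
        assert out[-1] == 1.0 and np.allclose(out[:-1], 0.0)
        assert AU_NAMES[-1] == "AU45"

    def test_single_frame_echoed(self):
        frame = np.linspace(0, 1, 17)
        assert np.allclose(au_session_features(frame), frame)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(SchemaError):
            au_session_features(np.zeros((10, 16)))


class TestLabeling:
    @pytest.mark.parametrize("rating, expected", [
        (0, "B"), (1, "LP"), (5, "LP"), (6, "HP"), (10, "HP"),
    ])
    def test_session_rating_mapping(self, rating, expected):
        assert label_from_vrs("session", rating) == expected

    def test_baseline_is_b(self):
        assert label_from_vrs("baseline") == "B"

    def test_out_of_range_rating_rejected(self):
        with pytest.raises(ValueError):
            label_from_vrs("session", 11)
        with pytest.raises(ValueError):
            label_from_vrs("session", -1)
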