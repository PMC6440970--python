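"""LFP filtering, Welch spectra, evoked power, r.m.s. courses, spikes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cordfc.core import LfpRecording, SpikeTrain
from cordfc.ephys.signal import (detect_spikes, evoked_power_change,
                                 preprocess_lfp, rms_course, spike_summaries,
                                 welch_psd)
from cordfc.protocols import ephys_protocol
from cordfc.synth.ephys import EphysGenConfig, simulate_lfp, simulate_spikes

FS = 500.0


def _single_channel_rec(x, fs=FS):
    geom = pd.DataFrame([{"channel": 0, "shank": 0, "contact": 0, "depth_um": 0.0}])
    return LfpRecording(np.asarray(x, dtype=np.float32)[None, :], fs, geom)


def _tone(freq, fs=FS, dur=30.0):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestPreprocessLfp:
    def test_line_frequency_suppressed(self):
        out = preprocess_lfp(_single_channel_rec(_tone(60.0)))
        x = out.voltages[0, 2000:-2000]
        assert np.sqrt(np.mean(x**2)) < 0.05 * np.sqrt(0.5)

    def test_stimulus_band_preserved(self):
        out = preprocess_lfp(_single_channel_rec(_tone(8.0)))
        x = out.voltages[0, 2000:-2000]
        assert np.sqrt(np.mean(x**2)) == pytest.approx(np.sqrt(0.5), rel=0.05)

    def test_stopband_attenuated_20db(self):
        out = preprocess_lfp(_single_channel_rec(_tone(200.0)))
        x = out.voltages[0, 2000:-2000]
        assert np.sqrt(np.mean(x**2)) < 0.1 * np.sqrt(0.5)

    def test_band_outside_nyquist_raises(self):
        with pytest.raises(ValueError, match="band"):
            preprocess_lfp(_single_channel_rec(_tone(8.0)), band=(1.0, 300.0))

    def test_respiration_harmonics_notched(self):
        x = sum(_tone(0.5 * k, dur=60.0) for k in range(2, 6))
        out = preprocess_lfp(_single_channel_rec(x), resp_hz=0.5)
        inner = out.voltages[0, 5000:-5000]
        assert np.sqrt(np.mean(inner**2)) < 0.15 * np.sqrt(2.0)


class TestWelchPsd:
    def test_sinusoid_peak_bin_and_integrated_power(self):
        x = _tone(8.0, dur=60.0)
        f, p = welch_psd(x, FS)
        assert f[np.argmax(p)] == pytest.approx(8.0, abs=1e-9)
        total = np.trapezoid(p, f)
        assert total == pytest.approx(0.5, rel=0.1)  # amplitude^2 / 2

    def test_white_noise_parseval(self, rng):
        x = 2.0 * rng.standard_normal(int(120 * FS))
        f, p = welch_psd(x, FS)
        assert np.trapezoid(p, f) == pytest.approx(4.0, rel=0.1)

    def test_dc_signal_concentrates_in_bin_zero(self):
        f, p = welch_psd(np.full(int(20 * FS), 3.0), FS)
        assert p[0] == p.max()
        assert p[1:].max() <= 1e-12 * max(p[0], 1.0)

    def test_short_series_raises(self):
        with pytest.raises(ValueError, match="window"):
            welch_psd(np.zeros(100), FS, window_s=10.0)


class TestEvokedPowerChange:
    def _rec_with_tone_during_on(self, amp, rng, n_channels=2, stim_ch=0):
        protocol = ephys_protocol(n_epochs=4)
        n = int(protocol.duration_s * FS)
        t = np.arange(n) / FS
        on = np.zeros(n, dtype=bool)
        for a, b in protocol.on_windows():
            on |= (t >= a) & (t < b)
        x = rng.standard_normal((n_channels, n))
        x[stim_ch] += amp * np.sin(2 * np.pi * 8.0 * t) * on
        geom = pd.DataFrame([{"channel": c, "shank": 0, "contact": c,
                              "depth_um": 150.0 * c} for c in range(n_channels)])
        return LfpRecording(x.astype(np.float32), FS, geom), protocol

    def test_null_case_change_near_zero(self, rng):
        rec, protocol = self._rec_with_tone_during_on(0.0, rng)
        summary = evoked_power_change(rec, protocol)
        # Monte-Carlo null band: ~2/sqrt(K) relative power fluctuation per
        # 20-s segment pair over 4 epochs stays well under 50%
        assert summary.table["power_change_pct"].abs().max() < 50.0

    def test_added_tone_power_matches_closed_form(self, rng):
        amp = 1.0
        rec, protocol = self._rec_with_tone_during_on(amp, rng)
        summary = evoked_power_change(rec, protocol)
        # noise power in the five 0.1-Hz harmonic bins: 5 bins x df x PSD
        # with unit-variance white noise, PSD = 1/(fs/2) per Hz
        df = 0.1
        noise_power = 5 * df * (2.0 / FS)
        expected = 100.0 * (amp**2 / 2) / noise_power
        got = summary.channel_change(0)
        assert got == pytest.approx(expected, rel=0.35)

    def test_stimulated_channel_is_normalised_maximum(self, rng):
        rec, protocol = self._rec_with_tone_during_on(0.5, rng, n_channels=4,
                                                      stim_ch=2)
        summary = evoked_power_change(rec, protocol)
        table = summary.table
        assert table.loc[table["normalized"] == 1.0, "channel"].iloc[0] == 2
        assert (table.loc[table["channel"] != 2, "normalized"] < 1.0).all()


class TestRmsCourse:
    def test_stationary_noise_fluctuates_about_zero(self, rng):
        protocol = ephys_protocol(n_epochs=6)
        x = rng.standard_normal(int(protocol.duration_s * FS))
        _, course = rms_course(x, FS, protocol)
        assert abs(np.mean(course)) < 5.0

    def test_doubled_amplitude_gives_plus_100_percent(self, rng):
        protocol = ephys_protocol(n_epochs=6)
        n = int(protocol.duration_s * FS)
        t = np.arange(n) / FS
        gain = np.ones(n)
        for a, b in protocol.on_windows():
            gain[(t >= a) & (t < b)] = 2.0
        x = gain * rng.standard_normal(n)
        times, course = rms_course(x, FS, protocol)
        on_bins = (times > 1.0) & (times < 29.0)
        assert np.mean(course[on_bins]) == pytest.approx(100.0, abs=8.0)


class TestDetectSpikes:
    def test_gaussian_crossing_rate_matches_tail_probability(self, rng):
        fs = 20000.0
        x = rng.standard_normal(int(30 * fs))
        train = detect_spikes(x, fs, band=None, k=4.0, dead_time_s=0.0)
        expected = fs * 30 * sps.norm.cdf(-4.0) * (1 - sps.norm.cdf(-4.0))
        assert train.timestamps.size == pytest.approx(expected, rel=0.35)

    def test_strong_templates_recovered(self, rng):
        fs = 30000.0
        dur = 20.0
        x = rng.standard_normal(int(dur * fs))
        width = int(0.001 * fs)
        tpl = -8.0 * np.hanning(width)
        tpl[width // 2:] *= -0.5  # biphasic
        true_times = np.arange(0.5, dur - 0.5, 0.05)
        for tt in true_times:
            i = int(tt * fs)
            x[i:i + width] += tpl
        train = detect_spikes(x, fs, k=4.0, dead_time_s=0.001)
        hits = 0
        for tt in true_times:
            if np.any(np.abs(train.timestamps - (tt + 0.0005)) < 0.0005):
                hits += 1
        assert hits / true_times.size >= 0.99

    def test_weak_templates_recovered_near_chance_only(self, rng):
        # templates far below threshold are found at near-chance rate, in
        # sharp contrast with the >=99% recovery of strong templates
        fs = 30000.0
        x = rng.standard_normal(int(10 * fs))
        width = int(0.001 * fs)
        tpl = -1.0 * np.hanning(width)
        tpl[width // 2:] *= -0.5
        true_times = np.arange(0.5, 9.5, 0.05)
        for tt in true_times:
            x[int(tt * fs):int(tt * fs) + width] += tpl
        train = detect_spikes(x, fs, k=4.0, dead_time_s=0.001)
        hits = sum(np.any(np.abs(train.timestamps - (tt + 0.0005)) < 0.0005)
                   for tt in true_times)
        assert hits / true_times.size < 0.05

    def test_band_above_nyquist_raises(self):
        with pytest.raises(ValueError, match="Nyquist"):
            detect_spikes(np.zeros(1000), 1000.0, band=(250.0, 5000.0))


class TestSpikeSummaries:
    def test_homogeneous_train_shows_no_modulation(self, rng):
        protocol = ephys_protocol(n_epochs=8)
        dur = protocol.duration_s
        n = rng.poisson(10.0 * dur)
        train = SpikeTrain(np.sort(rng.uniform(0, dur, n)))
        summary = spike_summaries(train, protocol)
        on_bins = (summary.times_s >= 0) & (summary.times_s < 30)
        off_bins = summary.times_s >= 30
        diff = summary.rate_hz[on_bins].mean() - summary.rate_hz[off_bins].mean()
        assert abs(diff) < 1.0  # null band for 10 Hz over 8 epochs

    def test_evoked_generator_rate_change_near_700_percent(self):
        cfg = EphysGenConfig(seed=3, duration_s=630.0, baseline_rate_hz=5.0,
                             evoked_rate_hz=40.0)
        protocol = ephys_protocol(n_epochs=10)
        stim_ch = cfg.stim_shank * cfg.contacts_per_shank + cfg.seed_contact
        train = simulate_spikes(cfg, protocol, stim_ch)
        summary = spike_summaries(train, protocol)
        on_bins = (summary.times_s >= 1) & (summary.times_s < 29)
        # (40-5)/5 = +700%; the 3-s pre-onset baseline over 10 epochs has
        # ~8% Poisson sampling error, so the ratio carries a ~200% 3-sigma band
        assert np.mean(summary.rate_change_pct[on_bins]) == pytest.approx(700.0, abs=200.0)

    def test_empty_train_gives_zero_outputs(self):
        protocol = ephys_protocol(n_epochs=3)
        summary = spike_summaries(SpikeTrain(np.array([])), protocol)
        assert not summary.rate_hz.any()
        assert summary.raster.empty


class TestSimulateSpikes:
    def test_zero_rate_gives_empty_train(self):
        cfg = EphysGenConfig(seed=0, baseline_rate_hz=0.0, duration_s=100.0)
        train = simulate_spikes(cfg, None, channel=0)
        assert train.timestamps.size == 0

    def test_poisson_count_within_3_sigma(self):
        cfg = EphysGenConfig(seed=21, baseline_rate_hz=10.0, duration_s=100.0)
        train = simulate_spikes(cfg, None, channel=5)
        assert abs(train.timestamps.size - 1000) <= 95

    def test_evoked_rate_exceeds_baseline_in_every_epoch(self):
        cfg = EphysGenConfig(seed=2, duration_s=630.0, baseline_rate_hz=5.0,
                             evoked_rate_hz=40.0)
        protocol = ephys_protocol(n_epochs=10)
        stim_ch = cfg.stim_shank * cfg.contacts_per_shank + cfg.seed_contact
        ts = simulate_spikes(cfg, protocol, stim_ch).timestamps
        for onset in protocol.onsets_s:
            n_on = np.sum((ts >= onset) & (ts < onset + 30))
            n_off = np.sum((ts >= onset + 30) & (ts < onset + 60))
            assert n_on > n_off

    def test_determinism(self):
        cfg = EphysGenConfig(seed=9, duration_s=120.0)
        a = simulate_spikes(cfg, None, 3).timestamps
        b = simulate_spikes(EphysGenConfig(seed=9, duration_s=120.0), None, 3).timestamps
        assert np.array_equal(a, b)
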