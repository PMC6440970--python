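"""Stimulus-driven LFP and multi-unit analysis.

Filtering (zero-phase notch + band-pass), Welch power spectra, evoked
harmonic power changes, r.m.s. time courses, threshold spike detection and
peri-event spike summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from ..core import LfpRecording, SpikeTrain
from ..protocols import StimulusProtocol


def preprocess_lfp(rec: LfpRecording, line_hz: tuple[float, ...] = (60.0, 120.0),
                   band: tuple[float, float] = (1.0, 150.0),
                   resp_hz: float | None = None, notch_q: float = 30.0,
                   resp_harmonics: int = 5) -> LfpRecording:
    """Notch line frequencies (and respiration harmonics) then band-pass.

    All filters are applied forward-backward (zero phase), so event
    latencies are preserved.  ``resp_hz`` adds notches at its first
    ``resp_harmonics`` harmonics, the extra de-noising used for
    resting-state recordings.
    """
    fs = rec.fs_hz
    nyq = fs / 2.0
    if not 0.0 < band[0] < band[1] < nyq:
        raise ValueError(f"band {band} must lie inside (0, {nyq}) Hz")
    notches = list(line_hz)
    if resp_hz is not None:
        notches += [k * resp_hz for k in range(1, resp_harmonics + 1)]
    # all notches and the band-pass run as one zero-phase SOS cascade
    sections = []
    for f0 in notches:
        if 0 < f0 < nyq:
            sections.append(signal.tf2sos(*signal.iirnotch(f0, notch_q, fs=fs)))
    sections.append(signal.butter(5, band, btype="bandpass", fs=fs, output="sos"))
    sos = np.vstack(sections)
    x = signal.sosfiltfilt(sos, rec.voltages.astype(float), axis=1)
    out = LfpRecording(x.astype(np.float32), fs, rec.geometry, dict(rec.labels),
                       dict(rec.meta))
    out.meta["notched_hz"] = tuple(notches)
    return out


def welch_psd(x: np.ndarray, fs: float, window_s: float = 10.0,
              overlap_s: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Hamming-window Welch power spectral density (units^2 per Hz).

    Frequency resolution is 1/window_s; the default 50-ms overlap follows
    the evoked-analysis convention.  Raises if the series is shorter than
    one window.
    """
    nperseg = int(round(window_s * fs))
    if x.shape[-1] < nperseg:
        raise ValueError("series shorter than one Welch window")
    noverlap = int(round(overlap_s * fs))
    return signal.welch(x, fs=fs, window="hamming", nperseg=nperseg,
                        noverlap=noverlap, detrend="constant", axis=-1)


@dataclass
class EvokedSummary:
    """Per-channel evoked LFP power changes at the stimulus harmonics."""

    table: pd.DataFrame  # channel, power_change_pct, normalized, per-harmonic cols
    harmonics_hz: tuple[float, ...]

    def channel_change(self, channel: int) -> float:
        row = self.table.loc[self.table["channel"] == channel]
        return float(row["power_change_pct"].iloc[0])


def _segment_psd(x: np.ndarray, fs: float, windows: list[tuple[float, float]],
                 window_s: float, overlap_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD averaged over a set of equal-length time windows."""
    psds = []
    freqs = None
    for t0, t1 in windows:
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        if i0 < 0 or i1 > x.shape[-1]:
            continue
        freqs, p = welch_psd(x[..., i0:i1], fs, window_s, overlap_s)
        psds.append(p)
    if not psds:
        raise ValueError("no complete stimulus epochs inside the recording")
    return freqs, np.mean(psds, axis=0)


def evoked_power_change(rec: LfpRecording, protocol: StimulusProtocol,
                        window_on_off_s: float = 20.0, n_harmonics: int = 5,
                        welch_window_s: float = 10.0,
                        welch_overlap_s: float = 0.05) -> EvokedSummary:
    """Percent LFP power change at the first stimulus harmonics, on vs off.

    On/off segments are the ``window_on_off_s`` seconds after and before
    each onset.  Power is summed over the Welch bins nearest 8, 16, ... Hz;
    the percent change is (on - off)/off x 100 per channel, normalised so
    the largest channel equals 1.
    """
    fs = rec.fs_hz
    harmonics = tuple(protocol.freq_hz * (h + 1) for h in range(n_harmonics))
    on_w = [(t, t + window_on_off_s) for t in protocol.onsets_s]
    off_w = [(t - window_on_off_s, t) for t in protocol.onsets_s]
    freqs, p_on = _segment_psd(rec.voltages, fs, on_w, welch_window_s, welch_overlap_s)
    _, p_off = _segment_psd(rec.voltages, fs, off_w, welch_window_s, welch_overlap_s)
    bins = [int(np.argmin(np.abs(freqs - h))) for h in harmonics]
    rows = []
    for ch in range(rec.n_channels):
        on_h = p_on[ch, bins]
        off_h = p_off[ch, bins]
        change = 100.0 * (on_h.sum() - off_h.sum()) / off_h.sum()
        row = {"channel": ch, "power_change_pct": float(change)}
        for h, b in zip(harmonics, bins):
            row[f"pct_{h:g}hz"] = float(100.0 * (p_on[ch, b] - p_off[ch, b]) / p_off[ch, b])
        rows.append(row)
    table = pd.DataFrame(rows)
    peak = table["power_change_pct"].abs().max()
    table["normalized"] = table["power_change_pct"] / (peak if peak > 0 else 1.0)
    return EvokedSummary(table, harmonics)


def rms_course(x: np.ndarray, fs: float, protocol: StimulusProtocol,
               bin_s: float = 0.25, baseline_s: float = 3.0
               ) -> tuple[np.ndarray, np.ndarray]:
    """Epoch-averaged r.m.s. course as percent change vs pre-onset baseline.

    r.m.s. is computed in successive ``bin_s`` windows across each epoch
    (from ``baseline_s`` before onset to the end of the off period),
    averaged over epochs, and referenced to the mean baseline r.m.s.
    Returns (bin centre times relative to onset, percent-change course).
    """
    n_pre = int(round(baseline_s / bin_s))
    n_bins = n_pre + int(round((protocol.on_s + protocol.off_s) / bin_s))
    samples_per_bin = int(round(bin_s * fs))
    courses = []
    for onset in protocol.onsets_s:
        i0 = int(round((onset - baseline_s) * fs))
        i1 = i0 + n_bins * samples_per_bin
        if i0 < 0 or i1 > x.shape[-1]:
            warnings.warn("epoch with incomplete baseline window was dropped")
            continue
        seg = x[i0:i1].reshape(n_bins, samples_per_bin)
        courses.append(np.sqrt((seg.astype(float) ** 2).mean(axis=1)))
    if not courses:
        raise ValueError("no complete epochs inside the recording")
    rms = np.mean(courses, axis=0)
    base = rms[:n_pre].mean()
    times = (np.arange(n_bins) - n_pre + 0.5) * bin_s
    return times, 100.0 * (rms - base) / base


def detect_spikes(broadband: np.ndarray, fs: float,
                  band: tuple[float, float] | None = (250.0, 5000.0),
                  k: float = 4.0, dead_time_s: float = 0.001) -> SpikeTrain:
    """Threshold spike detection on a broadband extracellular trace.

    The trace is band-pass filtered (zero phase), thresholded at -k times
    its r.m.s., and negative-going threshold crossings are kept with one
    event per dead time.  ``band=None`` skips the filter.
    """
    x = np.asarray(broadband, dtype=float)
    if band is not None:
        if band[1] >= fs / 2.0:
            raise ValueError("band upper edge must be below Nyquist")
        sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, x)
    thr = -k * np.sqrt(np.mean(x**2))
    below = x < thr
    crossings = np.nonzero(below[1:] & ~below[:-1])[0] + 1
    if crossings.size:
        dead = max(int(round(dead_time_s * fs)), 1)
        kept = [crossings[0]]
        for c in crossings[1:]:
            if c - kept[-1] >= dead:
                kept.append(c)
        crossings = np.asarray(kept)
    return SpikeTrain(crossings / fs, duration_s=x.size / fs)


@dataclass
class SpikeSummary:
    times_s: np.ndarray          # rate-histogram bin centres relative to onset
    rate_hz: np.ndarray          # epoch-averaged rate
    rate_change_pct: np.ndarray  # percent change vs pre-onset baseline
    raster: pd.DataFrame         # columns: epoch, time_in_epoch_s
    peth_times_s: np.ndarray     # peri-event histogram bin centres
    peth_rate_hz: np.ndarray


def spike_summaries(train: SpikeTrain, protocol: StimulusProtocol,
                    rate_bin_s: float = 1.0, raster_bin_s: float = 0.005,
                    baseline_s: float = 3.0) -> SpikeSummary:
    """Rate histogram, peri-event raster and percent rate change.

    Epoch windows run from ``baseline_s`` before onset to the end of the
    off period.  An empty train yields all-zero outputs.  If the baseline
    rate is zero, the percent change is NaN outside bins that are also
    zero.
    """
    window = baseline_s + protocol.on_s + protocol.off_s
    n_bins = int(round(window / rate_bin_s))
    edges = np.arange(n_bins + 1) * rate_bin_s - baseline_s
    counts = np.zeros(n_bins)
    raster_rows = []
    ts = train.timestamps
    n_epochs = 0
    for e, onset in enumerate(protocol.onsets_s):
        rel = ts[(ts >= onset - baseline_s) & (ts < onset + protocol.on_s + protocol.off_s)] - onset
        counts += np.histogram(rel, bins=edges)[0]
        for r in rel:
            raster_rows.append({"epoch": e, "time_in_epoch_s": float(r)})
        n_epochs += 1
    rate = counts / (n_epochs * rate_bin_s) if n_epochs else counts
    n_pre = int(round(baseline_s / rate_bin_s))
    base = rate[:n_pre].mean() if n_pre else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        change = 100.0 * (rate - base) / base
    change[np.isnan(change) & (rate == 0)] = 0.0

    p_edges = np.arange(int(round(window / raster_bin_s)) + 1) * raster_bin_s - baseline_s
    all_rel = np.array([r["time_in_epoch_s"] for r in raster_rows])
    peth = np.histogram(all_rel, bins=p_edges)[0] / max(n_epochs, 1) / raster_bin_s
    return SpikeSummary(
        times_s=(edges[:-1] + edges[1:]) / 2.0,
        rate_hz=rate,
        rate_change_pct=change,
        raster=pd.DataFrame(raster_rows, columns=["epoch", "time_in_epoch_s"]),
        peth_times_s=(p_edges[:-1] + p_edges[1:]) / 2.0,
        peth_rate_hz=peth,
    )
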