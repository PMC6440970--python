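"""Synthetic multi-shank spinal LFP recordings and spike trains.

The geometry emulates four 16-contact linear arrays (150-um pitch) inserted
into the dorsal-to-intermediate gray matter, two shanks (left/right dorsal
horns) per spinal segment.  Channel voltages are built from:

* a flat band-limited (about 1-100 Hz) shared Gaussian process per segment,
  loaded onto dorsal channels (within-segment dorsal-dorsal coherence) and
  correlated across segments (across-segment coherence);
* a per-shank process shared between the dorsal seed channel and the
  intermediate-GM channel (seed-to-IGM coherence);
* independent broadband Gaussian noise per channel;
* 60/120-Hz line noise and a respiration artifact (fundamental plus
  harmonics) common across channels;
* during stimulus-on blocks, an 8-Hz oscillation plus decaying harmonics on
  the dorsal channels, strongest on the shank mapped to the stimulated
  digit.

Because all stochastic components have flat spectra inside the analysis
band, the magnitude-squared coherence between two channels is the square of
their spectral correlation, so the loadings that deliver target coherences
C solve the same fixed-point system as the fMRI generator with r = sqrt(C).
Estimated coherence carries a small positive bias of roughly 1/K for K
Welch segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from ..core import LfpRecording, SpikeTrain
from ..protocols import StimulusProtocol

#: band-mean magnitude-squared coherence targets for the three pair classes
LFP_TARGETS = {"DD_within": 0.19, "D_IGM": 0.12, "DD_across": 0.04}
#: spectral support of the shared processes (covers the 1-100 Hz analysis band)
SHARED_BAND_HZ = (0.75, 101.0)


def msc_from_ratio(noise_to_shared: float) -> float:
    """Population magnitude-squared coherence of x = s + n1, y = s + n2.

    With Pn/Pss = rho the coherence is (1 / (1 + rho))^2.
    """
    return (1.0 / (1.0 + noise_to_shared)) ** 2


def ratio_for_msc(target: float) -> float:
    """Noise-to-shared power ratio delivering a target coherence."""
    if not 0.0 < target < 1.0:
        raise ValueError("target coherence must lie in (0, 1)")
    return 1.0 / np.sqrt(target) - 1.0


def calibrate_lfp_loadings(c_dd: float = LFP_TARGETS["DD_within"],
                           c_digm: float = LFP_TARGETS["D_IGM"]) -> tuple[float, float]:
    """Solve seed and IGM loadings from the coherence targets.

    Single channels (no ROI averaging), unit channel noise: the spectral
    correlations are r_dd = a^2/(a^2+b^2+1) and
    r_digm = b^2/sqrt((a^2+b^2+1)(b^2+1)), with msc = r^2.
    """
    r_dd, r_digm = np.sqrt(c_dd), np.sqrt(c_digm)

    def eqs(x):
        a2, b2 = x
        v_d = a2 + b2 + 1.0
        return [a2 / v_d - r_dd, b2 / np.sqrt(v_d * (b2 + 1.0)) - r_digm]

    (a2, b2), _, ier, msg = optimize.fsolve(eqs, [1.4, 0.9], full_output=True)
    if ier != 1 or a2 <= 0 or b2 <= 0:
        raise RuntimeError(f"LFP loading calibration failed: {msg}")
    return float(np.sqrt(a2)), float(np.sqrt(b2))


@dataclass
class EphysGenConfig:
    """Settings for the LFP/spike generator (amplitudes in microvolts)."""

    n_shanks: int = 4
    contacts_per_shank: int = 16
    contact_pitch_um: float = 150.0
    fs_lfp_hz: float = 500.0
    duration_s: float = 900.0
    segment_map: tuple[int, ...] = (0, 0, 1, 1)
    seed_contact: int = 2
    loading_dd: float | None = None
    loading_d_igm: float | None = None
    across_segment_corr: float | None = None
    dorsal_decay_um: float = 500.0
    noise_uv: float = 30.0
    line_freqs_hz: tuple[float, ...] = (60.0, 120.0)
    line_amp_uv: float = 15.0
    resp_freq_hz: float = 0.5
    resp_harmonics: int = 5
    resp_amp_uv: float = 8.0
    evoked_8hz_amp: float = 25.0
    harmonic_decay: float = 0.5
    n_harmonics: int = 5
    evoked_spread_um: float = 200.0
    evoked_other_shank_frac: float = 0.3
    stim_shank: int = 0
    baseline_rate_hz: float = 5.0
    evoked_rate_hz: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contact_pitch_um <= 0:
            raise ValueError("contact pitch must be positive")
        if self.fs_lfp_hz <= 2 * max(SHARED_BAND_HZ[1], max(self.line_freqs_hz),
                                     self.n_harmonics * 8.0):
            raise ValueError("sampling rate must exceed twice the highest generated frequency")
        if min(self.baseline_rate_hz, self.evoked_rate_hz) < 0:
            raise ValueError("spike rates must be non-negative")
        if self.across_segment_corr is None:
            self.across_segment_corr = float(
                np.sqrt(LFP_TARGETS["DD_across"] / LFP_TARGETS["DD_within"]))
        if self.loading_dd is None or self.loading_d_igm is None:
            a, b = calibrate_lfp_loadings()
            if self.loading_dd is None:
                self.loading_dd = a
            if self.loading_d_igm is None:
                self.loading_d_igm = b

    @property
    def igm_contact(self) -> int:
        """Contact nearest 1 mm below the seed contact."""
        offsets = np.arange(self.contacts_per_shank) - self.seed_contact
        dist = np.abs(np.abs(offsets) * self.contact_pitch_um - 1000.0)
        # prefer the deeper contact on ties
        order = np.lexsort((-offsets, dist))
        return int(order[0])

    def geometry(self) -> pd.DataFrame:
        rows = []
        ch = 0
        for s in range(self.n_shanks):
            for k in range(self.contacts_per_shank):
                rows.append({"channel": ch, "shank": s, "contact": k,
                             "depth_um": k * self.contact_pitch_um})
                ch += 1
        return pd.DataFrame(rows)


def _flat_band_noise(rng: np.random.Generator, n_series: int, n: int, fs: float,
                     band: tuple[float, float] = SHARED_BAND_HZ) -> np.ndarray:
    """Unit-variance Gaussian processes with flat spectrum inside ``band``."""
    x = rng.standard_normal((n_series, n))
    spec = np.fft.rfft(x, axis=1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[:, ~((f >= band[0]) & (f <= band[1]))] = 0.0
    out = np.fft.irfft(spec, n=n, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def simulate_lfp(cfg: EphysGenConfig,
                 protocol: StimulusProtocol | None = None) -> LfpRecording:
    """Generate a multi-shank LFP recording (resting if ``protocol`` is None)."""
    if cfg.duration_s < 60:
        raise ValueError("recordings must be at least 60 s long")
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs_lfp_hz))
    t = np.arange(n) / cfg.fs_lfp_hz
    geom = cfg.geometry()
    n_ch = len(geom)
    segments = sorted(set(cfg.segment_map[: cfg.n_shanks]))

    # shared processes: correlated per-segment dorsal latents + per-shank IGM latents
    rho = cfg.across_segment_corr
    z = _flat_band_noise(rng, len(segments), n, cfg.fs_lfp_hz)
    seg_latent = {}
    for i, g in enumerate(segments):
        if i == 0:
            seg_latent[g] = z[0]
        else:
            seg_latent[g] = rho * z[0] + np.sqrt(max(1 - rho * rho, 0.0)) * z[i]
    shank_latent = _flat_band_noise(rng, cfg.n_shanks, n, cfg.fs_lfp_hz)

    line = sum(np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
               for f in cfg.line_freqs_hz)
    resp = sum((0.7 ** (k - 1)) *
               np.sin(2 * np.pi * k * cfg.resp_freq_hz * t + rng.uniform(0, 2 * np.pi))
               for k in range(1, cfg.resp_harmonics + 1))

    on_mask = np.zeros(n, dtype=bool)
    if protocol is not None:
        if protocol.duration_s > cfg.duration_s + 1e-9:
            raise ValueError("stimulus protocol extends past the recording")
        for a, b in protocol.on_windows():
            on_mask[(t >= a) & (t < b)] = True
        harmonics = sum(
            (cfg.harmonic_decay ** (h - 1)) *
            np.sin(2 * np.pi * 8.0 * h * t + rng.uniform(0, 2 * np.pi))
            for h in range(1, cfg.n_harmonics + 1))
        evoked_wave = harmonics * on_mask

    a, b = cfg.loading_dd, cfg.loading_d_igm
    d_seed = cfg.seed_contact * cfg.contact_pitch_um
    voltages = np.empty((n_ch, n), dtype=np.float32)
    labels: dict[int, str] = {}
    seed_channels: dict[int, int] = {}
    igm_channels: dict[int, int] = {}
    for _, row in geom.iterrows():
        ch, s, k, depth = (int(row["channel"]), int(row["shank"]),
                           int(row["contact"]), float(row["depth_um"]))
        g = cfg.segment_map[s]
        if k == cfg.seed_contact:
            sig = a * seg_latent[g] + b * shank_latent[s]
            labels[ch] = "dorsal"
            seed_channels[s] = ch
        elif k == cfg.igm_contact:
            sig = b * shank_latent[s]
            labels[ch] = "intermediate"
            igm_channels[s] = ch
        else:
            fall = np.exp(-abs(depth - d_seed) / cfg.dorsal_decay_um)
            sig = a * fall * seg_latent[g]
            labels[ch] = "dorsal" if depth < 750 else "ventral"
        # channel noise shares the latents' spectral support so that the
        # in-band power-density ratios (hence coherences) equal the
        # variance ratios the calibration solves for
        v = cfg.noise_uv * (sig + _flat_band_noise(rng, 1, n, cfg.fs_lfp_hz)[0])
        v += cfg.line_amp_uv * rng.uniform(0.7, 1.3) * line
        v += cfg.resp_amp_uv * rng.uniform(0.7, 1.3) * resp
        if protocol is not None:
            amp = cfg.evoked_8hz_amp * np.exp(-abs(depth - d_seed) / cfg.evoked_spread_um)
            if s != cfg.stim_shank:
                amp *= cfg.evoked_other_shank_frac
            v += amp * evoked_wave
        voltages[ch] = v

    return LfpRecording(
        voltages, cfg.fs_lfp_hz, geom, labels,
        meta={
            "seed_channels": seed_channels,
            "igm_channels": igm_channels,
            "segment_map": tuple(cfg.segment_map[: cfg.n_shanks]),
            "stim_channel": seed_channels[cfg.stim_shank],
        },
    )


def simulate_spikes(cfg: EphysGenConfig, protocol: StimulusProtocol | None,
                    channel: int) -> SpikeTrain:
    """Inhomogeneous Poisson spike train for one channel.

    The rate is ``baseline_rate_hz`` everywhere except during stimulus-on
    blocks on the stimulated channel, where it is ``evoked_rate_hz``.
    Seeded per channel so trains from one configuration are independent.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919, channel]))
    duration = cfg.duration_s
    stim_shank_seed_ch = cfg.stim_shank * cfg.contacts_per_shank + cfg.seed_contact
    is_stim = protocol is not None and channel == stim_shank_seed_ch

    boundaries = [0.0]
    rates = []
    if is_stim:
        for onset, end in protocol.on_windows():
            if onset > boundaries[-1]:
                rates.append(cfg.baseline_rate_hz)
                boundaries.append(min(onset, duration))
            if end > boundaries[-1]:
                rates.append(cfg.evoked_rate_hz)
                boundaries.append(min(end, duration))
        if boundaries[-1] < duration:
            rates.append(cfg.baseline_rate_hz)
            boundaries.append(duration)
    else:
        rates.append(cfg.baseline_rate_hz)
        boundaries.append(duration)

    times = []
    for (t0, t1), rate in zip(zip(boundaries, boundaries[1:]), rates):
        if rate <= 0 or t1 <= t0:
            continue
        count = rng.poisson(rate * (t1 - t0))
        times.append(rng.uniform(t0, t1, count))
    ts = np.sort(np.concatenate(times)) if times else np.array([])
    return SpikeTrain(ts, channel=channel, duration_s=duration)
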