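"""Resting-state LFP connectivity via magnitude-squared coherence.

Seed channels (greatest evoked LFP response per shank) and intermediate-GM
channels (contact nearest 1 mm from the seed on the same shank) anchor the
pair classes compared with the fMRI connectivity:

* ``DD_within``  - dorsal seeds of the two shanks in the same segment,
* ``D_IGM``      - seed to intermediate-GM channel on each shank,
* ``DD_across``  - dorsal seeds on shanks in different segments,
* ``contralateral_depth`` - same-depth contacts on the two shanks of a
  segment, up to 1.5 mm below the dorsal surface.

Coherence is estimated from Welch auto/cross spectra (2-s Hamming windows,
50% overlap) and averaged over a broadband range (default 1-100 Hz)
excluding notched line/respiration bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import signal

from ..core import LfpRecording
from .signal import EvokedSummary

DEFAULT_BAND = (1.0, 100.0)


@dataclass
class CoherenceResult:
    pair: tuple[int, int]
    freqs: np.ndarray
    msc_by_freq: np.ndarray
    band_mean: float
    pair_class: str = ""


def select_dorsal_seed(evoked: EvokedSummary, geometry: pd.DataFrame,
                       shank: int) -> int:
    """Channel with the greatest evoked LFP power change on one shank.

    Ties break toward the shallowest contact.  Raises if no channel on the
    shank shows a positive response.
    """
    chans = geometry.loc[geometry["shank"] == shank]
    merged = chans.merge(evoked.table, on="channel")
    if merged.empty:
        raise ValueError(f"no evoked responses for shank {shank}")
    best = merged["power_change_pct"].max()
    if best <= 0:
        raise ValueError(f"shank {shank}: no responsive channel")
    top = merged.loc[merged["power_change_pct"] == best]
    return int(top.sort_values("depth_um").iloc[0]["channel"])


def select_igm_channel(geometry: pd.DataFrame, seed_channel: int,
                       target_um: float = 1000.0) -> int:
    """Channel on the seed's shank closest to ``target_um`` away in depth.

    Ties break toward the deeper contact.  If no contact reaches at least
    half the target distance, the best available is returned with a warning.
    """
    seed_row = geometry.loc[geometry["channel"] == seed_channel]
    if seed_row.empty:
        raise ValueError(f"seed channel {seed_channel} not in geometry")
    shank = int(seed_row["shank"].iloc[0])
    d0 = float(seed_row["depth_um"].iloc[0])
    cand = geometry.loc[(geometry["shank"] == shank)
                        & (geometry["channel"] != seed_channel)].copy()
    cand["dist"] = (cand["depth_um"] - d0).abs()
    if cand["dist"].max() < target_um / 2.0:
        warnings.warn("seed too close to the array end to reach the IGM target distance")
    cand["err"] = (cand["dist"] - target_um).abs()
    cand = cand.sort_values(["err", "depth_um"], ascending=[True, False])
    return int(cand.iloc[0]["channel"])


def msc(x: np.ndarray, y: np.ndarray, fs: float, window_s: float = 2.0,
        band: tuple[float, float] = DEFAULT_BAND,
        exclude_hz: tuple[float, ...] = (), exclude_halfwidth_hz: float = 1.0
        ) -> CoherenceResult:
    """Magnitude-squared coherence |Sxy|^2 / (Sxx Syy) from Welch spectra.

    Requires at least 8 averaging segments (a single segment gives msc
    identically 1).  ``band_mean`` averages the in-band bins, excluding
    those within ``exclude_halfwidth_hz`` of any excluded (notched)
    frequency.  The estimator carries a positive bias of about 1/K for K
    segments under independence.
    """
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    nperseg = int(round(window_s * fs))
    noverlap = nperseg // 2
    n_segments = (x.shape[-1] - noverlap) // (nperseg - noverlap)
    if n_segments < 8:
        raise ValueError("coherence needs at least 8 Welch segments")
    freqs, coh = signal.coherence(x.astype(float), y.astype(float), fs=fs,
                                  window="hamming", nperseg=nperseg,
                                  noverlap=noverlap)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    for f0 in exclude_hz:
        keep &= np.abs(freqs - f0) > exclude_halfwidth_hz
    if not np.any(keep):
        raise ValueError("no coherence bins left in the requested band")
    return CoherenceResult((0, 0), freqs, coh, float(coh[keep].mean()))


def _pair_msc(rec: LfpRecording, ch_a: int, ch_b: int, pair_class: str,
              band, window_s) -> CoherenceResult:
    exclude = rec.meta.get("notched_hz", ())
    res = msc(rec.voltages[ch_a], rec.voltages[ch_b], rec.fs_hz,
              window_s=window_s, band=band, exclude_hz=tuple(exclude))
    res.pair = (ch_a, ch_b)
    res.pair_class = pair_class
    return res


def connectivity_summary(rec: LfpRecording, seeds: dict[int, int],
                         igm: dict[int, int], segment_map: dict[int, int] | None = None,
                         band: tuple[float, float] = DEFAULT_BAND,
                         window_s: float = 2.0,
                         max_contra_depth_um: float = 1500.0,
                         exclude_channels: tuple[int, ...] = (),
                         subject: str = "subj0") -> pd.DataFrame:
    """Band-mean coherence table over all pair classes of one recording.

    ``seeds``/``igm`` map shank -> channel; ``segment_map`` maps shank ->
    segment (defaults to the recording metadata).  Channels listed in
    ``exclude_channels`` (e.g. artifact-contaminated electrodes) are
    omitted from every pair.  Columns: subject, pair_class, chan_a,
    chan_b, depth_um, band_mean.
    """
    geom = rec.geometry
    if segment_map is None:
        seg_tuple = rec.meta.get("segment_map")
        if seg_tuple is None:
            raise ValueError("no segment map provided or stored in the recording")
        segment_map = {s: g for s, g in enumerate(seg_tuple)}
    shanks = [s for s in sorted(seeds) if seeds[s] not in exclude_channels]
    rows = []

    def add(ch_a, ch_b, cls, depth=np.nan):
        if ch_a in exclude_channels or ch_b in exclude_channels:
            return
        res = _pair_msc(rec, ch_a, ch_b, cls, band, window_s)
        rows.append({"subject": subject, "pair_class": cls, "chan_a": ch_a,
                     "chan_b": ch_b, "depth_um": depth,
                     "band_mean": res.band_mean})

    for s_a, s_b in combinations(shanks, 2):
        cls = "DD_within" if segment_map[s_a] == segment_map[s_b] else "DD_across"
        add(seeds[s_a], seeds[s_b], cls)
    for s in shanks:
        if s in igm:
            add(seeds[s], igm[s], "D_IGM")
    # same-depth contralateral pairs within each segment
    for s_a, s_b in combinations(sorted(set(geom["shank"])), 2):
        if segment_map.get(s_a) != segment_map.get(s_b):
            continue
        ga = geom.loc[geom["shank"] == s_a]
        gb = geom.loc[geom["shank"] == s_b]
        for _, row_a in ga.iterrows():
            d = float(row_a["depth_um"])
            if d > max_contra_depth_um:
                continue
            match = gb.loc[gb["depth_um"] == d]
            if match.empty:
                continue
            add(int(row_a["channel"]), int(match["channel"].iloc[0]),
                "contralateral_depth", depth=d)
    return pd.DataFrame(rows)


def flag_single_subject_classes(table: pd.DataFrame) -> pd.DataFrame:
    """Mark pair classes observed in only one subject (excluded from group
    statistics, mirroring the single-animal exclusion rule)."""
    out = table.copy()
    counts = out.groupby("pair_class")["subject"].nunique()
    out["single_subject"] = out["pair_class"].map(counts < 2)
    return out
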