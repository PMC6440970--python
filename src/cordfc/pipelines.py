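"""End-to-end study pipelines on synthetic data.

These functions chain generation, preprocessing and measurement the way the
experiments were analysed:

* :func:`resting_fmri_study` - N resting runs through motion correction,
  nuisance-PCA GLM and band-pass, then seed-ROI connectivity for the three
  pair classes (within-slice dorsal-dorsal, dorsal-to-functional-IGM with
  left/right concatenated, across-slice dorsal-dorsal).
* :func:`evoked_fmri_study` - N evoked runs; group peak of the
  epoch-averaged ipsilateral dorsal-horn percent-change course.
* :func:`lfp_rest_study` - N synthetic sessions, each with a stimulus run
  (for dorsal-seed selection) and a 15-min resting run; band-mean coherence
  per pair class.

Per-run random seeds are derived deterministically from a base seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BoldSeries, LabelVolume
from .ephys.connectivity import (connectivity_summary, select_dorsal_seed,
                                 select_igm_channel)
from .ephys.signal import evoked_power_change, preprocess_lfp
from .fmri.connectivity import (DepthProfile, RoiSet, build_roi_set,
                                block_response, depth_profile,
                                roi_pair_connectivity)
from .fmri.preprocess import (MotionParams, bandpass, extract_nuisance,
                              glm_denoise, motion_correct_2d, tsnr_gate)
from .protocols import StimulusProtocol, ephys_protocol, fmri_protocol
from .synth.ephys import EphysGenConfig, simulate_lfp
from .synth.fmri import FmriGenConfig, make_phantom, simulate_bold


def run_seed(base_seed: int, index: int) -> int:
    """Derived per-run seed, kept well below 2**31."""
    return (base_seed * 1009 + index) % (2**31 - 1)


@dataclass
class ProcessedRun:
    series: BoldSeries
    motion: MotionParams
    tsnr_map: np.ndarray
    tsnr_pass: bool


def preprocess_resting(series: BoldSeries, phantom: LabelVolume,
                       do_bandpass: bool = True,
                       tsnr_threshold: float = 50.0) -> ProcessedRun:
    """The full denoising chain for one run.

    Motion correction, muscle/CSF nuisance PCA + motion GLM, then (for
    resting analysis) the 0.01-0.1 Hz band-pass.  The tSNR gate is
    evaluated on the motion-corrected series, before filtering.
    """
    corrected, motion = motion_correct_2d(series)
    tsnr_map, passed = tsnr_gate(corrected, phantom.gm_mask(), tsnr_threshold)
    nuis = extract_nuisance(corrected, phantom.noise_mask())
    cleaned = glm_denoise(corrected, nuis, motion)
    if do_bandpass:
        cleaned = bandpass(cleaned)
    return ProcessedRun(cleaned, motion, tsnr_map, passed)


@dataclass
class RestingFmriResult:
    table: pd.DataFrame                       # run, pair_class, side info, value
    profiles: list[DepthProfile]
    group_means: dict[str, float] = field(default_factory=dict)

    def values(self, pair_class: str) -> np.ndarray:
        return self.table.loc[self.table["pair_class"] == pair_class, "value"].to_numpy()


def measure_run_connectivity(processed: ProcessedRun, phantom: LabelVolume,
                             rois: RoiSet | None = None,
                             run_label: str = "run0") -> tuple[pd.DataFrame, list[DepthProfile]]:
    """Pair-class connectivity values and depth profiles for one run."""
    if rois is None:
        rois = build_roi_set(phantom)
    series = processed.series
    mid = phantom.n_slices // 2
    rows = []
    profiles = []

    # within-slice dorsal-dorsal on the middle slice, both directions averaged
    r_lr = roi_pair_connectivity(series, rois.seeds[(mid, "L")], rois.seeds[(mid, "R")], mid)
    r_rl = roi_pair_connectivity(series, rois.seeds[(mid, "R")], rois.seeds[(mid, "L")], mid)
    rows.append({"run": run_label, "pair_class": "DD_within", "side": "LR",
                 "value": (r_lr + r_rl) / 2.0})

    # dorsal seed to functionally defined intermediate GM, each side
    for side in "LR":
        prof = depth_profile(series, rois, mid, side, processed.tsnr_map)
        profiles.append(prof)
        rows.append({"run": run_label, "pair_class": "D_IGM", "side": side,
                     "value": float(prof.r_by_depth[prof.igm_index])})

    # across-slice dorsal-dorsal: middle-slice seeds vs the adjacent slices
    vals = []
    for adj in (mid - 1, mid + 1):
        if not 0 <= adj < phantom.n_slices:
            continue
        for side_a in "LR":
            for side_b in "LR":
                vals.append(roi_pair_connectivity(
                    series, rois.seeds[(mid, side_a)], rois.seeds[(adj, side_b)],
                    mid, adj))
    rows.append({"run": run_label, "pair_class": "DD_across", "side": "all",
                 "value": float(np.mean(vals))})
    return pd.DataFrame(rows), profiles


def resting_fmri_study(n_runs: int = 15, volumes: int = 300, base_seed: int = 1,
                       n_slices: int = 5, apply_tsnr_gate: bool = True
                       ) -> RestingFmriResult:
    """Generate and analyse a group of resting runs with default calibration."""
    phantom = make_phantom(n_slices)
    rois = build_roi_set(phantom)
    tables = []
    profiles: list[DepthProfile] = []
    for i in range(n_runs):
        cfg = FmriGenConfig(volumes=volumes, n_slices=n_slices,
                            seed=run_seed(base_seed, i))
        series = simulate_bold(phantom, cfg)
        processed = preprocess_resting(series, phantom)
        if apply_tsnr_gate and not processed.tsnr_pass:
            continue
        table, profs = measure_run_connectivity(processed, phantom, rois, f"run{i}")
        tables.append(table)
        profiles.extend(profs)
    table = pd.concat(tables, ignore_index=True)
    means = table.groupby("pair_class")["value"].mean()
    return RestingFmriResult(table, profiles, {
        "dd_within": float(means["DD_within"]),
        "d_igm": float(means["D_IGM"]),
        "dd_across": float(means["DD_across"]),
    })


def evoked_fmri_study(n_runs: int = 7, base_seed: int = 1, n_slices: int = 5,
                      protocol: StimulusProtocol | None = None
                      ) -> tuple[float, np.ndarray, np.ndarray]:
    """Group evoked response: mean course over runs and its peak.

    Runs the evoked pipeline (motion correction + nuisance GLM, no
    band-pass) and averages the epoch-averaged ipsilateral dorsal-horn
    percent-change courses across runs; the group peak is the maximum of
    the group-mean course.
    """
    if protocol is None:
        protocol = fmri_protocol()
    volumes = int(np.ceil(protocol.duration_s / 3.0)) + 4
    phantom = make_phantom(n_slices)
    rois = build_roi_set(phantom)
    mid = n_slices // 2
    ipsi_side = "R" if protocol.side == "right" else "L"
    ipsi_dh = rois.compartments[(mid, ipsi_side, "DH")]
    courses = []
    times = None
    for i in range(n_runs):
        cfg = FmriGenConfig(volumes=volumes, n_slices=n_slices,
                            seed=run_seed(base_seed, i))
        series = simulate_bold(phantom, cfg, protocol)
        processed = preprocess_resting(series, phantom, do_bandpass=False)
        times, course, _ = block_response(processed.series, ipsi_dh, mid, protocol)
        courses.append(course)
    group = np.mean(courses, axis=0)
    return float(group.max()), times, group


@dataclass
class LfpStudyResult:
    table: pd.DataFrame
    group_means: dict[str, float] = field(default_factory=dict)


def lfp_session_connectivity(base_cfg_kwargs: dict | None = None, seed: int = 1,
                             subject: str = "subj0",
                             evoked_duration_s: float = 630.0) -> pd.DataFrame:
    """One synthetic session: evoked run for seed selection + resting run.

    Dorsal seeds are the channels with the greatest evoked harmonic power
    change per shank; intermediate-GM channels are the contacts nearest
    1 mm from each seed.  Coherence is then computed on the preprocessed
    resting recording.
    """
    kwargs = dict(base_cfg_kwargs or {})
    stim_cfg = EphysGenConfig(duration_s=evoked_duration_s, seed=seed * 2 + 1, **kwargs)
    protocol = ephys_protocol(
        n_epochs=max(int((evoked_duration_s - 30.0) // 60.0), 1))
    stim_rec = preprocess_lfp(simulate_lfp(stim_cfg, protocol))
    evoked = evoked_power_change(stim_rec, protocol)
    seeds = {s: select_dorsal_seed(evoked, stim_rec.geometry, s)
             for s in range(stim_cfg.n_shanks)}
    igm = {s: select_igm_channel(stim_rec.geometry, seeds[s]) for s in seeds}

    rest_cfg = EphysGenConfig(seed=seed * 2, **kwargs)
    rest = preprocess_lfp(simulate_lfp(rest_cfg), resp_hz=rest_cfg.resp_freq_hz)
    return connectivity_summary(rest, seeds, igm, subject=subject)


def lfp_rest_study(n_recordings: int = 4, base_seed: int = 1,
                   **cfg_kwargs) -> LfpStudyResult:
    """Group LFP coherence study over several synthetic subjects."""
    tables = []
    for i in range(n_recordings):
        tables.append(lfp_session_connectivity(
            cfg_kwargs or None, seed=run_seed(base_seed, i), subject=f"subj{i}"))
    table = pd.concat(tables, ignore_index=True)
    core = table[table["pair_class"].isin(["DD_within", "D_IGM", "DD_across"])]
    means = core.groupby("pair_class")["band_mean"].mean()
    return LfpStudyResult(table, {
        "dd_within": float(means["DD_within"]),
        "d_igm": float(means["D_IGM"]),
        "dd_across": float(means["DD_across"]),
    })
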