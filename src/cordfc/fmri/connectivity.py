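"""ROI connectivity, evoked responses and the depth correlation profile.

Connectivity between two ROIs is the mean of the Pearson correlations
between the first ROI's mean time series and each voxel series of the
second ROI.  The depth profile correlates a small dorsal-horn seed with a
stack of 1-voxel-deep ROIs running dorsal to ventral on one side of the
cord; a U-shaped profile (fall to a minimum at the intermediate gray
matter, rebound toward the ventral horn) defines the functional
intermediate-GM seed as the depth of greatest difference from the dorsal
seed.  Runs without a U shape fall back to the anatomical central-canal
depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import LABELS, BoldSeries, LabelVolume
from ..protocols import StimulusProtocol
from .preprocess import cluster_filter

Roi = np.ndarray  # (n, 2) array of in-plane (row, col) indices


@dataclass
class RoiSet:
    """Named voxel ROIs per slice and side.

    ``seeds[(slice, side)]`` is the 2-3 voxel dorsal-horn seed;
    ``depth_rois[(slice, side)]`` is the ordered dorsal-to-ventral list of
    1-voxel-deep ROIs (2-5 voxels wide); ``igm_fallback_index`` is the
    depth index at the anatomical central-canal level.
    """

    seeds: dict[tuple[int, str], Roi] = field(default_factory=dict)
    depth_rois: dict[tuple[int, str], list[Roi]] = field(default_factory=dict)
    compartments: dict[tuple[int, str, str], Roi] = field(default_factory=dict)
    igm_fallback_index: int = 0


def build_roi_set(phantom: LabelVolume, seed_rows: int = 1) -> RoiSet:
    """Derive seeds, depth ROIs and compartment ROIs from the label volume."""
    rois = RoiSet()
    lab = phantom.labels
    for s in range(phantom.n_slices):
        sl = lab[:, :, s]
        for side in "LR":
            gm_codes = [LABELS[f"{c}_{side}"] for c in ("DH", "IGM", "VH")]
            side_gm = np.isin(sl, gm_codes)
            rows = np.unique(np.nonzero(side_gm)[0])
            depth_list: list[Roi] = []
            for r in rows:
                cols = np.nonzero(side_gm[r])[0]
                depth_list.append(np.column_stack([np.full(cols.size, r), cols]))
            rois.depth_rois[(s, side)] = depth_list
            seed = np.concatenate(depth_list[:seed_rows], axis=0)
            rois.seeds[(s, side)] = seed
            for comp in ("DH", "IGM", "VH"):
                mask = sl == LABELS[f"{comp}_{side}"]
                rois.compartments[(s, side, comp)] = np.column_stack(np.nonzero(mask))
            if side == "L":
                igm_rows = np.unique(np.nonzero(sl == LABELS["IGM_L"])[0])
                centre = igm_rows[len(igm_rows) // 2]
                rois.igm_fallback_index = int(np.searchsorted(rows, centre))
    return rois


def _roi_series(series: BoldSeries, roi: Roi, slice_index: int) -> np.ndarray:
    """(n_voxels, n_time) matrix for one in-plane ROI."""
    return series.data[roi[:, 0], roi[:, 1], slice_index, :]


def roi_pair_connectivity(series: BoldSeries, roi_a: Roi, roi_b: Roi,
                          slice_a: int, slice_b: int | None = None) -> float:
    """Mean correlation of ROI-A's mean series with each ROI-B voxel series."""
    if roi_a.size == 0 or roi_b.size == 0:
        raise ValueError("ROIs must be non-empty")
    if slice_b is None:
        slice_b = slice_a
    mean_a = _roi_series(series, roi_a, slice_a).mean(axis=0)
    mat_b = _roi_series(series, roi_b, slice_b)
    sd_a = mean_a.std()
    if sd_a == 0:
        raise ValueError("ROI-A mean series has zero variance")
    za = (mean_a - mean_a.mean()) / sd_a
    zb = mat_b - mat_b.mean(axis=1, keepdims=True)
    sd_b = zb.std(axis=1)
    if np.any(sd_b == 0):
        raise ValueError("ROI-B contains a zero-variance voxel series")
    r = (zb / sd_b[:, None]) @ za / za.size
    return float(r.mean())


def block_response(series: BoldSeries, roi: Roi, slice_index: int,
                   protocol: StimulusProtocol, baseline_s: float = 12.0
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Epoch-averaged ROI percent-change time course and its peak.

    Each epoch window runs from ``baseline_s`` before onset to the end of
    the off period; the course is expressed as percent change relative to
    the pre-onset baseline mean of that epoch.  Epochs extending past the
    run are dropped with a warning.
    """
    tr = series.tr_seconds
    mean_series = _roi_series(series, roi, slice_index).mean(axis=0)
    n_pre = int(round(baseline_s / tr))
    n_epoch = int(round((protocol.on_s + protocol.off_s) / tr))
    courses = []
    for onset in protocol.onsets_s:
        i0 = int(round(onset / tr)) - n_pre
        i1 = int(round(onset / tr)) + n_epoch
        if i0 < 0 or i1 > series.n_volumes:
            warnings.warn("epoch outside the run was dropped")
            continue
        seg = mean_series[i0:i1]
        base = seg[:n_pre].mean()
        courses.append(100.0 * (seg - base) / base)
    if not courses:
        raise ValueError("no complete epochs inside the run")
    course = np.mean(courses, axis=0)
    times = (np.arange(course.size) - n_pre) * tr
    return times, course, float(course.max())


def activation_map(series: BoldSeries, protocol: StimulusProtocol,
                   threshold: float = 0.6, min_cluster: int = 2) -> np.ndarray:
    """Normalised stimulus-related percent-change map, thresholded and
    cluster-filtered.

    Per voxel: (on-block mean - off-block mean) / off-block mean x 100,
    normalised by the map maximum to [0, 1], thresholded at ``threshold``
    and cleaned with the in-plane cluster filter.  A non-positive maximum
    yields an empty map with a warning.
    """
    tr = series.tr_seconds
    n_t = series.n_volumes
    t = np.arange(n_t) * tr
    on = np.zeros(n_t, dtype=bool)
    off = np.zeros(n_t, dtype=bool)
    for a, b in protocol.on_windows():
        on |= (t >= a) & (t < b)
    for a, b in protocol.off_windows():
        off |= (t >= a) & (t < b)
    data = series.data
    on_mean = data[..., on].mean(axis=3)
    off_mean = data[..., off].mean(axis=3)
    pct = 100.0 * (on_mean - off_mean) / off_mean
    peak = pct.max()
    if peak <= 0:
        warnings.warn("activation map has a non-positive maximum; returning empty map")
        return np.zeros_like(pct)
    norm = pct / peak
    mask = cluster_filter(norm >= threshold, min_cluster)
    return np.where(mask, norm, 0.0)


# ----------------------------------------------------------------------
# depth profile
# ----------------------------------------------------------------------

@dataclass
class DepthProfile:
    """Seed-correlation-by-depth profile for one run, slice and side."""

    r_by_depth: np.ndarray
    tsnr_by_depth: np.ndarray | None
    igm_index: int
    shape_class: str  # "U", "monotone" or "other"
    side: str = "L"
    slice_index: int = 0


def _moving_average3(x: np.ndarray) -> np.ndarray:
    out = x.astype(float).copy()
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    out[0] = (x[0] + x[1]) / 2.0
    out[-1] = (x[-2] + x[-1]) / 2.0
    return out


def classify_profile(r_by_depth: np.ndarray, delta: float = 0.05,
                     fallback_index: int | None = None) -> tuple[str, int | None]:
    """Classify a depth profile as U-shaped, monotone or other.

    After 3-point moving-average smoothing the profile is U-shaped when it
    falls from the superficial depths to an interior minimum by at least
    ``delta`` and rebounds after the minimum by at least ``delta``.  The
    intermediate-GM index is the smoothed argmin (greatest difference from
    the seed's self-correlation); ties break toward the shallower depth.
    Profiles that fall by >= ``delta`` without the rebound are "monotone"
    and take the anatomical ``fallback_index``; anything else is "other".
    """
    r = np.asarray(r_by_depth, dtype=float)
    if r.size < 4:
        raise ValueError("need at least 4 depths to classify a profile")
    s = _moving_average3(r)
    interior = s[1:-1]
    m = 1 + int(np.argmin(interior))
    drop = s[0] - s[m]
    rebound = s[m + 1:].max() - s[m] if m + 1 < s.size else 0.0
    if drop >= delta and rebound >= delta:
        return "U", m
    if drop >= delta:
        return "monotone", fallback_index
    return "other", fallback_index


def depth_profile(series: BoldSeries, rois: RoiSet, slice_index: int, side: str,
                  tsnr_map: np.ndarray | None = None, delta: float = 0.05
                  ) -> DepthProfile:
    """Correlation of the dorsal seed with every depth ROI on one side."""
    depths = rois.depth_rois[(slice_index, side)]
    if len(depths) < 5:
        raise ValueError("need at least 5 depth ROIs")
    seed = rois.seeds[(slice_index, side)]
    r = np.array([
        roi_pair_connectivity(series, seed, d, slice_index) for d in depths
    ])
    tsnr = None
    if tsnr_map is not None:
        tsnr = np.array([
            tsnr_map[d[:, 0], d[:, 1], slice_index].mean() for d in depths
        ])
    shape, igm = classify_profile(r, delta, fallback_index=rois.igm_fallback_index)
    if igm is None:
        igm = rois.igm_fallback_index
    return DepthProfile(r, tsnr, int(igm), shape, side, slice_index)


def align_profiles(profiles: list[DepthProfile], min_count: int = 6) -> pd.DataFrame:
    """Group-average profiles after aligning each one's IGM depth to zero.

    Relative depths observed in fewer than ``min_count`` profiles are
    dropped.  Returns a DataFrame with columns ``rel_depth``, ``mean_r``,
    ``sem_r`` and ``n``.
    """
    if not profiles:
        raise ValueError("no profiles to align")
    rows: dict[int, list[float]] = {}
    for p in profiles:
        for d, r in enumerate(p.r_by_depth):
            rows.setdefault(d - p.igm_index, []).append(float(r))
    records = []
    for rel in sorted(rows):
        vals = np.array(rows[rel])
        if vals.size < min_count:
            continue
        records.append({
            "rel_depth": rel,
            "mean_r": vals.mean(),
            "sem_r": vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0,
            "n": vals.size,
        })
    return pd.DataFrame.from_records(records)
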