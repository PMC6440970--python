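"""Spinal fMRI denoising chain.

The preprocessing reproduces a slice-wise pipeline tailored to the cord:

1. 2D rigid-body motion correction per slice, maximising the mutual
   information of the joint intensity histogram against a reference volume
   (two translations + one rotation per slice per volume).
2. Nuisance regressors extracted from muscle and CSF voxels by principal
   component analysis (a CompCor-style approach): the first three to five
   components covering at least 70% of the cumulative variance.
3. Voxel-wise general linear model regression of the nuisance components and
   the motion parameters; residuals keep the voxel baseline so percent
   signal change remains meaningful.
4. Zero-phase Chebyshev type II band-pass filtering (0.01-0.1 Hz) for
   resting-state analysis.
5. A temporal-SNR gate (mean gray-matter tSNR >= 50) and a cluster-size
   filter (4-connected, in-plane only) against spurious single-voxel
   correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, signal

from ..core import BoldSeries, LabelVolume, MotionParams

TSNR_SENTINEL = 1e6


# ----------------------------------------------------------------------
# band-pass filter
# ----------------------------------------------------------------------

def bandpass_sos(tr_seconds: float, low_hz: float = 0.01, high_hz: float = 0.1,
                 order: int = 5, rs_db: float = 20.0) -> np.ndarray:
    """Chebyshev type II band-pass in second-order sections.

    ``low_hz``/``high_hz`` delimit the pass band; the stop-band corners are
    placed at 0.4x the lower and 1.3x the upper edge (clipped below Nyquist),
    giving a flat pass band (Chebyshev II ripple lives in the stop band) with
    at least ``rs_db`` attenuation outside.  Applied forward-backward, so the
    effective amplitude response is the square of the single-pass response.
    """
    fs = 1.0 / tr_seconds
    nyq = fs / 2.0
    if high_hz >= nyq:
        raise ValueError(
            f"band-pass upper edge {high_hz} Hz must be below Nyquist {nyq:.4f} Hz"
        )
    ws_lo = low_hz * 0.4
    ws_hi = min(high_hz * 1.3, 0.98 * nyq)
    return signal.cheby2(order, rs_db, [ws_lo, ws_hi], btype="bandpass",
                         fs=fs, output="sos")


def bandpass(series: BoldSeries, low_hz: float = 0.01, high_hz: float = 0.1) -> BoldSeries:
    """Zero-phase band-pass per voxel; the temporal mean is preserved.

    The mean is removed before filtering and added back afterwards so that
    the voxel baseline (needed for percent-signal-change computations)
    survives the filter's DC rejection.
    """
    sos = bandpass_sos(series.tr_seconds, low_hz, high_hz)
    data = series.data
    flat = data.reshape(-1, data.shape[3])
    mean = flat.mean(axis=1, keepdims=True)
    filtered = signal.sosfiltfilt(sos, flat - mean, axis=1) + mean
    return BoldSeries(filtered.reshape(data.shape), series.tr_seconds, series.voxel_size)


def white_noise_band_fraction(tr_seconds: float, low_hz: float = 0.01,
                              high_hz: float = 0.1, n_freqs: int = 4096) -> float:
    """Fraction of white-noise variance surviving the zero-phase band-pass.

    Computed from the designed filter's frequency response: the
    forward-backward pass has power gain |H(f)|^4, so the surviving variance
    fraction is the average of |H|^4 over the full band up to Nyquist.  Used
    by the synthetic-data calibration to account for residual thermal noise
    inside the analysis band.
    """
    sos = bandpass_sos(tr_seconds, low_hz, high_hz)
    w, h = signal.sosfreqz(sos, worN=n_freqs)
    return float(np.mean(np.abs(h) ** 4))


# ----------------------------------------------------------------------
# motion correction
# ----------------------------------------------------------------------

def _transform_slice(img: np.ndarray, dx: float, dy: float, theta_deg: float) -> np.ndarray:
    """Rigid in-plane transform (rotation about the slice centre, then shift)."""
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    mat = np.array([[c, -s], [s, c]])
    centre = (np.asarray(img.shape) - 1) / 2.0
    offset = centre - mat @ centre - np.array([dy, dx])
    return ndimage.affine_transform(img, mat, offset=offset, order=1, mode="nearest")


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32,
                        a_edges=None, b_edges=None) -> float:
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins,
                                range=None if a_edges is None else (a_edges, b_edges))
    p = hist / hist.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _phase_shift_init(ref: np.ndarray, mov: np.ndarray) -> tuple[float, float]:
    """Integer-pixel shift initialisation via FFT cross-correlation."""
    f = np.fft.fft2(ref) * np.conj(np.fft.fft2(mov))
    denom = np.abs(f)
    denom[denom == 0] = 1.0
    corr = np.fft.ifft2(f / denom).real
    idx = np.unravel_index(np.argmax(corr), corr.shape)
    shifts = np.array(idx, dtype=float)
    for ax, n in enumerate(ref.shape):
        if shifts[ax] > n / 2:
            shifts[ax] -= n
    dy, dx = shifts
    return float(dx), float(dy)


def motion_correct_2d(series: BoldSeries, reference_index: int = 0,
                      bins: int = 32, max_shift: float = 3.0,
                      max_rot_deg: float = 5.0,
                      presmooth_sigma: float = 1.0) -> tuple[BoldSeries, MotionParams]:
    """Slice-wise rigid-body motion correction by mutual-information maximisation.

    Every slice of every volume is aligned to the corresponding slice of the
    reference volume with an in-plane rigid transform (dx, dy, theta).  The
    cost is the negative mutual information of a 32-bin joint intensity
    histogram, evaluated on lightly Gaussian-smoothed copies of the images
    (``presmooth_sigma`` voxels) — smoothing regularises the histogram so
    the MI landscape stays smooth at sub-voxel scale.  Optimisation starts
    from an FFT cross-correlation shift estimate and refines all three
    parameters with Powell's method; the estimated transform is applied to
    the unsmoothed data.

    Returns the resampled series and the applied correction parameters
    (identity for the reference volume).  A constant (zero-contrast) slice
    cannot be registered; it is left untouched with a warning.
    """
    if series.n_volumes < 2:
        raise ValueError("motion correction needs at least 2 volumes")
    data = series.data
    ny, nx, n_sl, n_t = data.shape
    out = data.copy()
    dx_p = np.zeros((n_sl, n_t))
    dy_p = np.zeros((n_sl, n_t))
    th_p = np.zeros((n_sl, n_t))

    def smooth(img: np.ndarray) -> np.ndarray:
        if presmooth_sigma > 0:
            return ndimage.gaussian_filter(img, presmooth_sigma)
        return img

    for s in range(n_sl):
        ref = data[:, :, s, reference_index].astype(float)
        if np.ptp(ref) == 0:
            warnings.warn(f"slice {s}: reference has no contrast; skipping registration")
            continue
        ref_s = smooth(ref)
        # reference digitisation is fixed across cost evaluations; the moving
        # image is binned with linear partial-volume weights so the MI cost
        # varies smoothly with sub-voxel displacements
        ref_idx = np.clip(((ref_s - ref_s.min()) / np.ptp(ref_s) * bins).astype(np.int32),
                          0, bins - 1).ravel() * bins
        for t in range(n_t):
            if t == reference_index:
                continue
            mov = data[:, :, s, t].astype(float)
            if np.ptp(mov) == 0:
                warnings.warn(f"slice {s}, volume {t}: constant slice; identity used")
                continue
            mov_s = smooth(mov)
            m_min = mov_s.min()
            m_scale = (bins - 1) / np.ptp(mov_s)

            def cost(p: np.ndarray) -> float:
                dx, dy, th = p
                if abs(dx) > max_shift or abs(dy) > max_shift or abs(th) > max_rot_deg:
                    return 0.0  # outside the search range: no information
                moved = _transform_slice(mov_s, dx, dy, th)
                frac = np.clip((moved - m_min) * m_scale, 0, bins - 1 - 1e-9).ravel()
                lo = frac.astype(np.int32)
                w = frac - lo
                joint = np.bincount(ref_idx + lo, weights=1.0 - w,
                                    minlength=bins * bins)
                joint += np.bincount(ref_idx + lo + 1, weights=w,
                                     minlength=bins * bins)
                p_ab = joint / joint.sum()
                pa = p_ab.reshape(bins, bins).sum(axis=1)
                pb = p_ab.reshape(bins, bins).sum(axis=0)
                nz = p_ab > 0
                outer = np.outer(pa, pb).ravel()
                return -float(np.sum(p_ab[nz] * np.log(p_ab[nz] / outer[nz])))

            x0 = np.array([*_phase_shift_init(ref_s, mov_s), 0.0])
            x0[:2] = np.clip(x0[:2], -max_shift, max_shift)
            res = optimize.minimize(
                cost, x0, method="Powell",
                options={"xtol": 0.005, "ftol": 1e-6, "maxfev": 250},
            )
            dx, dy, th = res.x
            dx_p[s, t], dy_p[s, t], th_p[s, t] = dx, dy, th
            out[:, :, s, t] = _transform_slice(mov, dx, dy, th)

    params = MotionParams(dx_p, dy_p, th_p, reference_index)
    return BoldSeries(out, series.tr_seconds, series.voxel_size), params


# ----------------------------------------------------------------------
# nuisance extraction and regression
# ----------------------------------------------------------------------

@dataclass
class NuisanceSet:
    """PCA nuisance regressors: time x k matrix with zero-mean, orthogonal
    columns, plus the cumulative variance fraction they explain."""

    regressors: np.ndarray
    explained_fraction: float
    singular_values: np.ndarray


def extract_nuisance(series: BoldSeries, noise_mask: np.ndarray,
                     var_threshold: float = 0.70, k_min: int = 3,
                     k_max: int = 5) -> NuisanceSet:
    """Principal components of the muscle/CSF voxel-by-time matrix.

    k is the smallest component count whose cumulative variance reaches
    ``var_threshold``, clamped into [k_min, k_max] and to the matrix rank.
    """
    if not np.any(noise_mask):
        raise ValueError("noise mask is empty")
    x = series.data[noise_mask, :].T.astype(float)  # time x voxels
    x = x - x.mean(axis=0, keepdims=True)
    u, sv, _ = np.linalg.svd(x, full_matrices=False)
    var = sv**2
    total = var.sum()
    if total <= 0:
        raise ValueError("noise-mask voxels have zero variance")
    cum = np.cumsum(var) / total
    k = int(np.searchsorted(cum, var_threshold) + 1)
    k = min(max(k, k_min), k_max)
    rank = int(np.sum(sv > sv[0] * max(x.shape) * np.finfo(float).eps))
    if rank < k_min:
        warnings.warn(f"noise matrix rank {rank} < k_min {k_min}; returning {rank} components")
    k = min(k, rank)
    return NuisanceSet(u[:, :k] * sv[:k], float(cum[k - 1]), sv[:k])


def glm_denoise(series: BoldSeries, nuisance: NuisanceSet | None,
                motion: MotionParams | None = None) -> BoldSeries:
    """Voxel-wise OLS removal of nuisance and motion regressors.

    The design per slice is [intercept | nuisance PCs | slice motion
    parameters]; the returned series is the residual plus the fitted
    intercept, so the baseline is preserved for percent-change computations.
    Collinear columns are dropped (via rank-revealing QR) with a warning.
    """
    data = series.data
    ny, nx, n_sl, n_t = data.shape
    out = np.empty_like(data, dtype=float)
    base_cols = [np.ones(n_t)]
    if nuisance is not None:
        if nuisance.regressors.shape[0] != n_t:
            raise ValueError("nuisance regressor rows must match the time axis")
        base_cols.append(nuisance.regressors - nuisance.regressors.mean(axis=0))
    for s in range(n_sl):
        cols = list(base_cols)
        if motion is not None:
            cols.append(motion.as_design(s))
        design = np.column_stack(cols)
        q, r = np.linalg.qr(design)
        keep = np.abs(np.diag(r)) > np.abs(r[0, 0]) * 1e-10
        if not np.all(keep):
            warnings.warn("rank-deficient GLM design; dropping collinear columns")
            design = design[:, keep]
        y = data[:, :, s, :].reshape(-1, n_t).T.astype(float)  # time x voxels
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        resid += beta[0]  # intercept column is always first and always kept
        out[:, :, s, :] = resid.T.reshape(ny, nx, n_t)
    return BoldSeries(out, series.tr_seconds, series.voxel_size)


# ----------------------------------------------------------------------
# quality gates
# ----------------------------------------------------------------------

def tsnr_gate(series: BoldSeries, gm_mask: np.ndarray,
              threshold: float = 50.0) -> tuple[np.ndarray, bool]:
    """Temporal SNR map and a pass flag for the run.

    tSNR = temporal mean / temporal s.d. after linear detrending.  Voxels
    with (numerically) zero variance get a large sentinel value and are
    excluded from the gray-matter mean used for the gate.
    """
    if not np.any(gm_mask):
        raise ValueError("gray-matter mask is empty")
    data = series.data.astype(float)
    detr = signal.detrend(data, axis=3, type="linear")
    sd = detr.std(axis=3)
    mean = data.mean(axis=3)
    tsnr = np.full(sd.shape, TSNR_SENTINEL)
    ok = sd > np.abs(mean) * 1e-9 + 1e-12
    tsnr[ok] = mean[ok] / sd[ok]
    gm_vals = tsnr[gm_mask]
    gm_vals = gm_vals[gm_vals < TSNR_SENTINEL]
    passed = bool(gm_vals.size and gm_vals.mean() >= threshold)
    return tsnr, passed


def cluster_filter(binary_map: np.ndarray, min_size: int = 2) -> np.ndarray:
    """Remove in-plane connected components smaller than ``min_size``.

    Connectivity is 4-connected within each slice and never across slices,
    matching the slice-wise processing of the rest of the pipeline.
    """
    mask = np.asarray(binary_map).astype(bool)
    if mask.ndim == 2:
        mask = mask[:, :, None]
        squeeze = True
    else:
        squeeze = False
    out = np.zeros_like(mask)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for s in range(mask.shape[2]):
        lab, n = ndimage.label(mask[:, :, s], structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = sizes[1:] >= min_size
        out[:, :, s] = keep[lab]
    return out[:, :, 0] if squeeze else out


def resample_inplane(series: BoldSeries, factor: int = 2) -> BoldSeries:
    """Linear in-plane upsampling (e.g. functional 0.5 mm -> 0.25 mm grid)."""
    data = series.data
    out = ndimage.zoom(data, (factor, factor, 1, 1), order=1)
    vx = series.voxel_size
    return BoldSeries(out, series.tr_seconds, (vx[0] / factor, vx[1] / factor, vx[2]))
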