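"""fMRI denoising chain: filters, registration, PCA nuisance, GLM, gates."""

import numpy as np
import pytest
from scipy import signal

from cordfc.core import BoldSeries
from cordfc.fmri.preprocess import (TSNR_SENTINEL, bandpass, bandpass_sos,
                                    cluster_filter, extract_nuisance,
                                    glm_denoise, motion_correct_2d,
                                    _transform_slice, tsnr_gate)
from cordfc.synth.fmri import FmriGenConfig, simulate_bold


def _filtfilt_gain(tr, freq, n=6000):
    sos = bandpass_sos(tr)
    t = np.arange(n) * tr
    x = np.sin(2 * np.pi * freq * t)
    y = signal.sosfiltfilt(sos, x)
    return y[n // 4: -n // 4].std() / x.std()


class TestBandpass:
    def test_constant_series_is_preserved(self):
        series = BoldSeries(np.full((3, 3, 1, 200), 42.0), 3.0)
        out = bandpass(series)
        assert np.allclose(out.data, 42.0, atol=1e-8)

    def test_passband_sinusoid_amplitude_preserved(self):
        assert _filtfilt_gain(1.5, 0.05) >= 0.95

    def test_stopband_sinusoid_attenuated_20db(self):
        assert _filtfilt_gain(1.5, 0.30) <= 0.1

    def test_upper_edge_above_nyquist_raises(self):
        series = BoldSeries(np.zeros((3, 3, 1, 100)), 6.0)  # Nyquist ~0.083
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(series, 0.01, 0.1)


class TestMotionCorrection:
    def test_motion_free_run_estimates_near_identity(self, phantom):
        cfg = FmriGenConfig(seed=3, volumes=100, motion_sd=0.0,
                            motion_rot_sd_deg=0.0)
        series = simulate_bold(phantom, cfg)
        sub = BoldSeries(series.data[:, :, 2:3, :10], 3.0)
        _, params = motion_correct_2d(sub)
        assert np.abs(params.dx).max() < 0.1
        assert np.abs(params.dy).max() < 0.1
        assert np.abs(params.theta).max() < 0.2

    def test_injected_shift_recovered(self, phantom):
        cfg = FmriGenConfig(seed=5, volumes=100, motion_sd=0.0,
                            motion_rot_sd_deg=0.0)
        series = simulate_bold(phantom, cfg)
        img = series.data[:, :, 2, 0]
        moved = _transform_slice(img, 2.0, -1.0, 0.0)
        pair = BoldSeries(np.stack([img, moved], axis=-1)[:, :, None, :], 3.0)
        _, params = motion_correct_2d(pair)
        assert params.dx[0, 1] == pytest.approx(-2.0, abs=0.25)
        assert params.dy[0, 1] == pytest.approx(1.0, abs=0.25)

    def test_injected_rotation_recovered(self, phantom):
        cfg = FmriGenConfig(seed=5, volumes=100, motion_sd=0.0,
                            motion_rot_sd_deg=0.0)
        series = simulate_bold(phantom, cfg)
        img = series.data[:, :, 2, 0]
        moved = _transform_slice(img, 0.0, 0.0, 3.0)
        pair = BoldSeries(np.stack([img, moved], axis=-1)[:, :, None, :], 3.0)
        _, params = motion_correct_2d(pair)
        assert params.theta[0, 1] == pytest.approx(-3.0, abs=0.5)

    def test_roundtrip_interpolation_error_small(self, phantom):
        """Correcting a known transform restores the image within 2% of the
        dynamic range (interpolation error only).

        Uses a band-limited (smoothed, texture-free) phantom image: linear
        interpolation can only round-trip signal it can represent, so the
        property is about registration accuracy, not sub-voxel texture.
        """
        from scipy import ndimage
        cfg = FmriGenConfig(seed=5, volumes=100, motion_sd=0.0,
                            motion_rot_sd_deg=0.0, texture_sd_pct=0.0)
        series = simulate_bold(phantom, cfg)
        img = ndimage.gaussian_filter(series.data[:, :, 2, 0], 1.5)
        moved = _transform_slice(img, 1.3, -0.7, 2.0)
        pair = BoldSeries(np.stack([img, moved], axis=-1)[:, :, None, :], 3.0)
        corrected, _ = motion_correct_2d(pair)
        inner = (slice(4, -4), slice(4, -4))
        err = np.abs(corrected.data[:, :, 0, 1][inner] - img[inner]).mean()
        assert err < 0.02 * np.ptp(img)

    def test_constant_slice_warns_and_returns_identity(self):
        data = np.ones((16, 16, 1, 3))
        data[:, :, 0, 0] = np.arange(256).reshape(16, 16)  # ref has contrast
        with pytest.warns(UserWarning, match="constant"):
            _, params = motion_correct_2d(BoldSeries(data, 3.0))
        assert params.dx[0, 1] == 0.0

    def test_single_volume_raises(self):
        with pytest.raises(ValueError):
            motion_correct_2d(BoldSeries(np.zeros((8, 8, 1, 1)), 3.0))


class TestNuisancePCA:
    def test_rank_one_structure_clamped_to_k_min(self, rng):
        t = np.arange(200) * 3.0
        sine = np.sin(2 * np.pi * 0.05 * t)
        vox = sine[None, :] * rng.uniform(1, 2, (30, 1))
        vox = vox + 1e-4 * rng.standard_normal(vox.shape)
        data = np.zeros((6, 5, 1, 200))
        data.reshape(-1, 200)[:30] = vox
        mask = np.zeros((6, 5, 1), dtype=bool)
        mask.reshape(-1)[:30] = True
        nuis = extract_nuisance(BoldSeries(data, 3.0), mask)
        assert nuis.regressors.shape[1] == 3  # k_min clamp
        var = nuis.singular_values**2
        assert var[0] / var.sum() > 0.99 or nuis.explained_fraction > 0.99

    def test_variance_split_75_25_reaches_threshold_at_one(self, rng):
        # two orthogonal sinusoids with a 75/25 variance split: the first
        # component alone reaches the 70% threshold, so k is the k_min clamp
        t = np.arange(300)
        s1 = np.sqrt(0.75) * np.sqrt(2) * np.sin(2 * np.pi * 10 * t / 300)
        s2 = np.sqrt(0.25) * np.sqrt(2) * np.cos(2 * np.pi * 20 * t / 300)
        vox = np.zeros((300, 40))
        vox[:, :20] = s1[:, None] * rng.uniform(0.9, 1.1, 20)
        vox[:, 20:] = s2[:, None] * rng.uniform(0.9, 1.1, 20)
        vox += 1e-5 * rng.standard_normal(vox.shape)  # full rank
        data = vox.T.reshape(40, 1, 1, 300)
        mask = np.ones((40, 1, 1), dtype=bool)
        nuis = extract_nuisance(BoldSeries(data, 1.0), mask)
        assert nuis.regressors.shape[1] == 3
        # independent eigenvalue oracle for the leading variance fraction
        centred = vox - vox.mean(axis=0)
        eig = np.linalg.svd(centred, compute_uv=False) ** 2
        assert eig[0] / eig.sum() == pytest.approx(0.75, abs=0.05)
        # columns zero-mean and orthogonal
        assert np.allclose(nuis.regressors.mean(axis=0), 0.0, atol=1e-9)
        gram = nuis.regressors.T @ nuis.regressors
        off = gram - np.diag(np.diag(gram))
        assert np.allclose(off, 0.0, atol=1e-6 * np.abs(gram).max())

    def test_five_equal_components_need_four(self, rng):
        # five orthogonal equal-variance sources: cumulative 70% first at k=4
        n = 500
        base = rng.standard_normal((n, 5))
        q, _ = np.linalg.qr(base)
        sources = q * np.sqrt(n)
        loads = np.kron(np.eye(5), np.ones((1, 8)))  # 40 voxels, 8 per source
        vox = sources @ loads  # time x 40
        data = vox.T.reshape(40, 1, 1, n)
        mask = np.ones((40, 1, 1), dtype=bool)
        nuis = extract_nuisance(BoldSeries(data, 1.0), mask)
        assert nuis.regressors.shape[1] == 4

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            extract_nuisance(BoldSeries(np.zeros((4, 4, 1, 50)), 3.0),
                             np.zeros((4, 4, 1), dtype=bool))


class TestGlmDenoise:
    def _series(self, vox, tr=3.0):
        n = vox.shape[-1]
        return BoldSeries(vox.reshape(1, 1, 1, n).astype(float), tr)

    def test_voxel_equal_to_regressor_leaves_constant(self, rng):
        from cordfc.fmri.preprocess import NuisanceSet
        reg = rng.standard_normal(200)
        reg -= reg.mean()
        nuis = NuisanceSet(reg[:, None], 1.0, np.array([1.0]))
        out = glm_denoise(self._series(reg + 5.0), nuis)
        assert out.data.std() < 1e-10
        assert out.data.mean() == pytest.approx(5.0)

    def test_orthogonal_voxel_unchanged(self):
        from cordfc.fmri.preprocess import NuisanceSet
        t = np.arange(200)
        reg = np.sin(2 * np.pi * 5 * t / 200)
        vox = np.cos(2 * np.pi * 5 * t / 200)
        nuis = NuisanceSet(reg[:, None], 1.0, np.array([1.0]))
        out = glm_denoise(self._series(vox), nuis)
        assert np.allclose(out.data.ravel(), vox, atol=1e-10)

    def test_mixed_signal_recovered(self, rng):
        from cordfc.fmri.preprocess import NuisanceSet
        t = np.arange(300)
        sig = np.sin(2 * np.pi * 3 * t / 300)
        reg = rng.standard_normal(300)
        reg -= reg.mean()
        nuis = NuisanceSet(reg[:, None], 1.0, np.array([1.0]))
        out = glm_denoise(self._series(sig + 0.5 * reg), nuis)
        r = np.corrcoef(out.data.ravel(), sig)[0, 1]
        assert r > 0.99

    def test_never_increases_variance(self, phantom, quiet_cfg):
        series = simulate_bold(phantom, quiet_cfg)
        nuis = extract_nuisance(series, phantom.noise_mask())
        out = glm_denoise(series, nuis)
        assert np.all(out.data.var(axis=3) <= series.data.var(axis=3) + 1e-9)


class TestTsnrGate:
    def test_gate_boundary_case(self, rng):
        data = 100.0 + 2.0 * rng.standard_normal((4, 4, 1, 300))
        mask = np.ones((4, 4, 1), dtype=bool)
        tsnr, _ = tsnr_gate(BoldSeries(data, 3.0), mask)
        assert tsnr[mask].mean() == pytest.approx(50.0, rel=0.1)

    def test_zero_mean_noise_fails(self, rng):
        data = rng.standard_normal((4, 4, 1, 300))
        mask = np.ones((4, 4, 1), dtype=bool)
        _, passed = tsnr_gate(BoldSeries(data, 3.0), mask)
        assert not passed

    def test_noiseless_ramp_hits_sentinel(self):
        ramp = np.linspace(0, 10, 100)
        data = np.tile(ramp, (2, 2, 1, 1))
        mask = np.ones((2, 2, 1), dtype=bool)
        tsnr, _ = tsnr_gate(BoldSeries(data, 3.0), mask)
        assert np.all(tsnr == TSNR_SENTINEL)


class TestClusterFilter:
    def test_isolated_voxel_removed(self):
        m = np.zeros((8, 8), dtype=bool)
        m[3, 3] = True
        assert not cluster_filter(m, 2).any()

    def test_adjacent_pair_kept(self):
        m = np.zeros((8, 8), dtype=bool)
        m[3, 3] = m[3, 4] = True
        assert cluster_filter(m, 2).sum() == 2

    def test_diagonal_pair_removed_under_4_connectivity(self):
        m = np.zeros((8, 8), dtype=bool)
        m[3, 3] = m[4, 4] = True
        assert not cluster_filter(m, 2).any()

    def test_no_across_slice_connectivity(self):
        m = np.zeros((4, 4, 2), dtype=bool)
        m[2, 2, 0] = m[2, 2, 1] = True  # stacked across slices only
        assert not cluster_filter(m, 2).any()

    def test_idempotent(self, rng):
        m = rng.random((16, 16, 3)) > 0.6
        once = cluster_filter(m, 2)
        assert np.array_equal(cluster_filter(once, 2), once)
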