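"""Confound-handling contracts: FD, Friston-24, spikes, regression,
band-pass, smoothing, motion exclusion."""

from __future__ import annotations

import numpy as np
import pytest

from fcnm import VolumeGrid
from fcnm.preprocess import (
    PreprocessError,
    bandpass,
    build_confounds,
    framewise_displacement,
    friston24,
    gaussian_smooth,
    motion_exclude,
    nuisance_regress,
    spike_regressors,
)


class TestFramewiseDisplacement:
    def test_constant_trace_gives_zero(self):
        fd = framewise_displacement(np.ones((30, 6)))
        np.testing.assert_allclose(fd, 0.0)

    def test_translation_step(self):
        motion = np.zeros((10, 6))
        motion[5:, 0] = 0.5
        fd = framewise_displacement(motion)
        assert fd[5] == pytest.approx(0.5)
        assert np.count_nonzero(fd) == 1

    def test_rotation_step_scaled_by_head_radius(self):
        motion = np.zeros((10, 6))
        motion[5:, 3] = 0.01  # radians
        fd = framewise_displacement(motion)
        assert fd[5] == pytest.approx(50 * 0.01)

    def test_first_frame_is_zero(self):
        rng = np.random.default_rng(0)
        fd = framewise_displacement(rng.normal(size=(20, 6)))
        assert fd[0] == 0.0

    def test_nonfinite_motion_rejected(self):
        motion = np.zeros((10, 6))
        motion[3, 2] = np.nan
        with pytest.raises(PreprocessError, match="finite"):
            framewise_displacement(motion)


class TestFriston24:
    def test_zero_motion_gives_zero_matrix(self):
        np.testing.assert_array_equal(friston24(np.zeros((15, 6))), np.zeros((15, 24)))

    def test_lag_and_square_structure(self):
        rng = np.random.default_rng(1)
        motion = rng.normal(size=(12, 6))
        f = friston24(motion)
        assert f.shape == (12, 24)
        np.testing.assert_array_equal(f[1:, 6:12], motion[:-1])
        np.testing.assert_array_equal(f[0, 6:12], np.zeros(6))
        np.testing.assert_array_equal(f[:, 12:18], motion**2)
        np.testing.assert_array_equal(f[:, 18:24], f[:, 6:12] ** 2)


class TestSpikeRegressors:
    def test_no_spikes_gives_zero_width(self):
        assert spike_regressors(np.full(10, 0.3)).shape == (10, 0)

    def test_one_column_per_spike_volume(self):
        out = spike_regressors(np.array([0.0, 0.6, 0.2, 0.7]))
        np.testing.assert_array_equal(
            out, np.array([[0, 0], [1, 0], [0, 0], [0, 1]], dtype=float)
        )

    def test_threshold_is_strict(self):
        assert spike_regressors(np.array([0.0, 0.5, 0.0])).shape[1] == 0


class TestNuisanceRegress:
    def test_self_regression_gives_zero_residual(self):
        rng = np.random.default_rng(2)
        conf = np.column_stack([rng.normal(size=50), np.ones(50)])
        ts = conf[:, [0]].copy()
        res = nuisance_regress(ts, conf)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_intercept_only_demeans(self):
        rng = np.random.default_rng(3)
        ts = rng.normal(size=(40, 5))
        res = nuisance_regress(ts, np.ones((40, 1)))
        np.testing.assert_allclose(res, ts - ts.mean(axis=0), atol=1e-12)

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(4)
        ts = rng.normal(size=(60, 7))
        conf = np.column_stack([rng.normal(size=(60, 4)), np.ones(60)])
        res = nuisance_regress(ts, conf)
        oracle = ts - conf @ (np.linalg.pinv(conf) @ ts)
        np.testing.assert_allclose(res, oracle, atol=1e-8)

    def test_residuals_orthogonal_to_confounds(self):
        from fcnm.synthetic import make_motion

        rng = np.random.default_rng(5)
        ts = rng.normal(size=(80, 10))
        motion = make_motion(80, spike_times=[40], spike_mm=0.8, rng_seed=5)
        conf, _ = build_confounds(motion)
        res = nuisance_regress(ts, conf)
        rel = np.abs(conf.T @ res) / (
            np.linalg.norm(conf, axis=0)[:, None] * np.linalg.norm(res, axis=0)[None, :]
        )
        assert rel.max() < 1e-6

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        ts = rng.normal(size=(50, 3))
        conf = np.column_stack([rng.normal(size=(50, 3)), np.ones(50)])
        once = nuisance_regress(ts, conf)
        twice = nuisance_regress(once, conf)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_rank_deficient_design_names_columns(self):
        x = np.random.default_rng(7).normal(size=30)
        conf = np.column_stack([x, 2 * x, np.ones(30)])
        with pytest.raises(PreprocessError, match="rank-deficient"):
            nuisance_regress(np.zeros((30, 1)), conf, names=["a", "b", "intercept"])


class TestBandpass:
    def test_constant_series_removed(self):
        out = bandpass(np.full((200, 2), 3.7), tr_s=2.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    @pytest.mark.parametrize(
        "freq, lo, hi",
        [(0.05, 0.95, 1.05), (0.2, 0.0, 0.1), (0.002, 0.0, 0.1)],
    )
    def test_sinusoid_amplitudes(self, freq, lo, hi):
        t = np.arange(1000) * 2.0
        x = np.sin(2 * np.pi * freq * t)
        out = bandpass(x[:, None], tr_s=2.0)
        amp = 2 * np.abs(np.fft.rfft(out[:, 0]) / len(out)).max()
        assert lo <= amp <= hi

    def test_idempotent_on_passband(self):
        t = np.arange(1000) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)[:, None]
        once = bandpass(x, 2.0)
        twice = bandpass(once, 2.0)
        assert np.abs(twice - once).max() < 0.02 * np.abs(once).max()

    def test_above_nyquist_rejected(self):
        with pytest.raises(PreprocessError, match="Nyquist"):
            bandpass(np.zeros((100, 1)), tr_s=3.0, low_hz=0.01, high_hz=0.2)


class TestGaussianSmooth:
    @pytest.fixture()
    def grid(self):
        return VolumeGrid.pseudo_mni((15, 15, 15), 3.0)

    def test_fwhm_zero_is_identity(self, grid):
        rng = np.random.default_rng(8)
        vol = rng.normal(size=grid.shape)
        np.testing.assert_array_equal(gaussian_smooth(vol, 0.0, grid), vol)

    def test_point_source_mass_preserved(self, grid):
        vol = np.zeros(grid.shape)
        vol[7, 7, 7] = 1.0
        out = gaussian_smooth(vol, 6.0, grid)
        assert out.sum() == pytest.approx(1.0, abs=1e-3)

    def test_point_source_peak_at_source_and_decreasing(self, grid):
        vol = np.zeros(grid.shape)
        vol[7, 7, 7] = 1.0
        out = gaussian_smooth(vol, 6.0, grid)
        assert np.unravel_index(out.argmax(), out.shape) == (7, 7, 7)
        # strictly decreasing until the kernel's truncation radius (4 sigma)
        line = out[7:12, 7, 7]
        assert np.all(np.diff(line) < 0)

    def test_negative_fwhm_rejected(self, grid):
        with pytest.raises(PreprocessError):
            gaussian_smooth(np.zeros(grid.shape), -1.0, grid)


class TestMotionExclude:
    def test_under_limits_keeps(self):
        motion = np.zeros((20, 6))
        motion[:, 0] = 1.9
        motion[:, 3] = np.radians(1.9)
        assert motion_exclude(motion, 2.0, 2.0)

    def test_translation_over_limit_drops(self):
        motion = np.zeros((20, 6))
        motion[4, 1] = 2.5
        assert not motion_exclude(motion, 2.0, 2.0)

    def test_rotation_compared_in_degrees(self):
        motion = np.zeros((20, 6))
        motion[3, 5] = np.radians(2.1)
        assert not motion_exclude(motion, 2.0, 2.0)
        assert motion_exclude(motion, 3.0, 3.0)


def test_confound_matrix_column_budget():
    """Friston-24 + spikes + 3 tissue signals + drift + intercept."""
    rng = np.random.default_rng(9)
    motion = rng.normal(size=(60, 6)) * 0.05
    motion[30:, 0] += 0.8  # one spike
    signals = {"global": rng.normal(size=60), "wm": rng.normal(size=60), "csf": rng.normal(size=60)}
    conf, names = build_confounds(motion, 0.5, signals)
    n_spikes = sum(1 for n in names if n.startswith("spike_"))
    assert conf.shape[1] == 24 + n_spikes + 3 + 2
    assert n_spikes >= 1
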