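"""Local-metric checks against hand-computed and brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from twinlocal.metrics import (
    apply_motion_exclusion,
    average_runs,
    bandpass,
    compute_falff,
    compute_fd,
    compute_reho,
    detrend_linear,
    extract_roi_means,
    friston24,
    regress_confounds,
    scrub_mask,
    smooth_gaussian,
    zscore_map,
)
from twinlocal.synthetic import FmriRun

import pandas as pd


def _run_from_series(series_matrix, shape=None, tr=1.0):
    """Pack (v, t) series into a small 4D run with an all-true mask."""
    series_matrix = np.asarray(series_matrix, dtype=float)
    v, t = series_matrix.shape
    if shape is None:
        shape = (v, 1, 1)
    data = series_matrix.reshape(shape + (t,))
    return FmriRun(data=data, tr=tr, mask=np.ones(shape, dtype=bool))


def kcc_oracle(series_matrix):
    """Brute-force Kendall's W: explicit rank table and rank-sum formula."""
    K, n = series_matrix.shape
    ranks = np.array([stats.rankdata(s) for s in series_matrix])
    R = ranks.sum(axis=0)
    S = np.sum((R - K * (n + 1) / 2.0) ** 2)
    return 12.0 * S / (K**2 * (n**3 - n))


class TestFD:
    def test_zero_motion(self):
        fd, mean_fd = compute_fd(np.zeros((10, 6)))
        assert np.all(fd == 0) and mean_fd == 0

    def test_translation_step(self):
        mp = np.zeros((5, 6))
        mp[2:, 0] = 0.1  # 0.1 mm step in x at volume 3
        fd, _ = compute_fd(mp)
        assert fd[2] == pytest.approx(0.1)
        assert fd[1] == fd[3] == 0.0

    def test_rotation_projected_to_head_radius(self):
        mp = np.zeros((4, 6))
        mp[1:, 3] = 0.002  # rad
        fd, _ = compute_fd(mp)
        assert fd[1] == pytest.approx(50 * 0.002)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError, match="6"):
            compute_fd(np.zeros((10, 5)))


class TestScrub:
    def test_all_below_threshold_kept(self):
        assert scrub_mask(np.full(20, 0.1)).all()

    def test_spike_extends_one_back_two_forward(self):
        fd = np.full(20, 0.1)
        fd[10] = 0.9
        keep = scrub_mask(fd)
        assert sorted(np.flatnonzero(~keep)) == [9, 10, 11, 12]

    def test_zero_threshold_keeps_only_first_volume(self):
        fd = np.r_[0.0, np.full(10, 0.1)]
        keep = scrub_mask(fd, threshold=0.0, extend_before=0, extend_after=0)
        assert keep[0] and not keep[1:].any()


class TestConfoundRegression:
    def test_intercept_only_is_identity(self, rng):
        Y = rng.normal(size=(4, 50))
        run = _run_from_series(Y)
        out = regress_confounds(run, np.ones((50, 1)))
        assert np.allclose(out.data.reshape(4, 50), Y, atol=1e-10)

    def test_exact_linear_combination_removed(self, rng):
        X = rng.normal(size=(60, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 3.0
        run = _run_from_series(y[None, :])
        out = regress_confounds(run, X)
        res = out.data.ravel()
        assert np.var(res) == pytest.approx(0.0, abs=1e-20)

    def test_residuals_orthogonal_to_design(self, rng):
        X = rng.normal(size=(80, 5))
        Y = rng.normal(size=(6, 80))
        run = _run_from_series(Y)
        out = regress_confounds(run, X)
        res = out.data.reshape(6, 80) - out.data.reshape(6, 80).mean(
            axis=1, keepdims=True
        )
        scale = np.abs(X).max() * np.abs(Y).max() * 80
        assert np.max(np.abs(X.T @ res.T)) < 1e-8 * scale

    def test_rank_deficient_design_warns(self, rng):
        X = rng.normal(size=(40, 2))
        X = np.hstack([X, X[:, :1] * 2.0])
        run = _run_from_series(rng.normal(size=(2, 40)))
        with pytest.warns(UserWarning, match="rank-deficient"):
            regress_confounds(run, X)

    def test_friston24_layout(self):
        mp = np.arange(30, dtype=float).reshape(5, 6)
        F = friston24(mp)
        assert F.shape == (5, 24)
        assert np.allclose(F[1:, 6:12], mp[:-1])
        assert np.allclose(F[:, 12:18], mp**2)


class TestDetrend:
    def test_constant_unchanged_and_ramp_flattened(self):
        t = np.arange(40, dtype=float)
        Y = np.vstack([np.full(40, 3.0), 2.0 * t + 1.0])
        out = detrend_linear(_run_from_series(Y)).data.reshape(2, 40)
        assert np.allclose(out[0], 3.0, atol=1e-10)
        assert np.allclose(out[1], out[1].mean(), atol=1e-9)

    def test_ramp_plus_sine_leaves_sine(self):
        t = np.arange(128, dtype=float)
        sine = np.sin(2 * np.pi * 8 * t / 128)  # orthogonal to linear trend
        y = 0.5 * t + sine + 2.0
        out = detrend_linear(_run_from_series(y[None, :])).data.ravel()
        # least-squares oracle
        X = np.c_[np.ones(128), t]
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        expect = y - X @ beta + y.mean()
        assert np.allclose(out, expect, atol=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detrend_linear(_run_from_series(np.zeros((1, 2))))


class TestBandpass:
    def test_inband_preserved_outband_removed(self):
        t = np.arange(200, dtype=float)
        tr = 1.0
        inband = np.sin(2 * np.pi * 0.04 * t * tr)   # on-bin: 0.04 = 8/200
        outband = np.sin(2 * np.pi * 0.2 * t * tr)   # 0.2 = 40/200
        run = _run_from_series(np.vstack([inband, outband]), tr=tr)
        out = bandpass(run).data.reshape(2, 200)
        assert out[0].std() == pytest.approx(inband.std(), rel=0.01)
        assert out[1].std() == pytest.approx(0.0, abs=1e-10)

    def test_white_noise_variance_scales_with_bin_fraction(self, rng):
        t, tr = 400, 1.0
        Y = rng.normal(size=(200, t))
        run = _run_from_series(Y, shape=(200, 1, 1), tr=tr)
        out = bandpass(run).data.reshape(200, t)
        freqs = np.fft.rfftfreq(t, tr)
        keep = (freqs >= 0.01) & (freqs <= 0.08)
        # Parseval: each interior bin carries 2/t of the variance
        frac = (2.0 * keep.sum()) / t
        ratio = out.var(axis=1).mean() / Y.var(axis=1).mean()
        assert ratio == pytest.approx(frac, rel=0.1)

    def test_parameter_validation(self):
        run = _run_from_series(np.zeros((1, 64)), tr=1.0)
        with pytest.raises(ValueError, match="low"):
            bandpass(run, low=0.1, high=0.05)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(FmriRun(data=run.data, tr=4.0, mask=run.mask), high=0.2)


class TestReHo:
    def test_identical_series_give_w_of_one(self):
        base = np.sin(np.linspace(0, 6, 20))
        data = np.tile(base, (3, 3, 3, 1))
        run = FmriRun(data=data, tr=1.0, mask=np.ones((3, 3, 3), bool))
        reho = compute_reho(run)
        assert reho[1, 1, 1] == pytest.approx(1.0)

    def test_small_integer_table_matches_rank_sum_oracle(self):
        # K=3 voxels, n=4 time points, hand-checkable integer series
        table = np.array(
            [
                [1.0, 3.0, 2.0, 4.0],
                [2.0, 1.0, 4.0, 3.0],
                [1.0, 2.0, 3.0, 4.0],
            ]
        )
        data = np.zeros((3, 1, 1, 4))
        data[:, 0, 0, :] = table
        run = FmriRun(data=data, tr=1.0, mask=np.ones((3, 1, 1), bool))
        reho = compute_reho(run)
        # middle voxel's neighborhood holds all three series
        assert reho[1, 0, 0] == pytest.approx(kcc_oracle(table), abs=1e-12)

    def test_brute_force_oracle_on_random_instances(self, rng):
        """Vectorized KCC equals the explicit rank-sum formula, K<=27, n<=20.

        K masked voxels are placed inside a single 3x3x3 cube containing the
        center, so the center voxel's neighborhood is exactly the K series.
        """
        coords = [(i, j, k) for i in range(3) for j in range(3) for k in range(3)]
        others = [c for c in coords if c != (1, 1, 1)]
        for _ in range(200):
            K = int(rng.integers(2, 28))
            n = int(rng.integers(4, 21))
            series = rng.normal(size=(K, n))
            pick = [others[i] for i in rng.choice(26, size=K - 1, replace=False)]
            chosen = [(1, 1, 1)] + pick
            data = np.zeros((3, 3, 3, n))
            mask = np.zeros((3, 3, 3), bool)
            for c, s in zip(chosen, series):
                data[c] = s
                mask[c] = True
            run = FmriRun(data=data, tr=1.0, mask=mask)
            got = compute_reho(run)[1, 1, 1]
            assert got == pytest.approx(kcc_oracle(series), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        series = rng.normal(size=(27, 15))
        data = series.reshape(3, 3, 3, 15)
        mask = np.ones((3, 3, 3), bool)
        r1 = compute_reho(FmriRun(data=data, tr=1.0, mask=mask))
        r2 = compute_reho(FmriRun(data=np.exp(2 * data), tr=1.0, mask=mask))
        assert np.allclose(r1[mask], r2[mask], atol=1e-12)

    def test_isolated_voxel_masked_missing(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[0, 0, 0] = True
        data = np.random.default_rng(0).normal(size=(5, 5, 5, 10))
        reho = compute_reho(FmriRun(data=data, tr=1.0, mask=mask))
        assert np.isnan(reho[0, 0, 0])

    def test_independent_series_expectation_near_inverse_k(self, rng):
        # E[W] ~ 1/K for independent continuous series
        K, n = 27, 50
        vals = []
        for _ in range(300):
            series = rng.normal(size=(K, n)).reshape(3, 3, 3, n)
            run = FmriRun(data=series, tr=1.0, mask=np.ones((3, 3, 3), bool))
            vals.append(compute_reho(run)[1, 1, 1])
        assert np.mean(vals) == pytest.approx(1.0 / K, abs=0.02)


class TestFalff:
    def _sine_run(self, freq, t=322, tr=0.93):
        x = np.arange(t)
        # snap to the nearest DFT bin so the tone is exactly on-bin
        k = round(freq * t * tr)
        y = np.sin(2 * np.pi * k * x / t)
        return _run_from_series(y[None, :], tr=tr)

    def test_inband_sine_gives_one(self):
        falff = compute_falff(self._sine_run(0.04))
        assert falff[0, 0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_outband_sine_gives_zero(self):
        falff = compute_falff(self._sine_run(0.2))
        assert falff[0, 0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_white_noise_matches_bin_count_ratio(self, rng):
        t, tr = 322, 0.93
        freqs = np.fft.rfftfreq(t, tr)
        n_band = int(((freqs >= 0.01) & (freqs <= 0.08)).sum())
        n_full = int(((freqs > 0) & (freqs <= 0.25)).sum())
        Y = rng.normal(size=(2000, t))
        run = _run_from_series(Y, shape=(2000, 1, 1), tr=tr)
        falff = compute_falff(run)
        assert np.nanmean(falff) == pytest.approx(n_band / n_full, abs=0.02)

    def test_scale_invariance_and_zero_variance_missing(self, rng):
        Y = rng.normal(size=(3, 100))
        r1 = compute_falff(_run_from_series(Y))
        r2 = compute_falff(_run_from_series(1000.0 * Y))
        assert np.allclose(r1, r2, atol=1e-12)
        flat = np.vstack([Y, np.zeros((1, 100))])
        r3 = compute_falff(_run_from_series(flat))
        assert np.isnan(r3[3, 0, 0])


class TestMapOps:
    def test_zscore_two_voxel_hand_case(self):
        m = np.array([[[1.0]], [[3.0]]])
        mask = np.ones((2, 1, 1), bool)
        z = zscore_map(m, mask)
        assert z[0, 0, 0] == pytest.approx(-1.0)  # population-SD convention
        assert z[1, 0, 0] == pytest.approx(1.0)

    def test_zscore_moments_and_constant_error(self, rng):
        m = rng.normal(size=(6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        z = zscore_map(m, mask)
        assert np.nanmean(z[mask]) == pytest.approx(0.0, abs=1e-12)
        assert np.nanstd(z[mask]) == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError, match="constant"):
            zscore_map(np.ones((3, 3, 3)), np.ones((3, 3, 3), bool))

    def test_smooth_constant_unchanged(self):
        mask = np.ones((8, 8, 8), bool)
        out = smooth_gaussian(np.full((8, 8, 8), 2.5), mask, fwhm=6, voxel_size=2)
        assert np.allclose(out[mask], 2.5, atol=1e-9)

    def test_smooth_delta_half_max_at_fwhm_over_two(self):
        mask = np.ones((31, 31, 31), bool)
        m = np.zeros((31, 31, 31))
        m[15, 15, 15] = 1.0
        out = smooth_gaussian(m, mask, fwhm=6.0, voxel_size=1.0)
        # half maximum at 3 mm = 3 voxels from the peak
        assert out[18, 15, 15] / out[15, 15, 15] == pytest.approx(0.5, rel=1e-6)

    def test_smooth_preserves_interior_sum(self):
        mask = np.ones((31, 31, 31), bool)
        m = np.zeros((31, 31, 31))
        m[15, 15, 15] = 1.0
        out = smooth_gaussian(m, mask, fwhm=6.0, voxel_size=2.0)
        assert np.nansum(out) == pytest.approx(1.0, rel=1e-6)

    def test_roi_means(self):
        atlas = np.zeros((4, 2, 1), int)
        atlas[:2] = 1
        atlas[2:] = 2
        m = np.arange(8, dtype=float).reshape(4, 2, 1)
        out = extract_roi_means(m, atlas, roi_ids=[1, 2, 9])
        assert out[0] == pytest.approx(np.mean([0, 1, 2, 3]))
        assert out[1] == pytest.approx(np.mean([4, 5, 6, 7]))
        assert np.isnan(out[2])  # absent ROI flagged missing
        const = extract_roi_means(np.full((4, 2, 1), 5.0), atlas, [1, 2])
        assert np.allclose(const, 5.0)

    def test_average_runs_policies(self):
        a, b = np.array([0.2, 0.4]), np.array([0.4, 0.2])
        assert np.allclose(average_runs(a, b), [0.3, 0.3])
        assert average_runs(a, None) is None
        assert np.allclose(average_runs(a, None, policy="single"), a)

    def test_motion_exclusion_strict_inequality(self):
        t = pd.DataFrame({"mean_fd_ap": [0.29, 0.31, 0.30],
                          "mean_fd_pa": [0.1, 0.1, 0.1]})
        out = apply_motion_exclusion(t, threshold=0.3)
        assert list(out["excluded"]) == [False, True, False]
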