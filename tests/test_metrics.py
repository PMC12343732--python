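import numpy as np
import pytest
from skimage.metrics import structural_similarity

from sphfod import metrics, simulate, sphharm


def random_fiber_fod(rng, n_fibers=1, kernel=None):
    fc = simulate._sample_fibers(rng, n_fibers, 40, 90, 1.7e-3, 0.4e-3)
    c = simulate.delta_fod_sh(fc)
    if kernel is not None:
        c = simulate.sh_convolve(c, kernel)
    return fc, c


class TestSHMSE:
    def test_zero_for_equal(self, rng):
        c = rng.standard_normal((5, 45))
        assert metrics.sh_mse(c, c) == 0.0

    def test_hand_arithmetic(self):
        p = np.zeros((1, 45))
        g = np.zeros((1, 45))
        p[0, 7] = 0.3
        assert metrics.sh_mse(p, g) == pytest.approx(0.09, rel=1e-12)

    def test_parseval_vs_spatial_loss(self, dense_sampling, rng):
        from sphfod.train import spatial_mse_loss

        p = rng.standard_normal((50, 45))
        g = rng.standard_normal((50, 45))
        loss = spatial_mse_loss(p, g, dense_sampling)
        assert metrics.sh_mse(p, g) == pytest.approx(loss * 4 * np.pi, rel=0.01)


class TestACC:
    def test_identity(self, rng):
        c = rng.standard_normal((4, 45))
        assert np.allclose(metrics.acc(c, c), 1.0)

    def test_scale_invariance(self, rng):
        c = rng.standard_normal((4, 45))
        assert np.allclose(metrics.acc(2.0 * c, c), 1.0)

    def test_orthogonal_amplitudes(self, sampling_724, rng):
        # Gram-Schmidt two coefficient vectors whose amplitude vectors are
        # orthogonal on the sampling
        a = rng.standard_normal(45)
        b = rng.standard_normal(45)
        A = sphharm.isft(a, sampling_724)
        B = sphharm.isft(b, sampling_724)
        B_orth = B - (A @ B) / (A @ A) * A
        b_orth = sphharm.sft(B_orth, sampling_724)
        val = metrics.acc(a[None], b_orth[None], sampling_724)[0]
        assert abs(val) < 1e-8

    def test_zero_norm_is_nan(self, rng):
        c = rng.standard_normal((2, 45))
        z = np.zeros((2, 45))
        out = metrics.acc(c, z)
        assert np.all(np.isnan(out))

    def test_joint_rotation_invariance(self, rng):
        R = sphharm.random_rotation(rng)
        D = sphharm.rotation_operator(R, 8).D
        p = rng.standard_normal((10, 45))
        g = rng.standard_normal((10, 45))
        d = np.abs(metrics.acc(p @ D.T, g @ D.T) - metrics.acc(p, g))
        assert d.max() <= 1e-6


class TestSSIM:
    def _fields(self, rng, shape=(12, 12, 12)):
        data = rng.standard_normal(shape + (45,))
        mask = np.ones(shape, dtype=bool)
        return metrics.FODField(data=data, mask=mask)

    def test_identity(self, rng):
        f = self._fields(rng)
        assert metrics.ssim_per_channel(f, f) == pytest.approx(1.0)

    def test_negated_below_one(self, rng):
        f = self._fields(rng)
        g = metrics.FODField(data=-f.data, mask=f.mask)
        assert metrics.ssim_per_channel(g, f) < 1.0

    def test_cross_implementation_oracle(self, rng):
        # independent reference: skimage's SSIM, channel by channel
        shape = (16, 16, 16)
        gt = rng.standard_normal(shape + (45,))
        pred = gt + 0.3 * rng.standard_normal(shape + (45,))
        mask = np.ones(shape, dtype=bool)
        mine = metrics.ssim_per_channel(
            metrics.FODField(data=pred, mask=mask),
            metrics.FODField(data=gt, mask=mask),
        )
        ref = np.mean(
            [
                structural_similarity(
                    pred[..., c],
                    gt[..., c],
                    data_range=float(gt[..., c].max() - gt[..., c].min()),
                    win_size=7,
                )
                for c in range(45)
            ]
        )
        assert mine == pytest.approx(ref, abs=1e-6)

    def test_constant_pair_is_one(self):
        shape = (8, 8, 8)
        data = np.ones(shape + (45,))
        mask = np.ones(shape, dtype=bool)
        f = metrics.FODField(data=data, mask=mask)
        assert metrics.ssim_per_channel(f, f) == 1.0


class TestPSNR:
    def test_zero_db_at_full_scale_error(self):
        g = np.zeros((1, 45))
        g[0, 0] = 1.0
        p = g.copy()
        # construct error with element MSE == data_range^2 == 1
        p = g + 1.0
        assert metrics.psnr(p, g) == pytest.approx(0.0, abs=1e-9)

    def test_halving_error_adds_6db(self, rng):
        g = rng.standard_normal((10, 45))
        e = rng.standard_normal((10, 45))
        d = metrics.psnr(g + 0.5 * e, g) - metrics.psnr(g + e, g)
        assert d == pytest.approx(20 * np.log10(2), abs=1e-9)

    def test_direct_formula(self, rng):
        g = rng.standard_normal((10, 45))
        p = g + 0.1 * rng.standard_normal((10, 45))
        expected = 10 * np.log10(
            np.max(np.abs(g)) ** 2 / np.mean((p - g) ** 2)
        )
        assert metrics.psnr(p, g) == pytest.approx(expected, abs=1e-9)

    def test_identical_is_inf(self, rng):
        g = rng.standard_normal((3, 45))
        assert metrics.psnr(g, g) == np.inf


class TestExtractPeaks:
    def test_single_fiber(self, icosphere_2562, rng):
        fc, c = random_fiber_fod(rng, 1)
        peaks = metrics.extract_peaks(c, icosphere_2562)
        assert len(peaks) == 1
        ang = np.degrees(np.arccos(min(1.0, abs(peaks.principal @ fc.directions[0]))))
        assert ang < 3.0

    def test_two_fibers_at_90(self, icosphere_2562):
        fc = simulate.FiberConfig(
            directions=np.array([[1.0, 0, 0], [0, 0, 1.0]]), weights=[0.5, 0.5]
        )
        peaks = metrics.extract_peaks(simulate.delta_fod_sh(fc), icosphere_2562)
        assert len(peaks) == 2
        for v in peaks.directions:
            best = min(
                np.degrees(np.arccos(min(1.0, abs(v @ u))))
                for u in fc.directions
            )
            assert best < 5.0

    def test_zero_coeffs_empty(self, icosphere_2562):
        assert len(metrics.extract_peaks(np.zeros(45), icosphere_2562)) == 0

    def test_antipodal_dedup(self, icosphere_2562):
        fc = simulate.FiberConfig(directions=[[0.0, 0.0, 1.0]], weights=[1.0])
        peaks = metrics.extract_peaks(simulate.delta_fod_sh(fc), icosphere_2562)
        assert len(peaks) == 1  # +z and -z collapse to one peak

    def test_amplitudes_positive_sorted(self, icosphere_2562, rng):
        _, c = random_fiber_fod(rng, 2)
        peaks = metrics.extract_peaks(c, icosphere_2562)
        assert np.all(peaks.amplitudes > 0)
        assert np.all(np.diff(peaks.amplitudes) <= 0)


class TestAngularError:
    def _ps(self, v):
        return metrics.PeakSet(np.atleast_2d(v), np.ones(1))

    def test_identical(self):
        assert metrics.angular_error(self._ps([0, 0, 1.0]), self._ps([0, 0, 1.0])) == 0.0

    def test_antipodal_zero(self):
        assert metrics.angular_error(self._ps([0, 0, 1.0]), self._ps([0, 0, -1.0])) == 0.0

    def test_orthogonal_90(self):
        assert metrics.angular_error(
            self._ps([0, 0, 1.0]), self._ps([1.0, 0, 0])
        ) == pytest.approx(90.0)

    def test_empty_is_nan(self):
        empty = metrics.PeakSet(np.empty((0, 3)), np.empty(0))
        assert np.isnan(metrics.angular_error(empty, self._ps([0, 0, 1.0])))


class TestPeakMatchRate:
    def test_perfect(self):
        assert metrics.peak_match_rate(np.zeros(10)) == 1.0

    def test_zero_threshold(self, rng):
        angles = rng.uniform(1.0, 90.0, 100)
        assert metrics.peak_match_rate(angles, 0.0) == 0.0

    def test_no_valid_voxels_rejected(self):
        with pytest.raises(ValueError, match="valid"):
            metrics.peak_match_rate(np.full(5, np.nan))

    def test_random_peaks_solid_angle(self, rng):
        # principal peaks uniformly random vs fixed gt: P(<20 deg) = 1 - cos 20
        n = 100_000
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        angles = np.degrees(np.arccos(np.abs(v[:, 2]).clip(max=1.0)))
        rate = metrics.peak_match_rate(angles, 20.0)
        expected = 1.0 - np.cos(np.deg2rad(20.0))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rate - expected) < 3 * se


class TestFieldEvaluation:
    def test_aeinvariance_under_joint_rotation(self, icosphere_2562, rng):
        kernel = simulate.watson_zonal(15.0)
        pred = np.stack([random_fiber_fod(rng, int(rng.integers(1, 3)), kernel)[1]
                         for _ in range(5)])
        gt = np.stack([random_fiber_fod(rng, 1, kernel)[1] for _ in range(5)])
        R = sphharm.random_rotation(rng)
        D = sphharm.rotation_operator(R, 8).D
        a0 = metrics.principal_peak_angles(pred, gt, icosphere_2562)
        a1 = metrics.principal_peak_angles(pred @ D.T, gt @ D.T, icosphere_2562)
        assert np.abs(a0 - a1).max() <= 1e-6
        r0 = metrics.peak_match_rate(a0)
        r1 = metrics.peak_match_rate(a1)
        assert abs(r0 - r1) <= 1e-6

    def test_ae_within_0_90(self, icosphere_2562, rng):
        pred = np.stack([random_fiber_fod(rng, 2)[1] for _ in range(10)])
        gt = np.stack([random_fiber_fod(rng, 1)[1] for _ in range(10)])
        angles = metrics.principal_peak_angles(pred, gt, icosphere_2562)
        valid = np.isfinite(angles)
        assert np.all(angles[valid] >= 0.0)
        assert np.all(angles[valid] <= 90.0)

    def test_evaluate_voxels_identity(self, icosphere_2562, rng):
        gt = np.stack([random_fiber_fod(rng, 1)[1] for _ in range(5)])
        rep = metrics.evaluate_voxels(gt, gt, icosphere_2562)
        assert rep.mse == 0.0
        assert rep.acc_mean == pytest.approx(1.0)
        assert rep.pmr == 1.0
        assert rep.psnr == np.inf

    def test_report_shape(self, icosphere_2562, rng):
        gt = np.stack([random_fiber_fod(rng, 1)[1] for _ in range(4)])
        pred = gt + 0.01 * rng.standard_normal(gt.shape)
        rep = metrics.evaluate_voxels(pred, gt, icosphere_2562)
        d = rep.to_dict()
        assert set(d["global_scalar"]) == {"MSE", "SSIM", "PSNR_dB"}
        assert d["fod_wise"]["peak_match_rate_20deg"] <= 1.0
        assert -1.0 <= d["fod_wise"]["ACC"]["mean"] <= 1.0

    def test_metric_maps(self, icosphere_2562, rng):
        kernel = simulate.watson_zonal(15.0)
        data = np.stack([random_fiber_fod(rng, 1, kernel)[1] for _ in range(8)])
        grid = data.reshape(2, 2, 2, 45)
        mask = np.ones((2, 2, 2), dtype=bool)
        mask[0, 0, 0] = False
        f = metrics.FODField(data=grid, mask=mask)
        maps = metrics.metric_maps(f, f, icosphere_2562)
        assert set(maps) == {"acc", "angular_error_deg"}
        assert np.isnan(maps["acc"][0, 0, 0])  # outside mask
        assert np.allclose(maps["acc"][mask], 1.0)
        assert np.nanmax(maps["angular_error_deg"]) < 1e-6

    def test_field_mask_mismatch_rejected(self, rng):
        data = rng.standard_normal((8, 8, 8, 45))
        m1 = np.ones((8, 8, 8), dtype=bool)
        m2 = m1.copy()
        m2[0, 0, 0] = False
        with pytest.raises(ValueError, match="mask"):
            metrics.evaluate_field(
                metrics.FODField(data=data, mask=m1),
                metrics.FODField(data=data, mask=m2),
            )
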