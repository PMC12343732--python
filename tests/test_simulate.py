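import numpy as np
import pytest

from sphfod import simulate, sphharm


class TestProtocol:
    def test_reduced_counts(self):
        p = simulate.protocol_reduced((64, 88, 128), 0.30)
        assert p.counts == (19, 26, 38)

    def test_reduced_total(self):
        assert simulate.protocol_reduced().total_directions == 83

    def test_identity_fraction(self):
        assert simulate.protocol_reduced(fraction=1.0).counts == (64, 88, 128)

    def test_too_small_fraction_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            simulate.protocol_reduced((10, 88, 128), 0.30)

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            simulate.protocol_reduced(fraction=0.0)

    def test_directions_unit_and_deterministic(self):
        p1 = simulate.protocol_reduced()
        p2 = simulate.protocol_reduced()
        for d1, d2 in zip(p1.directions, p2.directions):
            assert np.array_equal(d1, d2)
            assert np.abs(np.linalg.norm(d1, axis=1) - 1).max() < 1e-12


class TestTensorSignal:
    def test_b0(self):
        assert simulate.tensor_signal(0.0, [1, 0, 0], [0, 0, 1]) == 1.0

    def test_perpendicular(self):
        out = simulate.tensor_signal(1000.0, [1, 0, 0], [0, 0, 1], 1.7e-3, 0.4e-3)
        assert out == pytest.approx(np.exp(-0.4), rel=1e-12)

    def test_parallel(self):
        out = simulate.tensor_signal(1000.0, [0, 0, 1], [0, 0, 1], 1.7e-3, 0.4e-3)
        assert out == pytest.approx(np.exp(-1.7), rel=1e-12)

    def test_negative_b_rejected(self):
        with pytest.raises(ValueError):
            simulate.tensor_signal(-1.0, [1, 0, 0], [0, 0, 1])


class TestZonalResponse:
    def test_b0_constant_kernel(self):
        r = simulate.zonal_response(0.0)
        assert r[0] == pytest.approx(2.0 * np.sqrt(np.pi), rel=1e-12)
        assert np.abs(r[1:]).max() < 1e-12

    def test_isotropic_kernel(self):
        d = 1.0e-3
        r = simulate.zonal_response(1000.0, d_par=d, d_perp=d)
        assert r[0] == pytest.approx(2.0 * np.sqrt(np.pi) * np.exp(-1.0), rel=1e-10)
        assert np.abs(r[1:]).max() < 1e-12

    def test_quadrature_refinement(self):
        r64 = simulate.zonal_response(2600.0, quad_order=64)
        r128 = simulate.zonal_response(2600.0, quad_order=128)
        assert np.abs(r64 - r128).max() < 1e-10


class TestDeltaFOD:
    def test_single_fiber_z_axis(self):
        fc = simulate.FiberConfig(directions=[[0.0, 0.0, 1.0]], weights=[1.0])
        c = simulate.delta_fod_sh(fc)
        m = sphharm.index_table(8)[:, 1]
        assert np.abs(c[m != 0]).max() < 1e-12

    def test_antipodal_pair_equals_single(self):
        one = simulate.delta_fod_sh(
            simulate.FiberConfig(directions=[[0.6, 0.8, 0.0]], weights=[1.0])
        )
        pair = simulate.delta_fod_sh(
            simulate.FiberConfig(
                directions=[[0.6, 0.8, 0.0], [-0.6, -0.8, 0.0]], weights=[0.5, 0.5]
            )
        )
        assert np.abs(one - pair).max() < 1e-12

    def test_argmax_near_planted(self, dense_sampling, rng):
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        c = simulate.delta_fod_sh(
            simulate.FiberConfig(directions=[v], weights=[1.0])
        )
        amp = sphharm.isft(c, dense_sampling)
        best = dense_sampling.dirs[np.argmax(amp)]
        angle = np.degrees(np.arccos(min(1.0, abs(best @ v))))
        assert angle < 3.0

    def test_empty_fibers_rejected(self):
        with pytest.raises(ValueError):
            simulate.FiberConfig(directions=np.empty((0, 3)), weights=np.empty(0))

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            simulate.FiberConfig(directions=[[0, 0, 1.0]], weights=[0.5])


class TestWatsonKernel:
    def test_normalized_integral(self):
        c = simulate.watson_zonal(15.0)
        assert c[0] * np.sqrt(4 * np.pi) == pytest.approx(1.0, rel=1e-12)

    def test_kappa_zero_is_isotropic(self):
        c = simulate.watson_zonal(0.0)
        assert np.abs(c[1:]).max() < 1e-12

    def test_peak_stays_at_fiber(self, dense_sampling):
        v = np.array([0.0, 0.6, 0.8])
        fc = simulate.FiberConfig(directions=[v], weights=[1.0])
        c = simulate.fiber_fod_sh(fc, simulate.watson_zonal(15.0))
        best = dense_sampling.dirs[np.argmax(sphharm.isft(c, dense_sampling))]
        assert np.degrees(np.arccos(min(1.0, abs(best @ v)))) < 3.0


class TestSHConvolve:
    def test_zero_response(self, rng):
        c = rng.standard_normal(45)
        assert np.all(simulate.sh_convolve(c, np.zeros(5)) == 0)

    def test_isotropic_fod(self):
        c = np.zeros(45)
        c[0] = 1.0
        r = simulate.zonal_response(1000.0)
        out = simulate.sh_convolve(c, r)
        assert np.abs(out[1:]).max() < 1e-12

    def test_forward_model_matches_direct_evaluation(self, rng):
        # SH-convolution route vs per-fiber tensor evaluation, 100 configs
        protocol = simulate.protocol_reduced()
        responses = [simulate.zonal_response(b) for b in protocol.bvalues]
        bases = [sphharm.build_basis(d, 8) for d in protocol.directions]
        worst = 0.0
        for _ in range(100):
            nf = int(rng.integers(1, 4))
            fc = simulate._sample_fibers(rng, nf, 40, 90, 1.7e-3, 0.4e-3)
            fod = simulate.delta_fod_sh(fc)
            for b, r, Y, dirs in zip(
                protocol.bvalues, responses, bases, protocol.directions
            ):
                via_sh = Y @ simulate.sh_convolve(fod, r)
                direct = sum(
                    w * simulate.tensor_signal(b, dirs, v)
                    for w, v in zip(fc.weights, fc.directions)
                )
                worst = max(worst, np.abs(via_sh - direct).max())
        assert worst < 0.02  # within truncation error of s0 = 1


class TestRicianNoise:
    def test_sigma_zero_identity(self, rng):
        x = rng.random(100)
        assert np.array_equal(simulate.add_rician_noise(x, 0.0, rng), x)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            simulate.add_rician_noise(np.ones(3), -0.1, 0)

    def test_second_moment_identity(self):
        s, sigma, n = 0.7, 0.1, 100_000
        x = simulate.add_rician_noise(np.full(n, s), sigma, 0)
        expected = s**2 + 2 * sigma**2
        mc_se = np.std(x**2) / np.sqrt(n)
        assert abs(np.mean(x**2) - expected) < 3 * mc_se

    def test_rayleigh_mean_at_zero_signal(self):
        sigma, n = 0.25, 100_000
        x = simulate.add_rician_noise(np.zeros(n), sigma, 1)
        expected = sigma * np.sqrt(np.pi / 2.0)
        mc_se = np.std(x) / np.sqrt(n)
        assert abs(np.mean(x) - expected) < 3 * mc_se

    def test_seed_reproducibility(self):
        a = simulate.add_rician_noise(np.ones(10), 0.1, 7)
        b = simulate.add_rician_noise(np.ones(10), 0.1, 7)
        assert np.array_equal(a, b)


class TestPhantom:
    def test_reproducible(self):
        d1 = simulate.generate_phantom(50, seed=3)
        d2 = simulate.generate_phantom(50, seed=3)
        for a, b in zip(d1.voxels, d2.voxels):
            assert np.array_equal(a.fod_sh, b.fod_sh)
            for x, y in zip(a.dwi, b.dwi):
                assert np.array_equal(x, y)

    def test_requested_count(self):
        assert len(simulate.generate_phantom(120, seed=0)) == 120

    def test_splits_partition(self):
        ds = simulate.generate_phantom(100, seed=0)
        allidx = np.sort(np.concatenate(list(ds.splits.values())))
        assert np.array_equal(allidx, np.arange(100))

    def test_orientation_clustering(self):
        ds = simulate.generate_phantom(
            200, seed=8, noisy=False, fiber_fractions=(1.0, 0.0, 0.0),
            n_orientation_axes=3, orientation_kappa=80.0,
        )
        dirs = np.stack([v.fiber_config.directions[0] for v in ds.voxels])
        # greedy covering: every fiber within 30 degrees of <= 3 representatives
        reps = [dirs[0]]
        for v in dirs:
            if all(abs(v @ r) < np.cos(np.deg2rad(30.0)) for r in reps):
                reps.append(v)
        assert len(reps) <= 3

    def test_noiseless_single_fiber_peaks(self, dense_sampling):
        ds = simulate.generate_phantom(
            100, seed=11, noisy=False, fiber_fractions=(1.0, 0.0, 0.0)
        )
        hits = 0
        for vox in ds.voxels:
            amp = sphharm.isft(vox.fod_sh, dense_sampling)
            best = dense_sampling.dirs[np.argmax(amp)]
            v = vox.fiber_config.directions[0]
            if np.degrees(np.arccos(min(1.0, abs(best @ v)))) < 3.0:
                hits += 1
        assert hits == 100

    def test_ground_truth_integral(self, dense_sampling):
        ds = simulate.generate_phantom(20, seed=2, noisy=False)
        for vox in ds.voxels[:20]:
            integral = float(
                sphharm.isft(vox.fod_sh, dense_sampling) @ dense_sampling.quad_weights
            )
            assert integral == pytest.approx(1.0, rel=0.01)


class TestPerShellFit:
    def test_constant_signal(self):
        # overdetermined (full) protocol: least squares is exact
        protocol = simulate.protocol_reduced(fraction=1.0)
        dwi = [np.ones(c) for c in protocol.counts]
        ms = simulate.fit_per_shell_sh(dwi, protocol, ridge=0.0)
        assert ms.shape == (3, 45)
        for s in range(3):
            assert ms[s, 0] == pytest.approx(2 * np.sqrt(np.pi), abs=1e-6)
            assert np.abs(ms[s, 1:]).max() < 1e-6

    def test_output_shape_3x45(self, rng):
        ds = simulate.generate_phantom(10, seed=0)
        ms = simulate.fit_per_shell_sh(ds.dwi(), ds.protocol)
        assert ms.shape == (10, 3, 45)

    def test_refit_roundtrip(self, rng):
        # noiseless signal refit and re-evaluated at acquisition directions
        protocol = simulate.protocol_reduced()
        ds = simulate.generate_phantom(20, seed=5, noisy=False)
        ms = simulate.fit_per_shell_sh(ds.dwi(), ds.protocol, ridge=1e-6)
        for s, dirs in enumerate(protocol.directions):
            Y = sphharm.build_basis(dirs, 8)
            refit = ms[:, s, :] @ Y.T
            orig = np.stack([v.dwi[s] for v in ds.voxels])
            assert np.abs(refit - orig).max() < 0.05

    def test_small_shell_rejected(self):
        protocol = simulate.Protocol(
            bvalues=(1000.0,), directions=(sphharm.fibonacci_sphere(4),)
        )
        with pytest.raises(ValueError, match="b=1000"):
            simulate.fit_per_shell_sh([np.ones(4)], protocol)

    def test_laplace_beltrami_shrinks_high_degrees(self):
        ds = simulate.generate_phantom(20, seed=4)
        ridge = simulate.fit_per_shell_sh(ds.dwi(), ds.protocol, ridge=1e-3)
        lb = simulate.fit_per_shell_sh(
            ds.dwi(), ds.protocol, ridge=1e-3, regularizer="laplace_beltrami"
        )
        l8 = sphharm.degree_of_index(8) == 8
        assert np.linalg.norm(lb[..., l8]) < np.linalg.norm(ridge[..., l8])

    def test_unknown_regularizer_rejected(self):
        ds = simulate.generate_phantom(2, seed=4)
        with pytest.raises(ValueError, match="regularizer"):
            simulate.fit_per_shell_sh(ds.dwi(), ds.protocol, regularizer="bogus")

    def test_noise_floor_convergence(self):
        clean = simulate.generate_phantom(10, seed=9, noisy=False)
        near = simulate.generate_phantom(10, seed=9, snr=1e6)
        msc = simulate.fit_per_shell_sh(clean.dwi(), clean.protocol)
        msn = simulate.fit_per_shell_sh(near.dwi(), near.protocol)
        assert np.abs(msc - msn).max() <= 1e-3
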