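"""PCA trajectories, angular changes, and recurrence maps."""

import numpy as np
import pytest
from scipy.stats import kstest

from wormdyn import (angle_histogram, angular_changes, low_angle_mass,
                     recurrence_map, run_pca)
from wormdyn.errors import EmptyResultError


class TestPCA:
    def test_rank_one_data(self, rng):
        latent = rng.normal(0, 1, 500)
        weights = rng.normal(0, 1, 20)
        data = np.outer(weights, latent) + rng.normal(0, 1e-6, (20, 500))
        traj = run_pca(data, k=3)
        assert traj.explained_var[0] > 0.999

    def test_isotropic_noise_has_no_dominant_component(self, rng):
        traj = run_pca(rng.normal(0, 1, (120, 1200)), k=3)
        assert traj.explained_var[0] < 0.05

    def test_three_latents_variance_ratios(self, rng):
        n = 20000
        latents = rng.normal(0, 1, (3, n)) * np.array([[2.0], [np.sqrt(2)],
                                                       [1.0]])
        mixing = np.linalg.qr(rng.normal(0, 1, (12, 3)))[0]
        data = mixing @ latents
        traj = run_pca(data, k=3)
        np.testing.assert_allclose(traj.explained_var[:3],
                                   [4 / 7, 2 / 7, 1 / 7], rtol=0.02)

    def test_explained_var_sums_to_one(self, rng):
        traj = run_pca(rng.normal(0, 1, (10, 300)), k=3)
        assert traj.explained_var.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(traj.explained_var) <= 1e-12)

    def test_sign_convention_deterministic(self, rng):
        data = rng.normal(0, 1, (8, 200))
        a = run_pca(data, k=3)
        b = run_pca(data.copy(), k=3)
        np.testing.assert_array_equal(a.scores, b.scores)
        for j in range(3):
            assert a.loadings[np.argmax(np.abs(a.loadings[:, j])), j] > 0

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError):
            run_pca(rng.normal(0, 1, (3, 50)), k=5)


class TestAngles:
    def test_straight_line_all_zero(self):
        t = np.arange(100, dtype=float)
        P = np.stack([t, 2 * t, -t], axis=1)
        ang = angular_changes(P, sampling_rate=2.0, window_s=3.0)
        defined = ang.angles[~np.isnan(ang.angles)]
        np.testing.assert_allclose(defined, 0.0, atol=1e-6)

    def test_reversals_are_180(self):
        # direction flips every window
        w = 6
        steps = np.concatenate([np.ones(w) * (-1) ** k
                                for k in range(20)])
        P = np.cumsum(steps)[:, None]
        ang = angular_changes(P, sampling_rate=2.0, window_s=3.0)
        flips = ang.angles[w::w]
        flips = flips[~np.isnan(flips)]
        assert np.any(np.isclose(flips, 180.0))

    def test_random_walk_sine_density(self):
        rng = np.random.default_rng(6)
        P = np.cumsum(rng.normal(0, 1, (10001, 3)), axis=0)
        ang = angular_changes(P, sampling_rate=1.0, window_s=1.0)
        d = ang.angles[~np.isnan(ang.angles)]
        assert np.mean(d) == pytest.approx(90.0, abs=2.0)
        stat, _ = kstest(d, lambda x: 0.5 * (1 - np.cos(np.radians(x))))
        assert stat < 0.02

    def test_rigid_rotation_and_scaling_invariance(self, rng):
        P = np.cumsum(rng.normal(0, 1, (500, 3)), axis=0)
        R = np.linalg.qr(rng.normal(0, 1, (3, 3)))[0]
        a = angular_changes(P, 2.0, 3.0).angles
        b = angular_changes(5.0 * P @ R.T, 2.0, 3.0).angles
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_zero_displacement_marked_undefined(self):
        P = np.zeros((50, 3))
        ang = angular_changes(P, 2.0, 3.0)
        assert ang.n_undefined == 50 - 2 * 6
        assert np.all(np.isnan(ang.angles))


class TestAngleHistogram:
    def test_all_zero_angles_first_bin(self):
        t = np.arange(100, dtype=float)
        ang = angular_changes(np.stack([t, t, t], axis=1), 2.0, 3.0)
        h, _ = angle_histogram(ang, bins=18)
        assert h[0] == 1.0

    def test_uniform_angles_flat(self, rng):
        from wormdyn.states import AngularChangeSeries
        s = AngularChangeSeries(angles=rng.uniform(0, 180, 20000),
                                window_s=3.0, n_undefined=0)
        h, _ = angle_histogram(s, bins=18)
        np.testing.assert_allclose(h, 1 / 18, atol=0.01)

    def test_pooling_weights_by_count(self):
        from wormdyn.states import AngularChangeSeries
        a = AngularChangeSeries(angles=np.full(10, 5.0), window_s=3.0,
                                n_undefined=0)
        b = AngularChangeSeries(angles=np.full(30, 175.0), window_s=3.0,
                                n_undefined=0)
        h, _ = angle_histogram([a, b], bins=18)
        assert h[0] == pytest.approx(0.25)
        assert h[-1] == pytest.approx(0.75)

    def test_no_angles_error(self):
        from wormdyn.states import AngularChangeSeries
        s = AngularChangeSeries(angles=np.full(5, np.nan), window_s=3.0,
                                n_undefined=5)
        with pytest.raises(EmptyResultError):
            angle_histogram(s)


class TestRecurrence:
    def test_identical_frames_zero_distance(self):
        data = np.array([[1.0, 1.0, 2.0], [0.5, 0.5, 1.0]])
        rm = recurrence_map(data)
        assert rm.dist[0, 1] == 0.0

    def test_exact_period_gives_zero_bands(self, rng):
        block = rng.normal(0, 1, (5, 50))
        data = np.tile(block, (1, 4))
        rm = recurrence_map(data)
        for lag in (50, 100, 150):
            off = np.array([rm.dist[i, i + lag]
                            for i in range(200 - lag)])
            np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_symmetric_unit_max_zero_diagonal(self, rng):
        rm = recurrence_map(rng.normal(0, 1, (10, 80)))
        np.testing.assert_allclose(rm.dist, rm.dist.T)
        assert rm.dist.max() == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(rm.dist), 0.0)

    def test_frame_permutation_equivariance(self, rng):
        data = rng.normal(0, 1, (6, 40))
        perm = rng.permutation(40)
        a = recurrence_map(data).dist
        b = recurrence_map(data[:, perm]).dist
        np.testing.assert_allclose(a[np.ix_(perm, perm)], b, atol=1e-12)

    def test_degenerate_all_equal(self):
        rm = recurrence_map(np.ones((4, 10)))
        assert rm.degenerate
        np.testing.assert_allclose(rm.dist, 0.0)
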