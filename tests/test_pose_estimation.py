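"""Weights, weighted cost, P3P/RANSAC and Kalman filter tests."""

import numpy as np
import pytest
from scipy.linalg import solve_discrete_are
from scipy.spatial.transform import Rotation

from blurtrack.geometry import CameraIntrinsics, CameraRig, Pose, project_points, rotation_angle
from blurtrack.pose_estimation import (
    Correspondences2D3D,
    KalmanState,
    compute_weights,
    estimate_pose_ransac,
    kabsch,
    kalman_update,
    p3p_grunert,
    score_pose,
    unweighted_reprojection_error,
    weighted_reprojection_error,
    _bearing,
)


@pytest.fixture
def rig():
    cam = CameraIntrinsics(fx=1200, fy=1200, cx=512, cy=512)
    R = Rotation.from_euler("y", -12, degrees=True).as_matrix()
    return CameraRig(cam, cam, R, np.array([-0.5, 0.0, 0.1]))


def two_view_corrs(X, pose, rig, noise=0.0, rng=None):
    uv0 = project_points(X, pose, rig.cam0)
    pose1 = Pose(rig.rig_rotation, rig.rig_translation).compose(pose)
    uv1 = project_points(X, pose1, rig.cam1)
    if noise and rng is not None:
        uv0 = uv0 + rng.normal(0, noise, uv0.shape)
        uv1 = uv1 + rng.normal(0, noise, uv1.shape)
    n = len(X)
    return Correspondences2D3D(
        np.vstack([X, X]), np.vstack([uv0, uv1]),
        np.concatenate([np.zeros(n, int), np.ones(n, int)]),
    )


class TestComputeWeights:
    def test_two_points_symmetric(self):
        w = compute_weights(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert np.allclose(w, [0.5, 0.5])

    def test_collinear_hand_case(self):
        """x = 0, 1, 2 -> raw (5, 2, 5), normalized (5/12, 2/12, 5/12)."""
        w = compute_weights(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]))
        assert np.allclose(w, [5 / 12, 2 / 12, 5 / 12])

    def test_distant_point_outweighs_cluster(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 1.0, (10, 2)), [[300.0, 300.0]]])
        w = compute_weights(pts)
        assert w[-1] > w[:10].max()

    def test_sum_to_one_and_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, (17, 2))
        views = rng.integers(0, 2, 17)
        w = compute_weights(pts, views)
        assert abs(w.sum() - 1.0) < 1e-12
        perm = rng.permutation(17)
        assert np.allclose(compute_weights(pts[perm], views[perm]), w[perm])

    def test_coincident_points_uniform_fallback(self):
        w = compute_weights(np.zeros((4, 2)))
        assert np.allclose(w, 0.25)


class TestReprojectionCosts:
    def test_perfect_pose_zero_error(self, rig):
        rng = np.random.default_rng(2)
        pose = Pose(Rotation.random(random_state=np.random.RandomState(3)).as_matrix(),
                    [0.0, 0.1, 2.0])
        corrs = two_view_corrs(rng.normal(0, 0.15, (12, 3)), pose, rig)
        assert weighted_reprojection_error(pose, corrs, rig) < 1e-9

    def test_uniform_weights_equal_unweighted(self, rig):
        rng = np.random.default_rng(4)
        pose = Pose(np.eye(3), [0.0, 0.0, 2.0])
        corrs = two_view_corrs(rng.normal(0, 0.15, (10, 3)), pose, rig,
                               noise=2.0, rng=rng)
        n = len(corrs)
        w = weighted_reprojection_error(pose, corrs, rig, weights=np.full(n, 1 / n))
        u = unweighted_reprojection_error(pose, corrs, rig)
        assert w == pytest.approx(u, abs=1e-12)

    def test_matches_double_loop_oracle(self, rig):
        """Vectorized weighted cost equals an independently coded scalar loop."""
        rng = np.random.default_rng(5)
        pose_true = Pose(Rotation.random(random_state=np.random.RandomState(6)).as_matrix(),
                         [0.05, -0.1, 1.9])
        corrs = two_view_corrs(rng.normal(0, 0.2, (9, 3)), pose_true, rig,
                               noise=3.0, rng=rng)
        pose_eval = Pose(
            Rotation.from_euler("z", 2, degrees=True).as_matrix() @ pose_true.rotation,
            pose_true.translation + [0.01, 0, 0],
        )
        total = 0.0
        rig_pose = Pose(rig.rig_rotation, rig.rig_translation)
        for i in range(len(corrs)):
            X = corrs.object_points[i]
            if corrs.view_ids[i] == 0:
                Pc = pose_eval.rotation @ X + pose_eval.translation
                cam = rig.cam0
            else:
                P0 = pose_eval.rotation @ X + pose_eval.translation
                Pc = rig_pose.rotation @ P0 + rig_pose.translation
                cam = rig.cam1
            u = cam.fx * Pc[0] / Pc[2] + cam.cx
            v = cam.fy * Pc[1] / Pc[2] + cam.cy
            d = np.hypot(u - corrs.image_points[i, 0], v - corrs.image_points[i, 1])
            total += corrs.weights[i] * d
        assert weighted_reprojection_error(pose_eval, corrs, rig) == \
            pytest.approx(total, abs=1e-12)


class TestP3P:
    def test_recovers_true_pose_among_candidates(self):
        cam = CameraIntrinsics(fx=1000, fy=1000, cx=512, cy=512)
        rng = np.random.default_rng(7)
        for trial in range(50):
            R = Rotation.random(random_state=np.random.RandomState(trial)).as_matrix()
            pose = Pose(R, rng.normal(0, 0.2, 3) + [0, 0, 2.2])
            X = rng.normal(0, 0.25, (3, 3))
            uv = project_points(X, pose, cam)
            sols = p3p_grunert(X, _bearing(cam, uv))
            assert sols
            best = min(np.abs(s.rotation - R).max() + np.abs(s.translation - pose.translation).max()
                       for s in sols)
            assert best < 1e-3

    def test_kabsch_exact(self):
        rng = np.random.default_rng(8)
        R = Rotation.random(random_state=np.random.RandomState(9)).as_matrix()
        t = rng.normal(0, 1, 3)
        X = rng.normal(0, 1, (10, 3))
        R2, t2 = kabsch(X, X @ R.T + t)
        assert np.abs(R2 - R).max() < 1e-10 and np.abs(t2 - t).max() < 1e-10


class TestRansac:
    def test_noiseless_recovery(self, rig):
        rng = np.random.default_rng(10)
        R = Rotation.random(random_state=np.random.RandomState(11)).as_matrix()
        pose = Pose(R, [0.1, -0.05, 2.0])
        corrs = two_view_corrs(rng.normal(0, 0.15, (20, 3)), pose, rig)
        est = estimate_pose_ransac(corrs, rig, seed=1)
        assert est is not None
        assert rotation_angle(est.pose.rotation @ R.T) < 1e-6
        assert np.abs(est.pose.translation - pose.translation).max() < 1e-6

    def test_planted_outliers_excluded(self, rig):
        """16 exact + 4 corrupted correspondences: outliers identified, pose exact."""
        rng = np.random.default_rng(12)
        R = Rotation.random(random_state=np.random.RandomState(13)).as_matrix()
        pose = Pose(R, [0.0, 0.05, 1.8])
        X = rng.normal(0, 0.15, (10, 3))
        corrs = two_view_corrs(X, pose, rig)  # 20 correspondences
        bad = np.array([1, 6, 11, 16])
        corrs.image_points[bad] += 50.0
        est = estimate_pose_ransac(corrs, rig, seed=2)
        assert est is not None
        assert set(corrs.point_ids[bad]).isdisjoint(set(est.inlier_ids))
        assert rotation_angle(est.pose.rotation @ R.T) < 1e-6

    def test_seed_determinism(self, rig):
        rng = np.random.default_rng(14)
        pose = Pose(np.eye(3), [0.0, 0.0, 2.0])
        corrs = two_view_corrs(rng.normal(0, 0.15, (15, 3)), pose, rig,
                               noise=2.0, rng=rng)
        a = estimate_pose_ransac(corrs, rig, seed=42)
        b = estimate_pose_ransac(corrs, rig, seed=42)
        assert np.array_equal(a.inlier_ids, b.inlier_ids)
        assert np.array_equal(a.pose.rotation, b.pose.rotation)
        assert a.weighted_error == b.weighted_error

    def test_adding_exact_point_never_hurts(self, rig):
        rng = np.random.default_rng(15)
        R = Rotation.random(random_state=np.random.RandomState(16)).as_matrix()
        pose = Pose(R, [0.0, 0.0, 2.0])
        X = rng.normal(0, 0.15, (12, 3))
        corrs = two_view_corrs(X, pose, rig)
        base = estimate_pose_ransac(corrs, rig, seed=3)
        X_plus = np.vstack([X, rng.normal(0, 0.15, (1, 3))])
        corrs_plus = two_view_corrs(X_plus, pose, rig)
        more = estimate_pose_ransac(corrs_plus, rig, seed=3)
        assert more.weighted_error <= base.weighted_error + 1e-9

    def test_cluster_vs_sparse_scoring(self, rig):
        """A dense 3-point cluster moved by a conflicting transform: ranking
        by weighted inlier mass prefers the fit through the sparse points,
        ranking by raw count prefers the cluster fit."""
        balanced = Pose(np.eye(3), [0.0, 0.0, 2.0])
        conflict = Pose(
            Rotation.from_euler("z", 3, degrees=True).as_matrix(),
            [0.015, 0.01, 2.0],
        )
        cluster = np.array([[0.55, 0.55, 0.0], [0.57, 0.55, 0.0], [0.56, 0.57, 0.0]])
        sparse = np.array([[-0.6, -0.6, 0.0], [-0.6, 0.55, 0.0]])
        X = np.vstack([cluster, sparse])
        obs = np.vstack([
            project_points(cluster, conflict, rig.cam0),   # cluster follows the other motion
            project_points(sparse, balanced, rig.cam0),
        ])
        corrs = Correspondences2D3D(X, obs, np.zeros(5, int))
        _, cnt_bal, mass_bal = score_pose(balanced, corrs, rig, threshold_px=15.0)
        _, cnt_clu, mass_clu = score_pose(conflict, corrs, rig, threshold_px=15.0)
        assert cnt_clu > cnt_bal          # unweighted scoring picks the cluster fit
        assert mass_bal > mass_clu        # weighted scoring picks the balanced fit

    def test_too_few_points_fails(self, rig):
        rng = np.random.default_rng(17)
        pose = Pose(np.eye(3), [0, 0, 2.0])
        corrs = two_view_corrs(rng.normal(0, 0.1, (1, 3)), pose, rig)
        assert estimate_pose_ransac(corrs, rig, seed=0) is None


class TestKalman:
    dt = 0.005

    def _run_cv(self, state, n, x0, v, rot, rng=None, sigma=0.0):
        out = []
        for k in range(n):
            z = x0 + v * (k * self.dt)
            if rng is not None and sigma:
                z = z + rng.normal(0, sigma, 3)
            out.append(kalman_update(state, Pose(rot, z), self.dt))
        return out

    def test_constant_velocity_latches_exactly(self):
        st = KalmanState()
        x0 = np.array([0.1, 0.2, 2.0])
        v = np.array([1.0, -2.0, 0.3])
        R = Rotation.from_euler("x", 10, degrees=True).as_matrix()
        results = self._run_cv(st, 10, x0, v, R)
        for k in range(5, 10):
            pose, ok = results[k]
            assert ok
            assert np.abs(pose.translation - (x0 + v * k * self.dt)).max() < 1e-9

    def test_position_spike_rejected_by_gate(self):
        st = KalmanState()
        x0 = np.zeros(3)
        v = np.array([1.0, 0.0, 0.0])
        R = np.eye(3)
        self._run_cv(st, 10, x0, v, R)
        spike = x0 + v * (10 * self.dt) + [1.0, 0.0, 0.0]
        _, ok = kalman_update(st, Pose(R, spike), self.dt)
        assert not ok
        _, ok2 = kalman_update(st, Pose(R, x0 + v * (11 * self.dt)), self.dt)
        assert ok2  # track resumes

    def test_gain_converges_to_riccati_solution(self):
        st = KalmanState()
        rng = np.random.default_rng(18)
        self._run_cv(st, 600, np.zeros(3), np.array([1.0, -2.0, 0.3]), np.eye(3),
                     rng=rng, sigma=st.sigma_meas)
        dt = self.dt
        F = np.eye(6)
        F[:3, 3:] = dt * np.eye(3)
        G = np.concatenate([0.5 * dt * dt * np.eye(3), dt * np.eye(3)])
        Q = st.sigma_accel**2 * (G @ G.T)
        H = np.zeros((3, 6))
        H[:, :3] = np.eye(3)
        Rm = st.sigma_meas**2 * np.eye(3)
        P = solve_discrete_are(F.T, H.T, Q, Rm)
        K_inf = P @ H.T @ np.linalg.inv(H @ P @ H.T + Rm)
        assert np.abs(st.last_gain - K_inf).max() < 1e-6

    def test_uninitialized_state_adopts_measurement(self):
        st = KalmanState()
        pose, ok = kalman_update(st, Pose(np.eye(3), [1.0, 2.0, 3.0]), self.dt)
        assert ok and np.allclose(pose.translation, [1, 2, 3])

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            kalman_update(KalmanState(), Pose.identity(), 0.0)
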