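"""Weighted robust 6-DOF pose estimation from sparse 2D-3D correspondences.

An object is represented by a handful of reconstructed 3D points whose
images are anything but uniformly distributed: texture clusters project to
dense clumps while isolated features sit alone in large empty regions.  A
conventional mean-reprojection cost (and a RANSAC that ranks consensus
sets by raw inlier count) then over-fits the clumps — the estimator can
nail ten points in a 30-pixel patch, ignore the rest of the object, and
still look good.  The fix used here weights every image point by its
summed squared distance to the other points of the same view,

    w_i = sum_j |p_i - p_j|^2 ,   normalized so that sum_i w_i = 1

(the sum pooling both views), so points in sparsely sampled areas carry
much more importance.  The weights enter twice: consensus sets are ranked
by *weighted inlier mass* rather than by count, and the accepted pose must
achieve a weighted reprojection error below the pixel threshold (default
15 px — generous because motion blur smears a point's true location over
several pixels).

The minimal solver is Grunert's three-point resection plus a fourth point
for disambiguation; the final pose is a Levenberg-Marquardt refinement on
the inlier set.  A constant-velocity Kalman filter on translation with
innovation gating (plus exponential smoothing of rotation increments)
optionally rejects poorly estimated frames downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import optimize
from scipy.stats import chi2

from .geometry import (
    CameraRig,
    Pose,
    project_points,
    rodrigues,
    rodrigues_inverse,
)

__all__ = [
    "Correspondences2D3D",
    "RobustEstimate",
    "KalmanState",
    "compute_weights",
    "reprojection_residuals",
    "weighted_reprojection_error",
    "unweighted_reprojection_error",
    "score_pose",
    "p3p_grunert",
    "kabsch",
    "estimate_pose_ransac",
    "kalman_update",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Correspondences2D3D:
    """2D-3D correspondences pooled over both views.

    ``object_points`` are in the object-local frame; ``view_ids`` select the
    observing camera (0 or 1); ``weights`` are the normalized sparsity
    weights (sum to 1 over the whole problem) and are filled by
    :func:`compute_weights` when not supplied.
    """

    object_points: np.ndarray
    image_points: np.ndarray
    view_ids: np.ndarray
    weights: np.ndarray | None = None
    point_ids: np.ndarray | None = None

    def __post_init__(self):
        self.object_points = np.atleast_2d(np.asarray(self.object_points, float))
        self.image_points = np.atleast_2d(np.asarray(self.image_points, float))
        self.view_ids = np.atleast_1d(np.asarray(self.view_ids, int))
        if self.weights is None:
            self.weights = compute_weights(self.image_points, self.view_ids)
        else:
            self.weights = np.atleast_1d(np.asarray(self.weights, float))
        if self.point_ids is None:
            self.point_ids = np.arange(len(self.object_points))

    def __len__(self) -> int:
        return len(self.object_points)


@dataclass
class RobustEstimate:
    """Accepted robust pose estimate with its consensus diagnostics."""

    pose: Pose
    inlier_ids: np.ndarray
    weighted_error: float
    iterations_used: int
    inlier_mass: float


# ---------------------------------------------------------------------------
# Sparsity weights
# ---------------------------------------------------------------------------

def compute_weights(image_points: np.ndarray, view_ids: np.ndarray | None = None) -> np.ndarray:
    """Per-point sparsity weights, normalized to sum to 1 over all points.

    Within each view the raw weight of a point is its summed squared
    distance to every other point *of that view*; the raw weights of both
    views are then pooled and scaled by ``1 / sum``.  Isolated points are
    thereby up-weighted and dense clusters down-weighted.  If all points
    coincide (zero total), uniform weights ``1/n`` are returned.
    """
    pts = np.atleast_2d(np.asarray(image_points, float))
    n = len(pts)
    if n == 0:
        return np.zeros(0)
    if view_ids is None:
        view_ids = np.zeros(n, int)
    view_ids = np.atleast_1d(np.asarray(view_ids, int))
    raw = np.zeros(n)
    for v in np.unique(view_ids):
        sel = view_ids == v
        p = pts[sel]
        d2 = np.sum((p[:, None, :] - p[None, :, :]) ** 2, axis=2)
        raw[sel] = d2.sum(axis=1)
    total = raw.sum()
    if total <= 0:
        return np.full(n, 1.0 / n)
    return raw / total


# ---------------------------------------------------------------------------
# Reprojection costs
# ---------------------------------------------------------------------------

def _pose_in_view(pose: Pose, rig: CameraRig, view: int) -> Pose:
    if view == 0:
        return pose
    return Pose(rig.rig_rotation, rig.rig_translation).compose(pose)


def reprojection_residuals(pose: Pose, corrs: Correspondences2D3D,
                           rig: CameraRig) -> np.ndarray:
    """Per-correspondence pixel residual norms; +inf behind a camera."""
    res = np.full(len(corrs), np.inf)
    for view, cam in ((0, rig.cam0), (1, rig.cam1)):
        sel = np.nonzero(corrs.view_ids == view)[0]
        if len(sel) == 0:
            continue
        uv = project_points(corrs.object_points[sel], _pose_in_view(pose, rig, view),
                            cam, strict=False)
        d = np.linalg.norm(uv - corrs.image_points[sel], axis=1)
        res[sel] = np.where(np.isfinite(d), d, np.inf)
    return res


def weighted_reprojection_error(pose: Pose, corrs: Correspondences2D3D,
                                rig: CameraRig,
                                weights: np.ndarray | None = None) -> float:
    """Weighted cost ``sum_i w_i |p_i - p_i*|`` over both views."""
    w = corrs.weights if weights is None else weights
    res = reprojection_residuals(pose, corrs, rig)
    return float(np.sum(w * res))


def unweighted_reprojection_error(pose: Pose, corrs: Correspondences2D3D,
                                  rig: CameraRig) -> float:
    """Plain mean cost ``(1/n) sum_i |p_i - p_i*|`` for A/B comparison."""
    res = reprojection_residuals(pose, corrs, rig)
    return float(np.mean(res))


def score_pose(pose: Pose, corrs: Correspondences2D3D, rig: CameraRig,
               threshold_px: float):
    """Consensus statistics of a candidate pose.

    Returns ``(inlier_idx, count, weighted_mass)`` where inliers are the
    correspondences with residual below ``threshold_px``.
    """
    res = reprojection_residuals(pose, corrs, rig)
    inl = np.nonzero(res < threshold_px)[0]
    return inl, len(inl), float(np.sum(corrs.weights[inl]))


# ---------------------------------------------------------------------------
# Minimal solver: Grunert P3P + Kabsch
# ---------------------------------------------------------------------------

def kabsch(X: np.ndarray, Y: np.ndarray, weights: np.ndarray | None = None):
    """Least-squares rigid transform with ``Y ~ R X + t`` (proper rotation)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    w = np.ones(len(X)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    mx = w @ X
    my = w @ Y
    H = (X - mx).T @ ((Y - my) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = my - R @ mx
    return R, t


def p3p_grunert(object_points: np.ndarray, bearings: np.ndarray) -> list[Pose]:
    """Grunert's three-point resection.

    ``bearings`` are unit rays in the camera frame toward the three image
    observations.  Returns up to four poses mapping object coordinates into
    that camera frame.  The quartic in the distance ratio ``v = s3/s1`` is
    assembled by explicit polynomial arithmetic from the law-of-cosines
    system, which keeps the coefficients free of transcription errors.
    """
    X = np.asarray(object_points, float)
    f = np.asarray(bearings, float)
    f = f / np.linalg.norm(f, axis=1, keepdims=True)

    a = np.linalg.norm(X[1] - X[2])   # opposite ray 1
    b = np.linalg.norm(X[0] - X[2])   # opposite ray 2
    c = np.linalg.norm(X[0] - X[1])   # opposite ray 3
    if min(a, b, c) < 1e-12 or b < 1e-12:
        return []
    cos_a = float(f[1] @ f[2])
    cos_b = float(f[0] @ f[2])
    cos_g = float(f[0] @ f[1])
    A = (a * a) / (b * b)
    B = (c * c) / (b * b)

    # With u = s2/s1, v = s3/s1 and q(v) = 1 + v^2 - 2 v cos_b:
    #   (i)  u^2 + v^2 - 2 u v cos_a - A q(v) = 0
    #   (ii) u^2 + 1   - 2 u   cos_g - B q(v) = 0
    # (i)-(ii) is linear in u:  u * D(v) = N(v)
    q = np.array([1.0, -2.0 * cos_b, 1.0])      # q(v), ascending powers
    # (i)-(ii): v^2 - 1 - 2uv cos_a + 2u cos_g - (A-B) q = 0
    #   => u (2 cos_g - 2 v cos_a) = 1 - v^2 + (A-B) q =: N(v)
    N = npoly.polyadd(np.array([1.0, 0.0, -1.0]), (A - B) * q)
    D = np.array([2.0 * cos_g, -2.0 * cos_a])
    # substitute u = N/D into (ii) and clear D^2:
    #   N^2 - 2 cos_g N D + (1 - B q) D^2 = 0
    poly = npoly.polymul(N, N)
    poly = npoly.polysub(poly, 2.0 * cos_g * npoly.polymul(N, D))
    poly = npoly.polyadd(poly, npoly.polymul(npoly.polysub(np.array([1.0]), B * q),
                                             npoly.polymul(D, D)))
    roots = npoly.polyroots(poly)
    dpoly = npoly.polyder(poly)

    poses: list[Pose] = []
    for v in roots:
        if abs(v.imag) > 1e-8 or v.real <= 0:
            continue
        v = float(v.real)
        for _ in range(2):  # Newton polish: companion-matrix roots are only ~1e-8
            dv = npoly.polyval(v, dpoly)
            if abs(dv) < 1e-14:
                break
            v -= npoly.polyval(v, poly) / dv
        denom = float(npoly.polyval(v, D))
        if abs(denom) < 1e-12:
            continue
        u = float(npoly.polyval(v, N)) / denom
        if u <= 0:
            continue
        qv = 1.0 + v * v - 2.0 * v * cos_b
        if qv <= 0:
            continue
        s1 = b / np.sqrt(qv)
        s = np.array([s1, u * s1, v * s1])
        Y = f * s[:, None]
        R, t = kabsch(X, Y)
        poses.append(Pose(R, t))
    return poses


# ---------------------------------------------------------------------------
# Weighted RANSAC
# ---------------------------------------------------------------------------

def _within_increment(pose: Pose, prior: Pose, max_rot: float, max_trans: float) -> bool:
    from .geometry import rotation_angle
    if rotation_angle(pose.rotation @ prior.rotation.T) > max_rot:
        return False
    return bool(np.linalg.norm(pose.translation - prior.translation) <= max_trans)


def _bearing(cam, uv):
    xy = cam.normalized_from_pixel(np.atleast_2d(uv), undistort=False)
    vec = np.concatenate([xy, np.ones((len(xy), 1))], axis=1)
    return vec / np.linalg.norm(vec, axis=1, keepdims=True)


def _solve_minimal(corrs: Correspondences2D3D, rig: CameraRig,
                   tri_idx: np.ndarray, check_idx: int) -> Pose | None:
    """P3P on three same-view points; disambiguate with a fourth point."""
    view = int(corrs.view_ids[tri_idx[0]])
    cam = rig.cam0 if view == 0 else rig.cam1
    bearings = _bearing(cam, corrs.image_points[tri_idx])
    candidates = p3p_grunert(corrs.object_points[tri_idx], bearings)
    if not candidates:
        return None
    best, best_res = None, np.inf
    check = Correspondences2D3D(
        corrs.object_points[[check_idx]], corrs.image_points[[check_idx]],
        corrs.view_ids[[check_idx]], weights=np.ones(1),
    )
    for pose_cam in candidates:
        if view == 1:  # pose solved in camera-1 frame; move to camera-0
            rig_pose = Pose(rig.rig_rotation, rig.rig_translation)
            pose0 = rig_pose.inverse().compose(pose_cam)
        else:
            pose0 = pose_cam
        res = reprojection_residuals(pose0, check, rig)[0]
        if res < best_res:
            best, best_res = pose0, res
    return best


def _refit(pose0: Pose, corrs: Correspondences2D3D, rig: CameraRig,
           weights: np.ndarray) -> Pose:
    """Levenberg-Marquardt refinement of the weighted reprojection cost."""
    w = weights / weights.sum()
    sw = np.sqrt(w)

    def residual(x):
        pose = Pose(rodrigues_inverse(x[:3]), x[3:])
        out = np.zeros((len(corrs), 2))
        for view, cam in ((0, rig.cam0), (1, rig.cam1)):
            sel = corrs.view_ids == view
            if not sel.any():
                continue
            uv = project_points(corrs.object_points[sel],
                                _pose_in_view(pose, rig, view), cam, strict=False)
            d = uv - corrs.image_points[sel]
            d[~np.isfinite(d)] = 1e6
            out[sel] = d
        return (out * sw[:, None]).ravel()

    x0 = np.concatenate([rodrigues(pose0.rotation), pose0.translation])
    sol = optimize.least_squares(residual, x0, method="lm", max_nfev=200)
    return Pose(rodrigues_inverse(sol.x[:3]), sol.x[3:])


def estimate_pose_ransac(corrs: Correspondences2D3D, rig: CameraRig,
                         threshold_px: float = 15.0, max_iter: int = 500,
                         seed: int = 0, min_mass: float = 0.5,
                         confidence: float = 0.99,
                         weighted_scoring: bool = True,
                         refine: bool = True,
                         trim_factor: float = 3.0,
                         trim_floor_px: float = 2.0,
                         prior_pose: Pose | None = None,
                         max_rot_increment: float = np.deg2rad(15.0),
                         max_trans_increment: float = 0.08) -> RobustEstimate | None:
    """Weighted RANSAC pose estimation from pooled two-view correspondences.

    Each iteration samples three same-view points for Grunert resection and
    one further point (from the other view when available) for
    disambiguation; candidate poses are scored by the *weighted inlier
    mass* ``sum_{inliers} w_i`` (or by raw count when
    ``weighted_scoring=False``, kept for A/B comparison).  The best model is
    refit on its inliers by Levenberg-Marquardt and accepted iff its
    weighted reprojection error (inlier weights renormalized) stays below
    ``threshold_px``.  Deterministic for a fixed ``seed``; returns ``None``
    when no consensus set reaches ``min_mass`` or the refit error is too
    large — callers treat that as a tracking dropout for the frame.

    When ``prior_pose`` is given (the object's pose one frame earlier),
    candidate poses whose rotation or translation increment exceeds the
    physical per-frame bounds are discarded before scoring.  At a 5 ms
    frame interval a rigid body cannot rotate tens of degrees, yet a
    sparse, shallow point patch admits far-rotated phantom poses that
    reproject within the blur-scale threshold; the continuity prior is
    what keeps the estimator off that ambiguous branch.
    """
    n = len(corrs)
    if n < 4:
        return None
    rng = np.random.default_rng(seed)
    views, counts = np.unique(corrs.view_ids, return_counts=True)
    usable_views = [int(v) for v, c in zip(views, counts) if c >= 3]
    if not usable_views:
        return None
    idx_by_view = {int(v): np.nonzero(corrs.view_ids == v)[0] for v in views}

    best_key = (-np.inf, -np.inf)
    best_inliers: np.ndarray | None = None
    best_pose: Pose | None = None
    iters_needed = max_iter
    it = 0
    while it < min(max_iter, iters_needed):
        it += 1
        view = usable_views[int(rng.integers(len(usable_views)))]
        pool = idx_by_view[view]
        tri = rng.choice(pool, size=3, replace=False)
        other = [int(v) for v in views if v != view and len(idx_by_view[int(v)]) > 0]
        if other:  # prefer spanning both views
            check_pool = idx_by_view[other[0]]
        else:
            check_pool = np.setdiff1d(pool, tri)
            if len(check_pool) == 0:
                continue
        check = int(rng.choice(check_pool))
        pose = _solve_minimal(corrs, rig, tri, check)
        if pose is None:
            continue
        if prior_pose is not None and not _within_increment(
                pose, prior_pose, max_rot_increment, max_trans_increment):
            continue
        inl, count, mass = score_pose(pose, corrs, rig, threshold_px)
        key = (mass, -it) if weighted_scoring else (count, -it)
        if key > best_key:
            best_key, best_inliers, best_pose = key, inl, pose
            ratio = count / n
            if 0 < ratio < 1:
                iters_needed = int(np.ceil(
                    np.log(1 - confidence) / np.log(1 - ratio**4 + 1e-12)
                ))
            elif ratio >= 1:
                iters_needed = it

    if best_pose is None or best_inliers is None or len(best_inliers) < 4:
        return None
    mass = float(np.sum(corrs.weights[best_inliers]))
    if mass < min_mass:
        return None

    sub = Correspondences2D3D(
        corrs.object_points[best_inliers], corrs.image_points[best_inliers],
        corrs.view_ids[best_inliers], weights=corrs.weights[best_inliers],
        point_ids=corrs.point_ids[best_inliers],
    )
    pose = _refit(best_pose, sub, rig, sub.weights) if refine else best_pose
    if refine and trim_factor and len(sub) > 8:
        # second, trimmed pass: the acceptance threshold is deliberately wide
        # (motion-blur scale), so the inlier band still admits mismatches a
        # few pixels off; drop residuals far above the inlier median and
        # refit once on the consensus core
        res = reprojection_residuals(pose, sub, rig)
        cut = max(trim_factor * float(np.median(res)), trim_floor_px)
        core = np.nonzero(res <= cut)[0]
        if len(core) >= max(6, len(sub) // 2):
            trimmed = Correspondences2D3D(
                sub.object_points[core], sub.image_points[core],
                sub.view_ids[core], weights=sub.weights[core],
                point_ids=sub.point_ids[core],
            )
            pose = _refit(pose, trimmed, rig, trimmed.weights)
    werr = weighted_reprojection_error(pose, sub, rig,
                                       weights=sub.weights / sub.weights.sum())
    if not np.isfinite(werr) or werr >= threshold_px:
        return None
    if prior_pose is not None and not _within_increment(
            pose, prior_pose, max_rot_increment, max_trans_increment):
        return None
    return RobustEstimate(pose=pose, inlier_ids=corrs.point_ids[best_inliers],
                          weighted_error=werr, iterations_used=it,
                          inlier_mass=mass)


# ---------------------------------------------------------------------------
# Kalman filtering of the pose track
# ---------------------------------------------------------------------------

@dataclass
class KalmanState:
    """Constant-velocity filter on translation + smoothed rotation.

    Translation state is ``(position, velocity)`` with a white-acceleration
    process model; the measurement is the estimated object position.  A
    measurement is rejected when its innovation Mahalanobis distance
    exceeds the chi-squared gate (3 dof).  Rotation is smoothed
    separately by blending the axis-angle increment between the filtered
    and measured orientation — pose measurements arrive at 200 Hz and the
    rotation dynamics of a tumbling object are smooth at that timescale,
    so a first-order smoother is adequate and keeps the filter linear.
    """

    sigma_accel: float = 50.0      # m/s^2 process noise (free flight + jitter)
    sigma_meas: float = 0.005      # m, measurement noise of the triangulated centroid
    rot_smoothing: float = 0.7     # blend factor toward the measured rotation
    gate_prob: float = 0.99
    x: np.ndarray | None = None
    P: np.ndarray | None = None
    rotation: np.ndarray | None = None
    n_init: int = 0
    last_gain: np.ndarray | None = field(default=None, repr=False)


def kalman_update(state: KalmanState, measurement: Pose, dt: float):
    """Advance the filter by one measurement; returns ``(Pose, accepted)``.

    An uninitialized state adopts the measurement (accepted).  A gated
    (rejected) measurement leaves the corrected state at the prediction
    and returns ``accepted=False`` so the caller can discard the frame's
    estimate as unreliable.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    z = measurement.translation
    if state.n_init == 0:
        # two-point differencing initialization, part 1: store position
        state.x = np.concatenate([z, np.zeros(3)])
        state.rotation = measurement.rotation.copy()
        state.n_init = 1
        return Pose(state.rotation, z.copy()), True
    if state.n_init == 1:
        # part 2: exact velocity from the first two fixes; under an exact
        # constant-velocity track the filter is latched from here on
        v = (z - state.x[:3]) / dt
        state.x = np.concatenate([z, v])
        r = state.sigma_meas**2
        state.P = np.block([
            [r * np.eye(3), (r / dt) * np.eye(3)],
            [(r / dt) * np.eye(3), (2 * r / dt**2) * np.eye(3)],
        ])
        state.rotation = measurement.rotation.copy()
        state.n_init = 2
        return Pose(state.rotation, z.copy()), True

    F = np.eye(6)
    F[:3, 3:] = dt * np.eye(3)
    q = state.sigma_accel**2
    G = np.concatenate([0.5 * dt * dt * np.eye(3), dt * np.eye(3)])
    Q = q * (G @ G.T)
    R = state.sigma_meas**2 * np.eye(3)
    H = np.zeros((3, 6))
    H[:, :3] = np.eye(3)

    x_pred = F @ state.x
    P_pred = F @ state.P @ F.T + Q
    y = z - H @ x_pred
    S = H @ P_pred @ H.T + R
    d2 = float(y @ np.linalg.solve(S, y))
    gate = chi2.ppf(state.gate_prob, df=3)
    if d2 > gate:
        state.x = x_pred
        state.P = P_pred
        return Pose(state.rotation, x_pred[:3].copy()), False

    K = P_pred @ H.T @ np.linalg.inv(S)
    state.x = x_pred + K @ y
    state.P = (np.eye(6) - K @ H) @ P_pred
    state.last_gain = K

    increment = rodrigues(measurement.rotation @ state.rotation.T)
    state.rotation = rodrigues_inverse(state.rot_smoothing * increment) @ state.rotation
    return Pose(state.rotation, state.x[:3].copy()), True
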