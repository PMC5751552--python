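"""Camera models, projection, triangulation and rotation algebra.

Conventions shared by every module in the package:

* pixel coordinates are 0-based, continuous, with the origin at the center
  of the top-left pixel; a point is an ``(u, v)`` pair with ``u`` along the
  image x (column) axis and ``v`` along y (rows);
* 3D points are column 3-vectors ``P = (X, Y, Z)`` expressed either in an
  object-local frame or in the frame of camera 0 (the reference camera);
* a rigid pose ``(R, t)`` maps object-local coordinates into the camera-0
  frame, ``P' = R P + t``;
* rotation angles are reported in ``[0, pi]`` so that error percentages are
  unambiguous.

Lens distortion follows the standard radial-tangential model
``(k1, k2, p1, p2, k3, ...)``.  The pipeline undistorts detections once and
works in undistorted pixel coordinates everywhere downstream, so projection
with an all-zero coefficient vector must (and does) reduce exactly to the
pinhole model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.transform import Rotation as _Rotation

__all__ = [
    "CameraIntrinsics",
    "CameraRig",
    "Pose",
    "PointBehindCameraError",
    "DegenerateGeometryError",
    "project",
    "project_points",
    "triangulate",
    "triangulate_points",
    "rodrigues",
    "rodrigues_inverse",
    "rotation_angle",
    "pose_error_percentage",
    "fundamental_matrix",
    "load_calibration",
    "save_calibration",
]

_ORTHONORMAL_TOL = 1e-9


class PointBehindCameraError(ValueError):
    """A 3D point has non-positive depth in the projecting camera."""


class DegenerateGeometryError(ValueError):
    """Triangulation rays are near-parallel or the rig is degenerate."""


def _check_rotation(R: np.ndarray, tol: float = _ORTHONORMAL_TOL) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=max(tol, 1e-9)):
        raise ValueError("matrix is not orthonormal within tolerance")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation has determinant -1 (reflection)")
    return R


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics ``A = [[fx,0,cx],[0,fy,cy],[0,0,1]]`` plus distortion."""

    fx: float
    fy: float
    cx: float
    cy: float
    distortion: np.ndarray = field(default_factory=lambda: np.zeros(5))

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        d = np.atleast_1d(np.asarray(self.distortion, dtype=float))
        if d.ndim != 1 or d.size > 8:
            raise ValueError("distortion must be a vector of length <= 8")
        object.__setattr__(self, "distortion", d)

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    @property
    def has_distortion(self) -> bool:
        return bool(np.any(self.distortion != 0.0))

    # -- distortion -------------------------------------------------------

    def _distort_normalized(self, xy: np.ndarray) -> np.ndarray:
        d = np.zeros(8)
        d[: self.distortion.size] = self.distortion
        k1, k2, p1, p2, k3, k4, k5, k6 = d
        x, y = xy[..., 0], xy[..., 1]
        r2 = x * x + y * y
        radial = (1 + k1 * r2 + k2 * r2**2 + k3 * r2**3) / (
            1 + k4 * r2 + k5 * r2**2 + k6 * r2**3
        )
        xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
        yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
        return np.stack([xd, yd], axis=-1)

    def pixel_from_normalized(self, xy: np.ndarray, distort: bool = True) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        if distort and self.has_distortion:
            xy = self._distort_normalized(xy)
        out = np.empty_like(xy)
        out[..., 0] = self.fx * xy[..., 0] + self.cx
        out[..., 1] = self.fy * xy[..., 1] + self.cy
        return out

    def normalized_from_pixel(self, uv: np.ndarray, undistort: bool = True,
                              iterations: int = 20) -> np.ndarray:
        """Map pixels to normalized camera coordinates, undoing distortion.

        Undistortion uses fixed-point iteration (the model has no closed-form
        inverse); 20 iterations is far past convergence for moderate
        coefficients.
        """
        uv = np.asarray(uv, dtype=float)
        xy = np.empty_like(uv)
        xy[..., 0] = (uv[..., 0] - self.cx) / self.fx
        xy[..., 1] = (uv[..., 1] - self.cy) / self.fy
        if not (undistort and self.has_distortion):
            return xy
        x0 = xy.copy()
        x = xy.copy()
        for _ in range(iterations):
            delta = self._distort_normalized(x) - x
            x = x0 - delta
        return x

    def undistort_pixels(self, uv: np.ndarray) -> np.ndarray:
        """Return ideal (pinhole) pixel coordinates for observed pixels."""
        return self.pixel_from_normalized(self.normalized_from_pixel(uv), distort=False)


@dataclass(frozen=True)
class CameraRig:
    """Two calibrated cameras; extrinsics map camera-0 frame into camera-1.

    ``X_cam1 = rig_rotation @ X_cam0 + rig_translation`` with the translation
    in world length units (meters throughout this package).
    """

    cam0: CameraIntrinsics
    cam1: CameraIntrinsics
    rig_rotation: np.ndarray
    rig_translation: np.ndarray

    def __post_init__(self):
        R = _check_rotation(self.rig_rotation)
        t = np.asarray(self.rig_translation, dtype=float).reshape(3)
        if np.linalg.norm(t) <= 0:
            raise ValueError("stereo baseline must be non-zero")
        object.__setattr__(self, "rig_rotation", R)
        object.__setattr__(self, "rig_translation", t)

    @property
    def baseline(self) -> float:
        return float(np.linalg.norm(self.rig_translation))

    def projection_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Ideal (distortion-free) 3x4 projection matrices in the cam-0 frame."""
        P0 = self.cam0.matrix @ np.hstack([np.eye(3), np.zeros((3, 1))])
        P1 = self.cam1.matrix @ np.hstack(
            [self.rig_rotation, self.rig_translation.reshape(3, 1)]
        )
        return P0, P1

    def swapped(self) -> "CameraRig":
        """The same physical rig with the camera roles exchanged."""
        R = self.rig_rotation.T
        t = -R @ self.rig_translation
        return CameraRig(self.cam1, self.cam0, R, t)


@dataclass(frozen=True)
class Pose:
    """Rigid transform ``P' = R P + t`` from object-local into camera-0 frame."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = _check_rotation(self.rotation)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def inverse_apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (points - self.translation) @ self.rotation

    def compose(self, other: "Pose") -> "Pose":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return Pose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "Pose":
        return Pose(self.rotation.T, -self.rotation.T @ self.translation)


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

def project_points(points: np.ndarray, pose: Pose, cam: CameraIntrinsics,
                   min_depth: float = 1e-9,
                   strict: bool = True) -> np.ndarray:
    """Project object-local points through ``pose`` into pixel coordinates.

    With ``strict`` (default) a non-positive transformed depth raises
    :class:`PointBehindCameraError`; with ``strict=False`` such points come
    back as ``nan`` rows so that robust estimators can penalize them instead.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    Pc = pose.apply(P)
    Z = Pc[:, 2]
    behind = Z <= min_depth
    if np.any(behind):
        if strict:
            raise PointBehindCameraError(
                f"{int(behind.sum())} point(s) at non-positive depth"
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        xy = Pc[:, :2] / Z[:, None]
    uv = cam.pixel_from_normalized(xy)
    uv[behind] = np.nan
    return uv


def project(point: np.ndarray, pose: Pose, cam: CameraIntrinsics) -> np.ndarray:
    """Single-point convenience wrapper around :func:`project_points`."""
    return project_points(np.asarray(point, dtype=float).reshape(1, 3), pose, cam)[0]


# ---------------------------------------------------------------------------
# Triangulation (homogeneous two-view DLT)
# ---------------------------------------------------------------------------

def triangulate_points(p0: np.ndarray, p1: np.ndarray, rig: CameraRig,
                       min_ray_angle: float = 1e-4,
                       strict: bool = True):
    """Triangulate undistorted pixel correspondences by homogeneous DLT.

    For each correspondence the standard 4x4 linear system from both
    projection matrices is solved by SVD; the result is the algebraic
    least-squares 3D point in the camera-0 frame.  Correspondences whose
    viewing rays subtend less than ``min_ray_angle`` radians are degenerate
    (depth unobservable): with ``strict`` this raises, otherwise those rows
    are returned as ``nan`` and flagged.

    Returns ``(points, residuals, valid)`` where ``residuals`` is an (n, 2)
    array of per-view reprojection error norms in pixels.
    """
    p0 = np.atleast_2d(np.asarray(p0, dtype=float))
    p1 = np.atleast_2d(np.asarray(p1, dtype=float))
    if p0.shape != p1.shape:
        raise ValueError("correspondence arrays must have matching shapes")
    n = p0.shape[0]
    P0, P1 = rig.projection_matrices()

    A = np.empty((n, 4, 4))
    A[:, 0] = p0[:, 0, None] * P0[2] - P0[0]
    A[:, 1] = p0[:, 1, None] * P0[2] - P0[1]
    A[:, 2] = p1[:, 0, None] * P1[2] - P1[0]
    A[:, 3] = p1[:, 1, None] * P1[2] - P1[1]

    _, _, Vt = np.linalg.svd(A)
    Xh = Vt[:, -1, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        X = Xh[:, :3] / Xh[:, 3, None]

    # ray-angle degeneracy test: rays in the cam-0 frame
    r0 = np.concatenate([rig.cam0.normalized_from_pixel(p0, undistort=False),
                         np.ones((n, 1))], axis=1)
    r1c1 = np.concatenate([rig.cam1.normalized_from_pixel(p1, undistort=False),
                           np.ones((n, 1))], axis=1)
    r1 = r1c1 @ rig.rig_rotation  # R^T r
    cosang = np.abs(np.sum(r0 * r1, axis=1)) / (
        np.linalg.norm(r0, axis=1) * np.linalg.norm(r1, axis=1)
    )
    angle = np.arccos(np.clip(cosang, -1.0, 1.0))
    valid = np.isfinite(X).all(axis=1) & (angle >= min_ray_angle)
    if strict and not valid.all():
        raise DegenerateGeometryError(
            f"{int((~valid).sum())} correspondence(s) with near-parallel rays"
        )
    X = np.where(valid[:, None], X, np.nan)

    residuals = np.full((n, 2), np.nan)
    ok = valid & (X[:, 2] > 0)
    if np.any(ok):
        uv0 = project_points(X[ok], Pose.identity(), rig.cam0, strict=False)
        pose1 = Pose(rig.rig_rotation, rig.rig_translation)
        uv1 = project_points(X[ok], pose1, rig.cam1, strict=False)
        residuals[ok, 0] = np.linalg.norm(uv0 - p0[ok], axis=1)
        residuals[ok, 1] = np.linalg.norm(uv1 - p1[ok], axis=1)
    return X, residuals, valid


def triangulate(p0: np.ndarray, p1: np.ndarray, rig: CameraRig,
                min_ray_angle: float = 1e-4):
    """Triangulate a single correspondence; returns ``(point, residuals)``."""
    X, res, _ = triangulate_points(
        np.asarray(p0).reshape(1, 2), np.asarray(p1).reshape(1, 2), rig,
        min_ray_angle=min_ray_angle, strict=True,
    )
    return X[0], res[0]


# ---------------------------------------------------------------------------
# Rotation algebra
# ---------------------------------------------------------------------------

def rodrigues(R: np.ndarray) -> np.ndarray:
    """Axis-angle 3-vector of a rotation matrix; norm = angle in [0, pi]."""
    R = _check_rotation(R, tol=1e-8)
    return _Rotation.from_matrix(R).as_rotvec()


def rodrigues_inverse(rvec: np.ndarray) -> np.ndarray:
    """Rotation matrix from an axis-angle 3-vector."""
    rvec = np.asarray(rvec, dtype=float).reshape(3)
    if not np.all(np.isfinite(rvec)):
        raise ValueError("axis-angle vector must be finite")
    return _Rotation.from_rotvec(rvec).as_matrix()


def rotation_angle(R: np.ndarray) -> float:
    """Rotation angle of ``R`` in radians, in [0, pi]."""
    return float(np.linalg.norm(rodrigues(R)))


def pose_error_percentage(true_prev: Pose, true_curr: Pose,
                          est_prev: Pose, est_curr: Pose,
                          min_true_angle: float = 1e-6) -> float:
    """Orientation-difference error as a fraction of the true rotation angle.

    Let ``R`` be the true orientation change between the two frames and
    ``R*`` the estimated change.  The correction rotation ``R_err`` is
    defined by ``R_err R* = R``; the error measure is the axis-angle norm of
    ``R_err`` divided by the true rotation angle.  Because only orientation
    *differences* enter, the measure is invariant both to a global rotation
    of the world and to a fixed rotation offset between the estimated and
    true object-local frames (the auto-generated local frame is arbitrary).
    """
    R_true = true_curr.rotation @ true_prev.rotation.T
    R_est = est_curr.rotation @ est_prev.rotation.T
    theta_true = rotation_angle(R_true)
    if theta_true < min_true_angle:
        raise ValueError(
            "true rotation angle below threshold: error percentage undefined"
        )
    R_err = R_true @ R_est.T
    return rotation_angle(R_err) / theta_true


# ---------------------------------------------------------------------------
# Epipolar geometry
# ---------------------------------------------------------------------------

def fundamental_matrix(rig: CameraRig) -> np.ndarray:
    """Fundamental matrix mapping view-0 pixels to view-1 epipolar lines.

    ``F = K1^{-T} [t]_x R K0^{-1}`` for ideal (undistorted) pixel
    coordinates; ``l1 = F @ [u0, v0, 1]``.
    """
    t = rig.rig_translation
    if np.linalg.norm(t) <= 0:
        raise DegenerateGeometryError("zero baseline: no epipolar geometry")
    tx = np.array([[0, -t[2], t[1]], [t[2], 0, -t[0]], [-t[1], t[0], 0]])
    E = tx @ rig.rig_rotation
    K0, K1 = rig.cam0.matrix, rig.cam1.matrix
    return np.linalg.inv(K1).T @ E @ np.linalg.inv(K0)


# ---------------------------------------------------------------------------
# Calibration I/O
# ---------------------------------------------------------------------------

def _intrinsics_to_dict(cam: CameraIntrinsics) -> dict:
    return {
        "camera_matrix": cam.matrix.tolist(),
        "dist_coeffs": cam.distortion.tolist(),
    }


def _intrinsics_from_dict(d: dict) -> CameraIntrinsics:
    K = np.asarray(d["camera_matrix"], dtype=float)
    if K.shape != (3, 3):
        raise ValueError("camera_matrix must be 3x3")
    if not (K[0, 1] == 0 and np.allclose(K[2], [0, 0, 1])):
        raise ValueError("camera_matrix must be an upper-triangular intrinsics matrix")
    return CameraIntrinsics(
        fx=float(K[0, 0]), fy=float(K[1, 1]), cx=float(K[0, 2]), cy=float(K[1, 2]),
        distortion=np.asarray(d.get("dist_coeffs", np.zeros(5)), dtype=float),
    )


def save_calibration(rig: CameraRig, path) -> None:
    """Write the rig as YAML (units: meters)."""
    doc = {
        "units": "meters",
        "camera0": _intrinsics_to_dict(rig.cam0),
        "camera1": _intrinsics_to_dict(rig.cam1),
        "stereo": {
            "R": rig.rig_rotation.tolist(),
            "T": rig.rig_translation.tolist(),
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_calibration(path) -> CameraRig:
    """Load and validate a stereo calibration YAML file."""
    doc = yaml.safe_load(Path(path).read_text())
    try:
        cam0 = _intrinsics_from_dict(doc["camera0"])
        cam1 = _intrinsics_from_dict(doc["camera1"])
        stereo = doc["stereo"]
        rig = CameraRig(
            cam0, cam1,
            np.asarray(stereo["R"], dtype=float),
            np.asarray(stereo["T"], dtype=float),
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed calibration file {path}: {exc}") from exc
    return rig
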