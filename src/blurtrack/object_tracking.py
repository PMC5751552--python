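"""Object lifecycle: point-set maintenance, motion-consistency association,
object generation and retirement.

A tracked object is nothing but a sparse set of 3D points, each frozen in
the object-local frame the moment it is accepted (rigidity assumption),
plus per-view binary descriptors that identify the points in new frames.
Because appearance changes with perspective and blur, descriptors are
perishable: they are refreshed from the images every frame a point is
confidently re-observed, and re-synthesized by projecting the point into
the current frames when it is not.

Newly triangulated scene points cannot be assigned to an object from a
single observation — a single point's rigid motion parameters are not
identifiable — so candidates are buffered in a *dummy object* for one
generation cycle.  Once a candidate has two camera-frame positions
``P(t0), P(t1)``, it is tested against every object's frame-to-frame
motion ``dR = R1 R0^-1``, ``dt = t1 - dR t0``: a residual
``|P(t1) - (dR P(t0) + dt)|`` under the alignment threshold assigns the
point to that object.  Leftovers seed new-object generation: the largest
subset consistent with one rigid transform (3D-3D RANSAC with a
Kabsch solver) becomes a new object, provided it is big enough and its
common motion is not the identity — static structure is background by
definition and is left to the background model upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .geometry import CameraRig, Pose, project_points, rotation_angle
from .interest_points import InterestPointSet, hamming_cdist
from .pose_estimation import KalmanState, kabsch

__all__ = [
    "PointStatus",
    "ObjectPoints",
    "TrackedObject",
    "DummyObject",
    "DummyPairs",
    "pair_dummy_cycles",
    "update_object",
    "associate_new_points",
    "generate_object",
    "retire_objects",
]

logger = logging.getLogger(__name__)


class PointStatus(IntEnum):
    HEALTHY = 0
    UNMATCHED = 1
    PENDING_REMOVAL = 2


@dataclass
class ObjectPoints:
    """Struct-of-arrays store for an object's 3D points.

    ``local`` coordinates are fixed once a point is accepted; only the
    descriptors, bookkeeping fields and membership ever change.
    """

    local: np.ndarray
    desc0: np.ndarray
    desc1: np.ndarray
    last_matched: np.ndarray
    residual: np.ndarray
    status: np.ndarray
    last_uv0: np.ndarray = None   # last matched image position per view
    last_uv1: np.ndarray = None   # (nan until first confident match)
    patch0: np.ndarray = None     # canonical appearance templates per view
    patch1: np.ndarray = None     # (nan until captured)
    patch_frame0: np.ndarray = None
    patch_frame1: np.ndarray = None
    born: np.ndarray = None       # frame each point joined the object

    def __post_init__(self):
        n = len(self.local)
        if self.last_uv0 is None:
            self.last_uv0 = np.full((n, 2), np.nan)
        if self.last_uv1 is None:
            self.last_uv1 = np.full((n, 2), np.nan)
        if self.patch_frame0 is None:
            self.patch_frame0 = np.full(n, -1, np.int64)
        if self.patch_frame1 is None:
            self.patch_frame1 = np.full(n, -1, np.int64)
        if self.born is None:
            self.born = self.last_matched.copy()

    def ensure_patches(self, p: int) -> None:
        n = len(self.local)
        if self.patch0 is None or self.patch0.shape[1] != p:
            self.patch0 = np.full((n, p, p), np.nan, np.float32)
            self.patch1 = np.full((n, p, p), np.nan, np.float32)

    @classmethod
    def empty(cls, nbytes: int = 64) -> "ObjectPoints":
        return cls(np.zeros((0, 3)), np.zeros((0, nbytes), np.uint8),
                   np.zeros((0, nbytes), np.uint8), np.zeros(0, np.int64),
                   np.zeros(0), np.zeros(0, np.int8))

    def __len__(self) -> int:
        return len(self.local)

    def take(self, idx) -> "ObjectPoints":
        return ObjectPoints(self.local[idx], self.desc0[idx], self.desc1[idx],
                            self.last_matched[idx], self.residual[idx],
                            self.status[idx], self.last_uv0[idx], self.last_uv1[idx],
                            None if self.patch0 is None else self.patch0[idx],
                            None if self.patch1 is None else self.patch1[idx],
                            self.patch_frame0[idx], self.patch_frame1[idx],
                            self.born[idx])

    def extend(self, local, desc0, desc1, frame: int) -> None:
        k = len(local)
        self.local = np.vstack([self.local, local])
        self.desc0 = np.vstack([self.desc0, desc0])
        self.desc1 = np.vstack([self.desc1, desc1])
        self.last_matched = np.concatenate([self.last_matched, np.full(k, frame, np.int64)])
        self.residual = np.concatenate([self.residual, np.zeros(k)])
        self.status = np.concatenate([self.status, np.zeros(k, np.int8)])
        self.last_uv0 = np.vstack([self.last_uv0, np.full((k, 2), np.nan)])
        self.last_uv1 = np.vstack([self.last_uv1, np.full((k, 2), np.nan)])
        self.patch_frame0 = np.concatenate([self.patch_frame0, np.full(k, -1, np.int64)])
        self.patch_frame1 = np.concatenate([self.patch_frame1, np.full(k, -1, np.int64)])
        self.born = np.concatenate([self.born, np.full(k, frame, np.int64)])
        if self.patch0 is not None:
            p = self.patch0.shape[1]
            pad = np.full((k, p, p), np.nan, np.float32)
            self.patch0 = np.concatenate([self.patch0, pad])
            self.patch1 = np.concatenate([self.patch1, pad])


@dataclass
class TrackedObject:
    """A detected rigid object: identity, point set, pose and filter state."""

    object_id: int
    points: ObjectPoints
    pose: Pose
    birth_frame: int
    pose_history: dict = field(default_factory=dict)   # frame -> Pose
    filter_state: KalmanState = field(default_factory=KalmanState)
    frames_since_seen: int = 0
    tracked_frames: list = field(default_factory=list)

    def record_pose(self, frame: int, pose: Pose) -> None:
        self.pose = pose
        self.pose_history[frame] = pose
        self.tracked_frames.append(frame)
        self.frames_since_seen = 0

    def consistent_subsequences(self) -> list[list[int]]:
        """Maximal runs of consecutive frames with accepted estimates."""
        runs: list[list[int]] = []
        for f in self.tracked_frames:
            if runs and f == runs[-1][-1] + 1:
                runs[-1].append(f)
            else:
                runs.append([f])
        return runs


@dataclass
class DummyObject:
    """Candidate points from the most recent generation cycle (camera frame)."""

    points: np.ndarray
    desc0: np.ndarray
    desc1: np.ndarray
    frame: int = -1

    @classmethod
    def empty(cls, nbytes: int = 64) -> "DummyObject":
        return cls(np.zeros((0, 3)), np.zeros((0, nbytes), np.uint8),
                   np.zeros((0, nbytes), np.uint8))

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class DummyPairs:
    """Dummy points observed in two consecutive cycles: positions at both."""

    p0: np.ndarray        # camera-frame positions at t0
    p1: np.ndarray        # camera-frame positions at t1
    desc0: np.ndarray
    desc1: np.ndarray
    t0: int = -1
    t1: int = -1

    @classmethod
    def empty(cls, nbytes: int = 64) -> "DummyPairs":
        return cls(np.zeros((0, 3)), np.zeros((0, 3)),
                   np.zeros((0, nbytes), np.uint8), np.zeros((0, nbytes), np.uint8))

    def __len__(self) -> int:
        return len(self.p0)

    def take(self, idx) -> "DummyPairs":
        return DummyPairs(self.p0[idx], self.p1[idx], self.desc0[idx],
                          self.desc1[idx], self.t0, self.t1)


def pair_dummy_cycles(prev: DummyObject, curr: DummyObject,
                      max_travel: float = 0.05,
                      max_hamming_frac: float = 0.35,
                      n_bits: int = 512):
    """Match candidates across two generation cycles.

    Mutual-best Hamming matching on the view-0 descriptors, gated by the
    3D distance a point could plausibly travel between cycles
    (``max_travel``, meters).  Returns ``(pairs, unpaired_current_idx)``;
    candidates of the previous cycle that fail to re-appear are discarded
    (a point that cannot be found twice is not trackable evidence).
    """
    if len(prev) == 0 or len(curr) == 0:
        return DummyPairs.empty(), np.arange(len(curr), dtype=np.intp)
    dist = np.linalg.norm(prev.points[:, None, :] - curr.points[None, :, :], axis=2)
    ham = hamming_cdist(prev.desc0, curr.desc0).astype(float)
    ham[dist > max_travel] = np.inf
    ham[ham > max_hamming_frac * n_bits] = np.inf
    best_pc = np.argmin(ham, axis=1)
    best_cp = np.argmin(ham, axis=0)
    ip = np.arange(len(prev))
    mutual = (best_cp[best_pc] == ip) & np.isfinite(ham[ip, best_pc])
    ip = ip[mutual]
    ic = best_pc[mutual]
    pairs = DummyPairs(prev.points[ip], curr.points[ic],
                       curr.desc0[ic], curr.desc1[ic], prev.frame, curr.frame)
    unpaired = np.setdiff1d(np.arange(len(curr), dtype=np.intp), ic)
    return pairs, unpaired


# ---------------------------------------------------------------------------
# Point updating / rejection
# ---------------------------------------------------------------------------

def update_object(obj: TrackedObject, pose: Pose, rig: CameraRig,
                  matches: dict, frames: tuple, extractor,
                  frame_index: int, removal_thresh: float = 15.0,
                  gate_bound: float = 40.0,
                  resynth_unmatched: bool = True,
                  patch_size: int = 15, patch_refresh: int = 15) -> TrackedObject:
    """Refresh, demote or remove object points after an accepted estimate.

    ``matches`` maps view id to ``(TemporalMatches, InterestPointSet)`` for
    that view.  Per view, a matched point's reprojection residual (against
    the *new* pose) decides its fate: within ``removal_thresh`` the
    descriptor is replaced from the image; between ``removal_thresh`` and
    ``gate_bound`` the match is deemed a mismatch and the point demoted to
    unmatched; beyond ``gate_bound`` — unreachable for a correct 3D point,
    since temporal matching only searches a bounded gate — the 3D
    reconstruction itself is bad and the point is removed.  Unmatched
    points get their descriptors re-synthesized by projecting them into
    the current frames; their ``last_matched`` stamp is untouched.
    """
    pts = obj.points
    n = len(pts)
    if n == 0:
        return obj

    proj = {}
    for view, cam in ((0, rig.cam0), (1, rig.cam1)):
        view_pose = pose if view == 0 else Pose(rig.rig_rotation, rig.rig_translation).compose(pose)
        proj[view] = project_points(pts.local, view_pose, cam, strict=False)

    res_by_view = {0: np.full(n, np.nan), 1: np.full(n, np.nan)}
    matched_desc = {0: {}, 1: {}}
    matched_uv = {0: {}, 1: {}}
    for view in (0, 1):
        if view not in matches:
            continue
        tm, new_pts = matches[view]
        if len(tm) == 0:
            continue
        d = np.linalg.norm(tm.target_uv - proj[view][tm.source_idx], axis=1)
        res_by_view[view][tm.source_idx] = d
        for k, s in enumerate(tm.source_idx):
            t = int(tm.target_idx[k])
            # descriptors refresh only from a *detection* that agrees with
            # the final (template-refined) position; template-only matches
            # (t < 0) and far-away detections leave the descriptor alone
            if t >= 0 and np.linalg.norm(new_pts.uv[t] - tm.target_uv[k]) <= 3.0:
                matched_desc[view][int(s)] = new_pts.descriptors[t]
            matched_uv[view][int(s)] = tm.target_uv[k]

    r0, r1 = res_by_view[0], res_by_view[1]
    stacked = np.stack([r0, r1])
    remove = np.any(np.nan_to_num(stacked, nan=-np.inf) > gate_bound, axis=0)
    healthy0 = np.nan_to_num(r0, nan=np.inf) <= removal_thresh
    healthy1 = np.nan_to_num(r1, nan=np.inf) <= removal_thresh
    healthy = (healthy0 | healthy1) & ~remove

    n_removed = int(remove.sum())
    n_demoted = int((~healthy & ~remove & (np.isfinite(r0) | np.isfinite(r1))).sum())
    if n_removed or n_demoted:
        logger.info("object %d frame %d: %d removed, %d demoted",
                    obj.object_id, frame_index, n_removed, n_demoted)

    # descriptor refresh / re-synthesis, anchor bookkeeping, template capture
    h, w = frames[0].shape
    pts.ensure_patches(patch_size)
    hp = patch_size // 2
    for view in (0, 1):
        fresh_needed = []
        last_uv = pts.last_uv0 if view == 0 else pts.last_uv1
        descs = pts.desc0 if view == 0 else pts.desc1
        patches = pts.patch0 if view == 0 else pts.patch1
        patch_frame = pts.patch_frame0 if view == 0 else pts.patch_frame1
        frame = frames[view]
        for i in range(n):
            if remove[i]:
                continue
            view_healthy = (i in matched_uv[view]
                            and res_by_view[view][i] <= removal_thresh)
            if view_healthy:
                uv_i = matched_uv[view][i]
                last_uv[i] = uv_i
                if i in matched_desc[view]:
                    descs[i] = matched_desc[view][i]
                # capture/refresh the canonical appearance template: rarely,
                # so pose error bakes into the anchor only at refresh events
                if (patch_frame[i] < 0
                        or frame_index - patch_frame[i] >= patch_refresh):
                    cx, cy = int(round(uv_i[0])), int(round(uv_i[1]))
                    if hp <= cx < w - hp and hp <= cy < h - hp:
                        patches[i] = frame[cy - hp:cy + hp + 1,
                                           cx - hp:cx + hp + 1]
                        patch_frame[i] = frame_index
            else:
                last_uv[i] = np.nan
                if resynth_unmatched:
                    fresh_needed.append(i)
        if fresh_needed:
            uv = proj[view][fresh_needed]
            inside = np.isfinite(uv).all(axis=1)
            inside &= (uv[:, 0] >= 0) & (uv[:, 0] < w) & (uv[:, 1] >= 0) & (uv[:, 1] < h)
            idx = np.asarray(fresh_needed)[inside]
            if len(idx):
                packed, kept = extractor.extract(frames[view], proj[view][idx])
                tgt = idx[kept]
                if view == 0:
                    pts.desc0[tgt] = packed
                else:
                    pts.desc1[tgt] = packed

    min_res = np.nanmin(np.nan_to_num(stacked, nan=np.inf), axis=0)
    observed = np.isfinite(min_res)
    pts.residual = np.where(observed, min_res, pts.residual)
    pts.status[:] = PointStatus.UNMATCHED
    pts.status[healthy] = PointStatus.HEALTHY
    pts.last_matched[healthy] = frame_index

    keep = ~remove
    obj.points = pts.take(np.nonzero(keep)[0])
    return obj


# ---------------------------------------------------------------------------
# Motion-consistency association
# ---------------------------------------------------------------------------

def object_motion(obj: TrackedObject, t0: int, t1: int):
    """Frame-to-frame motion ``(dR, dt)`` of an object between two frames."""
    if t0 not in obj.pose_history or t1 not in obj.pose_history:
        return None
    P0, P1 = obj.pose_history[t0], obj.pose_history[t1]
    dR = P1.rotation @ P0.rotation.T
    dt = P1.translation - dR @ P0.translation
    return dR, dt


def associate_new_points(pairs: DummyPairs, objects: list[TrackedObject],
                         align_thresh: float = 0.01,
                         footprint_margin: float | None = None,
                         max_points: int | None = None):
    """Assign two-cycle dummy points to motion-consistent objects.

    Each paired point is tested against every object's motion between the
    two cycle frames; the best (minimum-residual) object under
    ``align_thresh`` (meters) receives the point, converted to its local
    frame through the object's current pose.  A point must additionally lie
    inside the object's 3D footprint (bounding radius plus
    ``footprint_margin``, default ``3 * align_thresh``): over one 5 ms
    frame two slow-spinning objects are nearly indistinguishable by motion
    alone, but rigid bodies are compact, so spatial membership is the
    stronger cue.  Unassigned pairs are returned as residue for new-object
    generation.
    """
    n = len(pairs)
    if n == 0:
        return pairs
    if footprint_margin is None:
        footprint_margin = 3.0 * align_thresh
    residuals = np.full((max(len(objects), 1), n), np.inf)
    motions = []
    for k, obj in enumerate(objects):
        m = object_motion(obj, pairs.t0, pairs.t1)
        motions.append(m)
        if m is None:
            continue
        if max_points is not None and len(obj.points) >= max_points:
            continue   # at capacity: more points add cost, not accuracy
        dR, dt = m
        pred = pairs.p0 @ dR.T + dt
        res = np.linalg.norm(pairs.p1 - pred, axis=1)
        if len(obj.points):
            radius = float(np.linalg.norm(obj.points.local, axis=1).max())
            center = obj.pose_history.get(pairs.t1, obj.pose).translation
            inside = np.linalg.norm(pairs.p1 - center, axis=1) <= radius + footprint_margin
            res = np.where(inside, res, np.inf)
        residuals[k] = res

    best_obj = np.argmin(residuals, axis=0)
    best_res = residuals[best_obj, np.arange(n)]
    assigned = best_res < align_thresh

    for k, obj in enumerate(objects):
        sel = np.nonzero(assigned & (best_obj == k))[0]
        if len(sel) == 0:
            continue
        pose = obj.pose_history.get(pairs.t1, obj.pose)
        local = pose.inverse_apply(pairs.p1[sel])
        obj.points.extend(local, pairs.desc0[sel], pairs.desc1[sel], pairs.t1)
        logger.info("object %d: %d point(s) associated by motion consistency",
                    obj.object_id, len(sel))
    return pairs.take(np.nonzero(~assigned)[0])


# ---------------------------------------------------------------------------
# Object generation
# ---------------------------------------------------------------------------

def generate_object(residue: DummyPairs, min_object_points: int = 10,
                    object_id: int = 0, inlier_tol: float = 0.01,
                    min_translation: float = 0.002,
                    min_rotation: float = np.deg2rad(0.1),
                    max_iter: int = 100, seed: int = 0,
                    cluster_link_radius: float = 0.18):
    """Create a new object from rigid-consistent residue points.

    Candidates are first grouped into spatially connected clusters
    (single linkage at ``cluster_link_radius`` meters): over a single 5 ms
    cycle two separate slow-spinning bodies move almost identically, so
    rigid consistency alone would happily fuse them into one phantom
    object, while real rigid objects are spatially compact.  Within the
    largest cluster, a small 3D-3D RANSAC (Kabsch on 3-point samples)
    finds the largest subset whose two-cycle displacement fits a single
    rigid transform; if that subset exceeds ``min_object_points``, a new
    object is born with its origin at the centroid of the subset, identity
    orientation, and local coordinates equal to camera coordinates minus
    the centroid.  Sets whose common motion is indistinguishable from rest
    (below ``min_translation`` meters and ``min_rotation`` radians per
    cycle) are background by definition and never become objects.

    Returns ``(object_or_None, leftover_residue)``.
    """
    n = len(residue)
    if n <= min_object_points:
        return None, residue

    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial import cKDTree
    tree = cKDTree(residue.p1)
    pairs_idx = tree.query_pairs(cluster_link_radius, output_type="ndarray")
    adj = csr_matrix((np.ones(len(pairs_idx)), (pairs_idx[:, 0], pairs_idx[:, 1])),
                     shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    main = int(np.argmax(sizes))
    cluster = np.nonzero(labels == main)[0]
    if len(cluster) <= min_object_points:
        return None, residue
    if len(cluster) < n:
        rest = residue.take(np.setdiff1d(np.arange(n), cluster))
        obj, leftover = generate_object(
            residue.take(cluster), min_object_points, object_id, inlier_tol,
            min_translation, min_rotation, max_iter, seed, cluster_link_radius)
        merged = DummyPairs(
            np.vstack([leftover.p0, rest.p0]), np.vstack([leftover.p1, rest.p1]),
            np.vstack([leftover.desc0, rest.desc0]),
            np.vstack([leftover.desc1, rest.desc1]),
            residue.t0, residue.t1)
        return obj, merged

    rng = np.random.default_rng(seed)
    best_inliers = None
    for _ in range(max_iter):
        tri = rng.choice(n, size=3, replace=False)
        R, t = kabsch(residue.p0[tri], residue.p1[tri])
        err = np.linalg.norm(residue.p1 - (residue.p0 @ R.T + t), axis=1)
        inl = np.nonzero(err < inlier_tol)[0]
        if best_inliers is None or len(inl) > len(best_inliers):
            best_inliers = inl
    if best_inliers is None or len(best_inliers) <= min_object_points:
        return None, residue
    R, t = kabsch(residue.p0[best_inliers], residue.p1[best_inliers])
    err = np.linalg.norm(residue.p1 - (residue.p0 @ R.T + t), axis=1)
    inliers = np.nonzero(err < inlier_tol)[0]
    if len(inliers) <= min_object_points:
        return None, residue

    net_translation = np.linalg.norm(
        residue.p1[inliers].mean(axis=0) - residue.p0[inliers].mean(axis=0))
    if net_translation < min_translation and rotation_angle(R) < min_rotation:
        logger.info("rigid-consistent set rejected as static background (%d points)",
                    len(inliers))
        return None, residue.take(np.setdiff1d(np.arange(n), inliers))

    sub = residue.take(inliers)
    centroid = sub.p1.mean(axis=0)
    points = ObjectPoints(
        local=sub.p1 - centroid,
        desc0=sub.desc0.copy(), desc1=sub.desc1.copy(),
        last_matched=np.full(len(sub), residue.t1, np.int64),
        residual=np.zeros(len(sub)),
        status=np.zeros(len(sub), np.int8),
    )
    obj = TrackedObject(object_id=object_id, points=points,
                        pose=Pose(np.eye(3), centroid), birth_frame=residue.t1)
    obj.record_pose(residue.t1, obj.pose)
    logger.info("object %d generated with %d points at frame %d",
                object_id, len(sub), residue.t1)
    return obj, residue.take(np.setdiff1d(np.arange(n), inliers))


def retire_objects(objects: list[TrackedObject], max_unseen_frames: int = 20,
                   stillborn_after: int = 5, current_frame: int | None = None,
                   min_recent_fraction: float = 0.5, recent_window: int = 30):
    """Drop objects unseen for too long; returns ``(active, retired)``.

    Two additional hygiene rules: an object that never achieved a pose
    estimate beyond its birth frame is retired after ``stillborn_after``
    consecutive failures, and (when ``current_frame`` is given) an object
    older than ``recent_window`` frames that was tracked in fewer than
    ``min_recent_fraction`` of the last ``recent_window`` frames is retired
    as well.  Such objects come from marginal, noise-contaminated candidate
    sets; holding on to them only blocks the generation of a viable
    replacement covering the same structure.
    """
    active, retired = [], []
    for obj in objects:
        stillborn = (len(obj.tracked_frames) <= 1
                     and obj.frames_since_seen >= stillborn_after)
        poor = False
        if current_frame is not None and current_frame - obj.birth_frame >= recent_window:
            recent = sum(fr > current_frame - recent_window for fr in obj.tracked_frames)
            poor = recent < min_recent_fraction * recent_window
        if stillborn or poor or obj.frames_since_seen > max_unseen_frames:
            retired.append(obj)
            logger.info("object %d retired after %d unseen frames (last pose t=%s)",
                        obj.object_id, obj.frames_since_seen,
                        np.array2string(obj.pose.translation, precision=4))
        else:
            active.append(obj)
    return active, retired
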