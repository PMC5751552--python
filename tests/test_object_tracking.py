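"""Object lifecycle tests: point updating, association, generation, retirement."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from blurtrack.geometry import CameraIntrinsics, CameraRig, Pose, project_points
from blurtrack.interest_points import DescriptorExtractor, InterestPointSet
from blurtrack.correspondence import match_temporal
from blurtrack.object_tracking import (
    DummyObject,
    DummyPairs,
    ObjectPoints,
    PointStatus,
    TrackedObject,
    associate_new_points,
    generate_object,
    object_motion,
    pair_dummy_cycles,
    retire_objects,
    update_object,
)


@pytest.fixture
def rig():
    cam = CameraIntrinsics(fx=1200, fy=1200, cx=256, cy=256)
    R = Rotation.from_euler("y", -12, degrees=True).as_matrix()
    return CameraRig(cam, cam, R, np.array([-0.5, 0.0, 0.1]))


def make_object(local, object_id=0, pose=None, frame=0, nbytes=64, rng=None):
    rng = rng or np.random.default_rng(0)
    n = len(local)
    pts = ObjectPoints(
        local=np.asarray(local, float),
        desc0=rng.integers(0, 256, (n, nbytes)).astype(np.uint8),
        desc1=rng.integers(0, 256, (n, nbytes)).astype(np.uint8),
        last_matched=np.zeros(n, np.int64),
        residual=np.zeros(n),
        status=np.zeros(n, np.int8),
    )
    obj = TrackedObject(object_id=object_id, points=pts,
                        pose=pose or Pose(np.eye(3), [0, 0, 2.0]), birth_frame=frame)
    obj.record_pose(frame, obj.pose)
    return obj


class TestUpdateObject:
    def _setup(self, rig, rng, n=8):
        local = rng.normal(0, 0.1, (n, 3))
        obj = make_object(local, rng=rng)
        pose = obj.pose
        frames = (rng.integers(0, 255, (512, 512)).astype(float),
                  rng.integers(0, 255, (512, 512)).astype(float))
        ext = DescriptorExtractor()
        return obj, pose, frames, ext

    def _matches_for(self, obj, pose, rig, view, uv_override=None, rng=None):
        cam = rig.cam0 if view == 0 else rig.cam1
        vpose = pose if view == 0 else Pose(rig.rig_rotation, rig.rig_translation).compose(pose)
        uv = project_points(obj.points.local, vpose, cam, strict=False)
        if uv_override is not None:
            uv = uv_override(uv)
        n = len(uv)
        desc = rng.integers(0, 256, (n, 64)).astype(np.uint8)
        new_pts = InterestPointSet(uv, desc, np.ones(n), view_id=view)
        tm = match_temporal(uv, desc, new_pts, gate_radius=40.0)
        return tm, new_pts

    def test_zero_residual_pure_descriptor_refresh(self, rig):
        rng = np.random.default_rng(1)
        obj, pose, frames, ext = self._setup(rig, rng)
        n = len(obj.points)
        tm0, np0 = self._matches_for(obj, pose, rig, 0, rng=rng)
        tm1, np1 = self._matches_for(obj, pose, rig, 1, rng=rng)
        update_object(obj, pose, rig, {0: (tm0, np0), 1: (tm1, np1)},
                      frames, ext, frame_index=1)
        assert len(obj.points) == n
        assert np.all(obj.points.status == PointStatus.HEALTHY)
        assert np.all(obj.points.last_matched == 1)
        # descriptors replaced by those of the matched image points
        assert np.array_equal(obj.points.desc0, np0.descriptors[tm0.target_idx])

    def test_bad_reconstruction_removed(self, rig):
        """A point whose residual exceeds the gate bound has bad 3D coords."""
        rng = np.random.default_rng(2)
        obj, pose, frames, ext = self._setup(rig, rng)
        n = len(obj.points)
        corrupted = 3
        obj.points.local[corrupted] += [0.12, 0.0, 0.0]  # ~60 px wrong at fx=1200, z=2
        true_local = obj.points.local.copy()
        true_local[corrupted] -= [0.12, 0.0, 0.0]

        def observe(view):
            cam = rig.cam0 if view == 0 else rig.cam1
            vpose = pose if view == 0 else Pose(rig.rig_rotation, rig.rig_translation).compose(pose)
            uv = project_points(true_local, vpose, cam, strict=False)
            desc = rng.integers(0, 256, (n, 64)).astype(np.uint8)
            new_pts = InterestPointSet(uv, desc, np.ones(n), view_id=view)
            pred = project_points(obj.points.local, vpose, cam, strict=False)
            return match_temporal(pred, desc, new_pts, gate_radius=80.0), new_pts

        m0, p0 = observe(0)
        m1, p1 = observe(1)
        update_object(obj, pose, rig, {0: (m0, p0), 1: (m1, p1)}, frames, ext,
                      frame_index=1, removal_thresh=15.0, gate_bound=40.0)
        assert len(obj.points) == n - 1

    def test_swapped_match_demoted_not_removed(self, rig):
        """Residual between removal threshold and gate bound -> mismatch."""
        rng = np.random.default_rng(3)
        obj, pose, frames, ext = self._setup(rig, rng)
        n = len(obj.points)

        def shift(uv):
            out = uv.copy()
            out[2] += [18.0, 0.0]  # matched image point 18 px off (thresh 15, gate 40)
            return out

        m0, p0 = self._matches_for(obj, pose, rig, 0, uv_override=shift, rng=rng)
        m1, p1 = self._matches_for(obj, pose, rig, 1, rng=rng)
        # force view-1 residual of point 2 to also be a mismatch by dropping it
        keep = m1.source_idx != 2
        from blurtrack.correspondence import TemporalMatches
        m1 = TemporalMatches(m1.source_idx[keep], m1.target_idx[keep],
                             m1.hamming[keep], m1.pixel_offset[keep],
                             np.array([2], np.intp), m1.target_uv[keep])
        update_object(obj, pose, rig, {0: (m0, p0), 1: (m1, p1)}, frames, ext,
                      frame_index=1, removal_thresh=15.0, gate_bound=40.0)
        assert len(obj.points) == n           # not removed
        assert obj.points.status[2] == PointStatus.UNMATCHED

    def test_unmatched_points_get_fresh_descriptors(self, rig):
        rng = np.random.default_rng(4)
        obj, pose, frames, ext = self._setup(rig, rng)
        old0 = obj.points.desc0.copy()
        empty = InterestPointSet.empty()
        from blurtrack.correspondence import match_temporal as mt
        tm = mt(np.zeros((0, 2)), np.zeros((0, 64), np.uint8), empty)
        update_object(obj, pose, rig, {0: (tm, empty), 1: (tm, empty)},
                      frames, ext, frame_index=5)
        assert np.all(obj.points.status == PointStatus.UNMATCHED)
        assert np.all(obj.points.last_matched == 0)  # stamp untouched
        assert not np.array_equal(obj.points.desc0, old0)  # re-synthesized


class TestAssociation:
    def _moving_object(self, rng, omega_deg=3.0, v=np.array([0.02, 0.0, 0.0])):
        obj = make_object(rng.normal(0, 0.1, (12, 3)), rng=rng)
        R0, t0 = obj.pose.rotation, obj.pose.translation
        dR = Rotation.from_euler("z", omega_deg, degrees=True).as_matrix()
        pose1 = Pose(dR @ R0, dR @ t0 + v)
        obj.record_pose(1, pose1)
        return obj

    def test_exact_rigid_motion_assigned(self, rng=np.random.default_rng(5)):
        obj = self._moving_object(rng)
        dR, dt = object_motion(obj, 0, 1)
        p0 = rng.normal(0, 0.1, (5, 3)) + [0, 0, 2.0]
        p1 = p0 @ dR.T + dt
        nb = 64
        pairs = DummyPairs(p0, p1,
                           rng.integers(0, 256, (5, nb)).astype(np.uint8),
                           rng.integers(0, 256, (5, nb)).astype(np.uint8), 0, 1)
        n_before = len(obj.points)
        residue = associate_new_points(pairs, [obj], align_thresh=0.01, footprint_margin=10.0)
        assert len(residue) == 0
        assert len(obj.points) == n_before + 5

    def test_wrong_object_motion_rejected(self, rng=np.random.default_rng(6)):
        obj_b = self._moving_object(rng, omega_deg=-10.0, v=np.array([-0.05, 0.03, 0.0]))
        # points moving with a *different* rigid motion
        dR = Rotation.from_euler("x", 6, degrees=True).as_matrix()
        dt = np.array([0.04, 0.0, 0.01])
        p0 = rng.normal(0, 0.1, (6, 3)) + [0, 0, 2.0]
        p1 = p0 @ dR.T + dt
        nb = 64
        pairs = DummyPairs(p0, p1,
                           rng.integers(0, 256, (6, nb)).astype(np.uint8),
                           rng.integers(0, 256, (6, nb)).astype(np.uint8), 0, 1)
        n_before = len(obj_b.points)
        residue = associate_new_points(pairs, [obj_b], align_thresh=0.01, footprint_margin=10.0)
        assert len(residue) == 6
        assert len(obj_b.points) == n_before

    def test_local_coords_roundtrip(self, rng=np.random.default_rng(7)):
        obj = self._moving_object(rng)
        dR, dt = object_motion(obj, 0, 1)
        p0 = rng.normal(0, 0.1, (4, 3)) + [0, 0, 2.0]
        p1 = p0 @ dR.T + dt
        nb = 64
        pairs = DummyPairs(p0, p1,
                           rng.integers(0, 256, (4, nb)).astype(np.uint8),
                           rng.integers(0, 256, (4, nb)).astype(np.uint8), 0, 1)
        n_before = len(obj.points)
        associate_new_points(pairs, [obj], align_thresh=0.01, footprint_margin=10.0)
        added_local = obj.points.local[n_before:]
        pose1 = obj.pose_history[1]
        recon = pose1.apply(added_local)
        assert np.abs(recon - p1).max() < 1e-9


class TestPairDummyCycles:
    def test_mutual_best_with_travel_gate(self):
        rng = np.random.default_rng(8)
        n = 10
        pts = rng.normal(0, 0.2, (n, 3)) + [0, 0, 2.0]
        desc = rng.integers(0, 256, (n, 64)).astype(np.uint8)
        prev = DummyObject(pts, desc, desc.copy(), frame=0)
        curr = DummyObject(pts + [0.01, 0, 0], desc.copy(), desc.copy(), frame=1)
        pairs, unpaired = pair_dummy_cycles(prev, curr, max_travel=0.05)
        assert len(pairs) == n and len(unpaired) == 0
        assert np.allclose(pairs.p1 - pairs.p0, [0.01, 0, 0])

    def test_travel_gate_blocks_far_jumps(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 0.2, (5, 3)) + [0, 0, 2.0]
        desc = rng.integers(0, 256, (5, 64)).astype(np.uint8)
        prev = DummyObject(pts, desc, desc.copy(), frame=0)
        curr = DummyObject(pts + [0.5, 0, 0], desc.copy(), desc.copy(), frame=1)
        pairs, unpaired = pair_dummy_cycles(prev, curr, max_travel=0.05)
        assert len(pairs) == 0 and len(unpaired) == 5


class TestGenerateObject:
    def _pairs(self, rng, n, dR, dt, center, spread=0.15, nbytes=64):
        p0 = rng.normal(0, spread, (n, 3)) + center
        p1 = p0 @ np.asarray(dR).T + dt
        return p0, p1

    def test_coherent_set_becomes_object_with_centroid_origin(self):
        rng = np.random.default_rng(10)
        dR = Rotation.from_euler("y", 4, degrees=True).as_matrix()
        dt = np.array([0.03, -0.01, 0.0])
        p0, p1 = self._pairs(rng, 30, dR, dt, [0, 0, 2.0])
        pairs = DummyPairs(p0, p1,
                           rng.integers(0, 256, (30, 64)).astype(np.uint8),
                           rng.integers(0, 256, (30, 64)).astype(np.uint8), 0, 1)
        obj, residue = generate_object(pairs, min_object_points=10, object_id=7, seed=1,
                                       cluster_link_radius=10.0)
        assert obj is not None and len(obj.points) == 30 and len(residue) == 0
        assert np.allclose(obj.pose.translation, p1.mean(axis=0))
        assert np.allclose(obj.pose.rotation, np.eye(3))
        assert np.allclose(obj.points.local, p1 - p1.mean(axis=0))

    def test_scattered_minority_left_in_residue(self):
        rng = np.random.default_rng(11)
        dR = Rotation.from_euler("y", 4, degrees=True).as_matrix()
        dt = np.array([0.03, -0.01, 0.0])
        p0, p1 = self._pairs(rng, 30, dR, dt, [0, 0, 2.0])
        s0 = rng.normal(0, 0.3, (8, 3)) + [0, 0, 2.0]
        s1 = s0 + rng.normal(0, 0.1, (8, 3))  # incoherent displacements
        P0, P1 = np.vstack([p0, s0]), np.vstack([p1, s1])
        pairs = DummyPairs(P0, P1,
                           rng.integers(0, 256, (38, 64)).astype(np.uint8),
                           rng.integers(0, 256, (38, 64)).astype(np.uint8), 0, 1)
        obj, residue = generate_object(pairs, min_object_points=10, seed=2,
                                       cluster_link_radius=10.0)
        assert obj is not None and len(obj.points) == 30
        assert len(residue) == 8

    def test_below_threshold_no_object(self):
        rng = np.random.default_rng(12)
        dR = Rotation.from_euler("y", 4, degrees=True).as_matrix()
        p0, p1 = self._pairs(rng, 5, dR, [0.03, 0, 0], [0, 0, 2.0])
        pairs = DummyPairs(p0, p1,
                           rng.integers(0, 256, (5, 64)).astype(np.uint8),
                           rng.integers(0, 256, (5, 64)).astype(np.uint8), 0, 1)
        obj, residue = generate_object(pairs, min_object_points=10, seed=3)
        assert obj is None and len(residue) == 5

    def test_static_set_rejected_as_background(self):
        """Rigid-consistent but motionless structure never becomes an object."""
        rng = np.random.default_rng(13)
        p0 = rng.normal(0, 0.2, (30, 3)) + [0, 0, 2.0]
        p1 = p0 + rng.normal(0, 1e-4, p0.shape)  # triangulation noise only
        pairs = DummyPairs(p0, p1,
                           rng.integers(0, 256, (30, 64)).astype(np.uint8),
                           rng.integers(0, 256, (30, 64)).astype(np.uint8), 0, 1)
        obj, _ = generate_object(pairs, min_object_points=10, seed=4)
        assert obj is None


class TestRetirement:
    def test_continuously_seen_never_retired(self):
        obj = make_object(np.random.default_rng(14).normal(0, 0.1, (12, 3)))
        for f in range(1, 50):
            obj.record_pose(f, obj.pose)
        active, retired = retire_objects([obj], max_unseen_frames=20)
        assert active == [obj] and retired == []

    def test_long_unseen_retired(self):
        obj = make_object(np.random.default_rng(15).normal(0, 0.1, (12, 3)))
        obj.frames_since_seen = 21
        active, retired = retire_objects([obj], max_unseen_frames=20)
        assert active == [] and retired == [obj]

    def test_consistent_subsequences_split_on_gaps(self):
        obj = make_object(np.random.default_rng(16).normal(0, 0.1, (12, 3)))
        for f in [1, 2, 3, 7, 8, 20]:
            obj.record_pose(f, obj.pose)
        runs = obj.consistent_subsequences()
        assert runs == [[0, 1, 2, 3], [7, 8], [20]]


class TestFootprintGate:
    def test_point_outside_footprint_not_associated(self):
        """A motion-consistent point far outside the object's bounding
        radius stays in the residue (compactness cue)."""
        rng = np.random.default_rng(30)
        obj = make_object(rng.normal(0, 0.05, (12, 3)), rng=rng)
        dR = Rotation.from_euler("z", 3, degrees=True).as_matrix()
        pose1 = Pose(dR @ obj.pose.rotation, dR @ obj.pose.translation + [0.02, 0, 0])
        obj.record_pose(1, pose1)
        from blurtrack.object_tracking import object_motion
        dRm, dtm = object_motion(obj, 0, 1)
        p0 = np.array([[1.5, 0.0, 2.0]])     # 1.5 m away from the object
        p1 = p0 @ dRm.T + dtm                # yet perfectly motion-consistent
        pairs = DummyPairs(p0, p1,
                           rng.integers(0, 256, (1, 64)).astype(np.uint8),
                           rng.integers(0, 256, (1, 64)).astype(np.uint8), 0, 1)
        residue = associate_new_points(pairs, [obj], align_thresh=0.01)
        assert len(residue) == 1 and len(obj.points) == 12


class TestClusterSeparation:
    def test_two_separated_clouds_yield_one_compact_object(self):
        """Two spatially distant clouds sharing (near-identical) motion must
        not fuse: generation returns the larger cloud only."""
        rng = np.random.default_rng(31)
        dR = Rotation.from_euler("y", 2, degrees=True).as_matrix()
        dt = np.array([0.02, -0.01, 0.0])
        a0 = rng.normal(0, 0.12, (25, 3)) + [-0.6, 0, 2.0]
        b0 = rng.normal(0, 0.12, (15, 3)) + [0.6, 0, 2.0]
        P0 = np.vstack([a0, b0])
        P1 = P0 @ dR.T + dt
        pairs = DummyPairs(P0, P1,
                           rng.integers(0, 256, (40, 64)).astype(np.uint8),
                           rng.integers(0, 256, (40, 64)).astype(np.uint8), 0, 1)
        obj, residue = generate_object(pairs, min_object_points=10, seed=5)
        assert obj is not None and len(obj.points) == 25
        assert len(residue) == 15
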