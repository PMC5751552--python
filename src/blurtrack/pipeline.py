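"""Per-frame orchestration of the full tracking pipeline, configuration and
evaluation reports.

Each synchronized frame pair passes through a fixed stage order:

1. interest-point detection in both views (background model update,
   gradient-thresholded candidates, descriptors, feature-space
   verification);
2. temporal matching of every existing object's points against the new
   detections;
3. per-object weighted-RANSAC pose estimation, optional Kalman step, and
   point-set update;
4. motion-consistency association of buffered dummy points to objects;
5. new-object generation from the unassigned residue;
6. construction of the next dummy object from the leftover interest
   points (those not consumed by temporal matching) via stereo matching,
   displacement filtering and triangulation.

The stage log records this order per frame so it can be asserted.

Evaluation compares estimated against true orientation *differences* over
a 20-frame lag inside each consistent subsequence (a maximal run of
frames in which an object keeps an accepted estimate), exactly the metric
a ground-truth renderer makes available; positions are reported as
centroid trajectories in camera-0 coordinates.  The auto-generated object
origin is biased away from the true center of mass by construction, so
absolute position error against a reference trajectory is *not* a
meaningful quantity and is never reported — reprojection error per view
serves as the position-quality proxy instead.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .correspondence import (
    TemporalMatches,
    filter_displacement_map,
    match_stereo,
    match_temporal,
    reconstruct_candidates,
    refine_subpixel,
    track_templates,
)
from .geometry import CameraRig, Pose, pose_error_percentage, project_points, rodrigues
from .interest_points import (
    BackgroundModel,
    DescriptorExtractor,
    InterestPointSet,
    compute_descriptors,
    detect_candidates,
    update_background,
    verify_interest_points,
)
from .object_tracking import (
    DummyObject,
    DummyPairs,
    TrackedObject,
    associate_new_points,
    generate_object,
    pair_dummy_cycles,
    retire_objects,
    update_object,
)
from .pose_estimation import (
    Correspondences2D3D,
    KalmanState,
    estimate_pose_ransac,
    kalman_update,
)

__all__ = [
    "RunConfig",
    "FramePairResult",
    "EvaluationReport",
    "Tracker",
    "evaluate_run",
    "STAGE_ORDER",
]

logger = logging.getLogger(__name__)


def _disk(r: int) -> np.ndarray:
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (xx * xx + yy * yy) <= r * r


STAGE_ORDER = (
    "detect",
    "temporal_match",
    "estimate_update",
    "associate",
    "generate",
    "new_dummy",
)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline parameters with their documented defaults.

    Serializes losslessly to/from YAML.  ``gate_radius`` is calibrated for
    200 fps and is scaled by ``200 / frame_rate`` at run time: halving the
    frame rate doubles the inter-frame travel the gate must cover.
    """

    # detection
    alpha: float = 0.05
    det_radius: int = 7
    verify_radius: float = 7.0
    dthresh: float = 0.02
    # background model
    bg_learning_rate: float = 0.05
    bg_k: float = 3.0
    bg_std_floor: float = 4.0
    bg_initial_std: float = 20.0
    bg_absorb_after: int = 60
    # descriptors
    n_bits: int = 512
    patch_size: int = 25
    desc_sigma: float = 1.0
    pattern_seed: int = 20
    # matching
    gate_radius: float = 40.0
    max_hamming_frac: float = 0.5
    epi_tol: float = 3.0
    disp_window: float = 31.0
    jump_factor: float = 4.0
    # robust estimation
    threshold_px: float = 15.0
    max_iter: int = 500
    min_mass: float = 0.5
    confidence: float = 0.99
    seed: int = 0
    # object lifecycle
    min_object_points: int = 10
    max_object_points: int = 1000
    removal_thresh: float = 15.0
    gate_bound: float = 40.0
    align_thresh: float | None = None   # None -> 3x median triangulation noise
    rigid_tol: float | None = None      # None -> 2x median triangulation noise
    sigma_px: float = 1.0               # assumed image localization noise
    max_travel: float = 0.06
    max_unseen_frames: int = 20
    residue_grace: int = 1
    resynth_unmatched: bool = True
    accrete_points: bool = True
    # stereo-anchored drift correction: fraction of the fresh-triangulation
    # registration discrepancy blended into the pose each frame (0 disables)
    drift_correction: float = 1.0
    drift_correction_max_deg: float = 5.0
    # smoothing of the per-frame registration measurement: the Kabsch fit on
    # one frame's fresh triangulations is noisy (~0.5-1 deg); drift is slow,
    # so an exponential average trades response time for far less injected
    # wander, which is what the orientation-difference metric penalizes
    drift_ewma: float = 0.3
    age_weighting: bool = False
    # sub-pixel refinement of matched positions
    subpixel_refine: bool = True
    refine_patch: int = 15
    refine_search: int = 3
    # per-point canonical-template tracking (the identity anchor)
    template_track: bool = True
    template_search: int = 5
    template_min_score: float = 0.5
    patch_refresh: int = 10
    mask_close_radius: int = 5
    # optionally keep candidates only this many pixels inside the foreground
    # boundary (silhouette detections do not move with the surface); off by
    # default — the candidate starvation costs more than the bias saved
    mask_erode_radius: int = 0
    # pose continuity (per-frame physical bounds at 200 fps); the bound must
    # sit well above the estimator's frame-to-frame jitter yet far below the
    # ~180-degree phantom-pose ambiguity it exists to exclude
    max_rot_increment_deg: float = 10.0
    max_trans_increment: float = 0.04
    tie_margin_bits: int = 8
    # Kalman filter
    use_kalman: bool = True
    sigma_accel: float = 50.0
    sigma_meas: float = 0.005
    rot_smoothing: float = 0.7
    kalman_gate_prob: float = 0.99
    # timing
    frame_rate: float = 200.0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    @property
    def effective_gate_radius(self) -> float:
        return self.gate_radius * 200.0 / self.frame_rate


# ---------------------------------------------------------------------------
# Per-frame result record
# ---------------------------------------------------------------------------

@dataclass
class FramePairResult:
    frame_index: int
    n_interest_points: tuple
    n_stereo: int = 0
    n_candidates: int = 0
    estimates: dict = field(default_factory=dict)       # obj_id -> RobustEstimate
    reprojection: dict = field(default_factory=dict)    # obj_id -> {view: mean px}
    filtered_flags: dict = field(default_factory=dict)  # obj_id -> Kalman accepted
    events: list = field(default_factory=list)
    stages: tuple = STAGE_ORDER


# ---------------------------------------------------------------------------
# The tracker
# ---------------------------------------------------------------------------

class Tracker:
    """Stateful multi-object tracker over a calibrated stereo sequence."""

    def __init__(self, rig: CameraRig, config: RunConfig | None = None):
        self.rig = rig
        self.config = config or RunConfig()
        c = self.config
        self.models = [
            BackgroundModel(learning_rate=c.bg_learning_rate, k=c.bg_k,
                            std_floor=c.bg_std_floor, initial_std=c.bg_initial_std,
                            absorb_after=c.bg_absorb_after)
            for _ in (0, 1)
        ]
        self.extractor = DescriptorExtractor(
            n_bits=c.n_bits, patch_size=c.patch_size,
            sigma=c.desc_sigma, pattern_seed=c.pattern_seed,
        )
        self.objects: list[TrackedObject] = []
        self.retired: list[TrackedObject] = []
        self.dummy = DummyObject.empty(c.n_bits // 8)
        self.dummy_ages = np.zeros(0, np.int64)
        self.next_object_id = 0
        self.frame_index = -1
        self.prev_frames = None
        self.masks = [None, None]
        self.prev_masks = [None, None]
        self._corr_ewma: dict = {}
        self.results: list[FramePairResult] = []

    # -- stage 1: detection ------------------------------------------------

    def _detect(self, img, view: int) -> InterestPointSet:
        c = self.config
        frame = np.asarray(img, dtype=float)
        model = update_background(self.models[view], frame)
        mask = model.foreground_mask
        if mask is None or not mask.any():
            self.masks[view] = None
            return InterestPointSet.empty(view, self.frame_index, c.n_bits)
        if c.mask_close_radius:
            # fill interior holes where object and background intensities
            # happen to agree; the closed mask also weights the sub-pixel
            # correlation so static background cannot anchor rim points
            mask = ndimage.binary_closing(mask, structure=_disk(c.mask_close_radius))
        self.masks[view] = mask
        detect_mask = mask
        if c.mask_erode_radius:
            solid = ndimage.binary_fill_holes(mask)
            detect_mask = ndimage.binary_erosion(solid, structure=_disk(c.mask_erode_radius))
            if not detect_mask.any():
                detect_mask = mask   # object too small to erode: keep the rim
        uv, gmag = detect_candidates(frame, detect_mask, alpha=c.alpha, radius=c.det_radius)
        pts = compute_descriptors(frame, uv, gmag, self.extractor,
                                  view_id=view, frame_index=self.frame_index)
        return verify_interest_points(pts, radius=c.verify_radius, dthresh=c.dthresh)

    # -- stage 3 helper: one object's estimate ------------------------------

    def _estimate_object(self, obj: TrackedObject, points, frames):
        c = self.config
        matches = {}
        obj_pts, img_pts, view_ids, pt_rows = [], [], [], []
        prior = self._predict_pose(obj)
        for view in (0, 1):
            cam = self.rig.cam0 if view == 0 else self.rig.cam1
            vpose = prior if view == 0 else \
                Pose(self.rig.rig_rotation, self.rig.rig_translation).compose(prior)
            pred = project_points(obj.points.local, vpose, cam, strict=False)
            desc = obj.points.desc0 if view == 0 else obj.points.desc1
            tm = match_temporal(pred, desc, points[view],
                                gate_radius=c.effective_gate_radius,
                                max_hamming_frac=c.max_hamming_frac,
                                tie_margin_bits=c.tie_margin_bits)
            if c.template_track:
                # canonical-template tracking: descriptor matching proposes a
                # correspondence, but the stored per-point patch is the
                # identity anchor — its correlation peak near the predicted
                # location overrides the (lattice-quantized, swap-prone)
                # detection, and points whose template is found need no
                # detection at all this frame
                obj.points.ensure_patches(c.refine_patch)
                patches = obj.points.patch0 if view == 0 else obj.points.patch1
                finite = np.isfinite(pred).all(axis=1)
                uv_t = np.full_like(pred, np.nan)
                ok_t = np.zeros(len(pred), bool)
                if finite.any():
                    sub_uv, _, sub_ok = track_templates(
                        patches[finite], frames[view], pred[finite],
                        search=c.template_search,
                        min_score=c.template_min_score)
                    uv_t[finite] = sub_uv
                    ok_t[finite] = sub_ok
                src2row = {int(s): k for k, s in enumerate(tm.source_idx)}
                extra = []
                for s in np.nonzero(ok_t)[0]:
                    row = src2row.get(int(s))
                    if row is not None:
                        tm.target_uv[row] = uv_t[s]
                    else:
                        extra.append(int(s))
                if extra:
                    extra = np.asarray(extra, np.intp)
                    tm = TemporalMatches(
                        np.concatenate([tm.source_idx, extra]),
                        np.concatenate([tm.target_idx,
                                        np.full(len(extra), -1, np.intp)]),
                        np.concatenate([tm.hamming, np.zeros(len(extra), np.int64)]),
                        np.vstack([tm.pixel_offset, uv_t[extra] - pred[extra]]),
                        np.setdiff1d(tm.unmatched_sources, extra),
                        np.vstack([tm.target_uv, uv_t[extra]]),
                    )
            matches[view] = (tm, points[view])
            if len(tm):
                obj_pts.append(obj.points.local[tm.source_idx])
                img_pts.append(tm.target_uv)
                view_ids.append(np.full(len(tm), view))
                pt_rows.append(tm.source_idx)
        if not obj_pts:
            return None, matches, np.zeros(0, np.intp)
        corrs = Correspondences2D3D(
            np.vstack(obj_pts), np.vstack(img_pts), np.concatenate(view_ids),
        )
        if c.age_weighting:
            # long-lived points carry the object's original registration;
            # up-weighting them slows the slow re-registration drift caused
            # by anchor turnover as new facets rotate into view
            rows = np.concatenate(pt_rows)
            age = self.frame_index - obj.points.born[rows]
            factor = 1.0 + np.minimum(age / 20.0, 2.0)
            w = corrs.weights * factor
            corrs.weights = w / w.sum()
        seed = (c.seed * 1000003 + self.frame_index * 97 + obj.object_id * 13) % (2**31)
        est = estimate_pose_ransac(
            corrs, self.rig, threshold_px=c.threshold_px, max_iter=c.max_iter,
            seed=seed, min_mass=c.min_mass, confidence=c.confidence,
            prior_pose=prior,
            # bounds grow with the dropout length so a briefly lost object
            # can still be re-acquired
            max_rot_increment=np.deg2rad(c.max_rot_increment_deg)
            * (obj.frames_since_seen + 1) * 200.0 / c.frame_rate,
            max_trans_increment=c.max_trans_increment
            * (obj.frames_since_seen + 1) * 200.0 / c.frame_rate,
        )
        consumed = np.concatenate([
            matches[v][0].target_idx for v in (0, 1) if len(matches[v][0])
        ]) if any(len(matches[v][0]) for v in (0, 1)) else np.zeros(0, np.intp)
        return est, matches, consumed

    # -- main entry ---------------------------------------------------------

    def process_frame_pair(self, img0, img1) -> FramePairResult:
        c = self.config
        self.frame_index += 1
        f = self.frame_index
        result = FramePairResult(frame_index=f, n_interest_points=(0, 0))
        stages = []

        # 1. detection
        stages.append("detect")
        points = [self._detect(img0, 0), self._detect(img1, 1)]
        result.n_interest_points = (len(points[0]), len(points[1]))

        # 2+3. temporal matching, estimation, update (per object)
        stages.append("temporal_match")
        stages.append("estimate_update")
        consumed = {0: [], 1: []}
        frames = (np.asarray(img0, float), np.asarray(img1, float))
        for obj in self.objects:
            est, matches, _ = self._estimate_object(obj, points, frames)
            accepted = est is not None
            filtered_ok = True
            if accepted and c.use_kalman:
                if obj.filter_state is None:
                    obj.filter_state = KalmanState()
                obj.filter_state.sigma_accel = c.sigma_accel
                obj.filter_state.sigma_meas = c.sigma_meas
                obj.filter_state.rot_smoothing = c.rot_smoothing
                obj.filter_state.gate_prob = c.kalman_gate_prob
                filtered_pose, filtered_ok = kalman_update(
                    obj.filter_state, est.pose, 1.0 / c.frame_rate)
                if filtered_ok:
                    est.pose = filtered_pose
            if accepted and filtered_ok:
                if c.drift_correction > 0:
                    est.pose = self._drift_correction(obj, est.pose, matches,
                                                      frames)
                for view in (0, 1):
                    tm, _ = matches[view]
                    if len(tm):
                        consumed[view].append(tm.target_idx[tm.target_idx >= 0])
                # reprojection stats use the pre-update point set (the match
                # indices refer to it; update_object may remove points)
                result.reprojection[obj.object_id] = self._mean_reprojection(
                    obj, matches, est.pose)
                update_object(obj, est.pose, self.rig, matches, frames,
                              self.extractor, frame_index=f,
                              removal_thresh=c.removal_thresh,
                              gate_bound=c.gate_bound,
                              resynth_unmatched=c.resynth_unmatched,
                              patch_size=c.refine_patch,
                              patch_refresh=c.patch_refresh)
                obj.record_pose(f, est.pose)
                result.estimates[obj.object_id] = est
                result.filtered_flags[obj.object_id] = filtered_ok
            else:
                obj.frames_since_seen += 1
                result.events.append(
                    ("estimation_failed" if not accepted else "filter_rejected",
                     obj.object_id))

        self.objects, newly_retired = retire_objects(self.objects, c.max_unseen_frames,
                                                     current_frame=f)
        for obj in newly_retired:
            result.events.append(("retired", obj.object_id))
        self.retired.extend(newly_retired)

        # leftover interest points -> stereo -> 3D candidates
        leftovers = []
        for view in (0, 1):
            if consumed[view]:
                used = np.unique(np.concatenate(consumed[view]))
                keep = np.setdiff1d(np.arange(len(points[view])), used)
                leftovers.append(points[view].take(keep))
            else:
                leftovers.append(points[view])
        if len(leftovers[0]) and len(leftovers[1]):
            stereo = match_stereo(leftovers[0], leftovers[1], self.rig,
                                  epi_tol=c.epi_tol,
                                  max_hamming_frac=c.max_hamming_frac)
            if len(stereo) and c.subpixel_refine:
                # align the view-1 detections to the view-0 patches so the
                # disparity (hence depth) is sub-pixel consistent
                stereo.uv1, _ = refine_subpixel(
                    frames[0], stereo.uv0, frames[1], stereo.uv1,
                    patch=c.refine_patch, search=c.refine_search,
                    ref_mask=self.masks[0])
            stereo = filter_displacement_map(stereo, window=c.disp_window,
                                             jump_factor=c.jump_factor)
            cands = reconstruct_candidates(stereo, self.rig)
        else:
            from .correspondence import CandidateSet, StereoCorrespondences
            stereo = StereoCorrespondences.empty(c.n_bits // 8)
            cands = CandidateSet(np.zeros((0, 3)),
                                 np.zeros((0, c.n_bits // 8), np.uint8),
                                 np.zeros((0, c.n_bits // 8), np.uint8),
                                 np.zeros((0, 2)), np.zeros((0, 2)))
        result.n_stereo = len(stereo)
        result.n_candidates = len(cands)
        new_dummy = DummyObject(cands.points, cands.desc0, cands.desc1, frame=f)

        # 4. motion-consistency association against the previous cycle
        stages.append("associate")
        pairs, unpaired_idx = pair_dummy_cycles(
            self.dummy, new_dummy, max_travel=c.max_travel,
            max_hamming_frac=c.max_hamming_frac, n_bits=c.n_bits)
        noise = self._triangulation_noise(cands.points)
        align = c.align_thresh if c.align_thresh is not None else 3.0 * noise
        rigid = c.rigid_tol if c.rigid_tol is not None else 2.0 * noise
        residue = associate_new_points(pairs,
                                       self.objects if c.accrete_points else [],
                                       align_thresh=align,
                                       max_points=c.max_object_points)

        # 5. new-object generation from the residue; points inside an active
        # object's 3D footprint may only ever *join* that object (scene
        # parsimony: no second parameter set for the same structure)
        stages.append("generate")
        free = np.ones(len(residue), bool)
        for obj_a in self.objects:
            if len(obj_a.points) == 0:
                continue
            radius = float(np.linalg.norm(obj_a.points.local, axis=1).max())
            d = np.linalg.norm(residue.p1 - obj_a.pose.translation, axis=1)
            free &= d > radius + 3.0 * align
        blocked = residue.take(np.nonzero(~free)[0])
        residue = residue.take(np.nonzero(free)[0])
        seed = (c.seed * 1000003 + f * 101 + 7) % (2**31)
        obj, residue = generate_object(
            residue, min_object_points=c.min_object_points,
            object_id=self.next_object_id, inlier_tol=rigid, seed=seed)
        if len(blocked):
            residue = DummyPairs(
                np.vstack([residue.p0, blocked.p0]),
                np.vstack([residue.p1, blocked.p1]),
                np.vstack([residue.desc0, blocked.desc0]),
                np.vstack([residue.desc1, blocked.desc1]),
                residue.t0 if len(residue) else blocked.t0,
                residue.t1 if len(residue) else blocked.t1)
        if obj is not None:
            self.next_object_id += 1
            self.objects.append(obj)
            result.events.append(("generated", obj.object_id))

        # 6. next dummy: unpaired fresh candidates + residue on grace
        stages.append("new_dummy")
        fresh = new_dummy.points[unpaired_idx] if len(new_dummy) else np.zeros((0, 3))
        fresh_d0 = new_dummy.desc0[unpaired_idx]
        fresh_d1 = new_dummy.desc1[unpaired_idx]
        res_keep = np.zeros(len(residue), bool)
        if len(residue):
            # residue ages are implicit: pairs entering residue have age >= 1;
            # they get residue_grace more cycles via the dummy
            res_keep[:] = c.residue_grace > 0
        self.dummy = DummyObject(
            np.vstack([fresh, residue.p1[res_keep]]),
            np.vstack([fresh_d0, residue.desc0[res_keep]]),
            np.vstack([fresh_d1, residue.desc1[res_keep]]),
            frame=f,
        )
        result.stages = tuple(stages)
        self.prev_frames = frames
        self.prev_masks = list(self.masks)
        self.results.append(result)
        return result

    def _drift_correction(self, obj: TrackedObject, pose: Pose, matches,
                          frames) -> Pose:
        """Pull the pose toward fresh stereo evidence to bound drift.

        The 2D reprojection fit inherits whatever registration error has
        accumulated in the maintained model (descriptor re-synthesis and
        point accretion both bake the current pose error into the model
        state, so small per-frame biases compound).  Triangulating the
        points matched in *both* views this frame gives 3D positions
        anchored only to the calibrated rig — an absolute, feedback-free
        registration measurement.  The rigid discrepancy between the stored
        local coordinates and the fresh measurements (robust Kabsch, one
        MAD trim) is blended into the pose with gain ``drift_correction``:
        drift is bounded at (bias rate / gain) while the added jitter is
        the Kabsch noise scaled by the gain.
        """
        c = self.config
        kappa = c.drift_correction
        tm0, _ = matches.get(0, (None, None))
        tm1, _ = matches.get(1, (None, None))
        if tm0 is None or tm1 is None or len(tm0) < 4 or len(tm1) < 4:
            return pose
        common, i0, i1 = np.intersect1d(tm0.source_idx, tm1.source_idx,
                                        return_indices=True)
        if len(common) < 12:   # a small, shallow set makes Kabsch ill-conditioned
            return pose
        from .geometry import triangulate_points
        uv0 = tm0.target_uv[i0]
        uv1 = tm1.target_uv[i1]
        # disparity consistency: the two views' matches were found
        # independently; align view 1 to the view-0 patches before
        # triangulating, else depth noise swamps the drift signal
        uv1, _ = refine_subpixel(frames[0], uv0, frames[1], uv1,
                                 patch=c.refine_patch, search=c.refine_search,
                                 ref_mask=self.masks[0])
        X, _, valid = triangulate_points(uv0, uv1, self.rig, strict=False)
        ok = valid & np.isfinite(X).all(axis=1) & (X[:, 2] > 0)
        if ok.sum() < 4:
            return pose
        L = obj.points.local[common[ok]]
        M = pose.inverse_apply(X[ok])          # fresh measurement in local frame
        from .pose_estimation import kabsch
        Rc, tc = kabsch(L, M)
        res = np.linalg.norm(M - (L @ Rc.T + tc), axis=1)
        cut = 3.0 * max(float(np.median(res)), 1e-4)
        core = res <= cut
        if core.sum() >= 4:
            Rc, tc = kabsch(L[core], M[core])
        # exponentially averaged measurement, then a clamped fractional step:
        # pose' maps local -> camera via pose o (Rc,tc)^kappa
        rv_meas = rodrigues(Rc)
        a = c.drift_ewma
        prev_rv, prev_t = self._corr_ewma.get(obj.object_id, (np.zeros(3), np.zeros(3)))
        rv_f = (1 - a) * prev_rv + a * rv_meas
        t_f = (1 - a) * prev_t + a * tc
        self._corr_ewma[obj.object_id] = (rv_f, t_f)

        rv = rv_f * kappa
        ang = np.linalg.norm(rv)
        max_step = np.deg2rad(c.drift_correction_max_deg)
        if ang > max_step:
            rv *= max_step / ang
        tk = kappa * t_f
        tn = np.linalg.norm(tk)
        if tn > 0.01:
            tk *= 0.01 / tn
        from .geometry import rodrigues_inverse
        Rk = rodrigues_inverse(rv)
        return Pose(pose.rotation @ Rk, pose.rotation @ tk + pose.translation)

    def _predict_pose(self, obj: TrackedObject) -> Pose:
        """Constant-velocity extrapolation of the object pose for gating."""
        hist = obj.pose_history
        if len(hist) < 2:
            return obj.pose
        frames = sorted(hist)
        f1, f0 = frames[-1], frames[-2]
        if f1 - f0 > 3:     # stale history: do not extrapolate across gaps
            return obj.pose
        steps = (self.frame_index - f1) / (f1 - f0)
        p1, p0 = hist[f1], hist[f0]
        dR = p1.rotation @ p0.rotation.T
        rv = rodrigues(dR) * steps
        from .geometry import rodrigues_inverse
        return Pose(rodrigues_inverse(rv) @ p1.rotation,
                    p1.translation + steps * (p1.translation - p0.translation))

    def _triangulation_noise(self, points: np.ndarray) -> float:
        """Median first-order depth noise of current candidates (meters).

        Depth uncertainty of a triangulated point grows as
        ``sqrt(2) * sigma_px * Z^2 / (f * B)``; the median over candidates
        sets the natural length scale for the motion-consistency and
        rigid-consistency tolerances.
        """
        if len(points) == 0:
            return 0.01
        Z = np.median(points[:, 2])
        fB = self.rig.cam0.fx * self.rig.baseline
        return float(np.sqrt(2.0) * self.config.sigma_px * Z * Z / fB)

    def _mean_reprojection(self, obj: TrackedObject, matches, pose: Pose):
        """Fig.-8-style per-view mean pixel error of matched object points."""
        out = {}
        for view, cam in ((0, self.rig.cam0), (1, self.rig.cam1)):
            tm, new_pts = matches[view]
            if len(tm) == 0:
                continue
            vpose = pose if view == 0 else \
                Pose(self.rig.rig_rotation, self.rig.rig_translation).compose(pose)
            proj = project_points(obj.points.local[tm.source_idx], vpose, cam,
                                  strict=False)
            d = np.linalg.norm(tm.target_uv - proj, axis=1)
            d = d[np.isfinite(d)]
            if len(d):
                out[view] = float(d.mean())
        return out

    # -- exports -------------------------------------------------------------

    def trajectory_frame(self) -> pd.DataFrame:
        """Per-frame pose estimates of all objects as a flat table."""
        from scipy.spatial.transform import Rotation as _R
        by_frame = {r.frame_index: r for r in self.results}
        rows = []
        for obj in list(self.objects) + list(self.retired):
            for fidx, pose in sorted(obj.pose_history.items()):
                rv = rodrigues(pose.rotation)
                q = _R.from_matrix(pose.rotation).as_quat()
                res = by_frame.get(fidx)
                est = res.estimates.get(obj.object_id) if res else None
                filtered = res.filtered_flags.get(obj.object_id, False) if res else False
                rows.append({
                    "frame": fidx, "object_id": obj.object_id,
                    "tx": pose.translation[0], "ty": pose.translation[1],
                    "tz": pose.translation[2],
                    "rx": rv[0], "ry": rv[1], "rz": rv[2],
                    "qx": q[0], "qy": q[1], "qz": q[2], "qw": q[3],
                    "weighted_error": est.weighted_error if est else np.nan,
                    "n_inliers": len(est.inlier_ids) if est else 0,
                    "filtered": bool(filtered),
                })
        return pd.DataFrame(rows, columns=["frame", "object_id", "tx", "ty", "tz",
                                           "rx", "ry", "rz", "qx", "qy", "qz", "qw",
                                           "weighted_error", "n_inliers", "filtered"])

    def registry(self) -> dict:
        """Object registry: lifetimes, point counts, subsequences."""
        entries = []
        for obj in list(self.objects) + list(self.retired):
            runs = obj.consistent_subsequences()
            entries.append({
                "object_id": obj.object_id,
                "birth_frame": int(obj.birth_frame),
                "last_seen_frame": int(max(obj.pose_history)) if obj.pose_history else None,
                "n_points": int(len(obj.points)),
                "retired": obj in self.retired,
                "subsequence_lengths": [len(r) for r in runs],
                "frames_tracked_total": int(sum(len(r) for r in runs)),
            })
        return {"objects": entries, "n_frames_processed": self.frame_index + 1}


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-object pose-error and tracking statistics."""

    per_object: list
    reprojection: list            # (frame, object_id, view, mean_px)

    def to_dict(self) -> dict:
        return {"objects": self.per_object, "reprojection": self.reprojection}

    @property
    def mean_pose_error_percent(self) -> float:
        vals = [o["mean_pose_error_percent"] for o in self.per_object
                if o["mean_pose_error_percent"] is not None]
        return float(np.mean(vals)) if vals else float("nan")


def _poses_from_frame_table(df: pd.DataFrame) -> dict:
    from .geometry import rodrigues_inverse
    out = {}
    for _, row in df.iterrows():
        out[int(row["frame"])] = Pose(
            rodrigues_inverse([row["rx"], row["ry"], row["rz"]]),
            [row["tx"], row["ty"], row["tz"]],
        )
    return out


def evaluate_run(estimates: pd.DataFrame, truth: pd.DataFrame,
                 results: list | None = None, lag: int = 20) -> EvaluationReport:
    """Score estimated pose tracks against ground truth.

    ``estimates`` is a trajectory table (``frame, object_id, tx..rz``) and
    ``truth`` the ground-truth table (``frame, object, tx..rz``).  Each
    tracked object is compared against the nearest ground-truth object (by
    median centroid distance over common frames).  The pose error per
    frame is the orientation-difference error over a ``lag``-frame
    baseline, computed only within consistent subsequences with at least
    ``lag`` frames of history, and averaged per object.  With no ground
    truth, a reprojection-only report is produced.
    """
    reproj = []
    if results is not None:
        for r in results:
            for oid, views in r.reprojection.items():
                for view, val in views.items():
                    reproj.append({"frame": r.frame_index, "object_id": int(oid),
                                   "view": int(view), "mean_px": float(val)})

    per_object = []
    if truth is None or len(truth) == 0:
        for oid, grp in (estimates.groupby("object_id") if len(estimates) else []):
            per_object.append({"object_id": int(oid),
                               "mean_pose_error_percent": None,
                               "n_error_samples": 0,
                               "subsequence_lengths": [],
                               "frames_tracked_total": int(len(grp))})
        return EvaluationReport(per_object, reproj)

    truth_by_obj = {
        int(k): _poses_from_frame_table(g)
        for k, g in truth.rename(columns={"object": "object_id"}).groupby("object_id")
    }

    for oid, grp in estimates.groupby("object_id"):
        est_poses = _poses_from_frame_table(grp)
        frames = sorted(est_poses)
        # consistent subsequences = maximal consecutive runs
        runs, cur = [], []
        for fr in frames:
            if cur and fr == cur[-1] + 1:
                cur.append(fr)
            else:
                if cur:
                    runs.append(cur)
                cur = [fr]
        if cur:
            runs.append(cur)

        # pick the nearest ground-truth object
        best_tid, best_dist = None, np.inf
        for tid, tposes in truth_by_obj.items():
            common = [fr for fr in frames if fr in tposes]
            if not common:
                continue
            d = np.median([
                np.linalg.norm(est_poses[fr].translation - tposes[fr].translation)
                for fr in common
            ])
            if d < best_dist:
                best_tid, best_dist = tid, d
        errors = []
        if best_tid is not None:
            tposes = truth_by_obj[best_tid]
            for run in runs:
                for fr in run:
                    f0 = fr - lag
                    if f0 not in run and f0 not in set(run):
                        continue
                    if f0 < run[0]:
                        continue
                    if fr not in tposes or f0 not in tposes:
                        continue
                    try:
                        e = pose_error_percentage(tposes[f0], tposes[fr],
                                                  est_poses[f0], est_poses[fr])
                    except ValueError:
                        continue
                    errors.append(e)
        per_object.append({
            "object_id": int(oid),
            "matched_truth_object": best_tid,
            "mean_pose_error_percent": float(100 * np.mean(errors)) if errors else None,
            "n_error_samples": len(errors),
            "subsequence_lengths": [len(r) for r in runs],
            "frames_tracked_total": int(sum(len(r) for r in runs)),
        })
    return EvaluationReport(per_object, reproj)
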