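"""Descriptor matching along time and across views, plus 3D candidate
reconstruction.

Temporal matching exploits the high frame rate: between adjacent 5 ms
frames a point cannot travel far in the image, so each maintained object
point only searches new detections inside a spatial gate around its
predicted location, which both speeds matching up and suppresses aliasing
between similar-looking texture elements.

Cross-view matching has no temporal gate; instead the epipolar constraint
from stereo calibration restricts candidates to a band around the epipolar
line, followed by a mutual-best Hamming check (repeated texture produces
descriptor-identical points; a pair is trusted only when each endpoint is
the other's best match).  Accepted pairs then pass a displacement-map
filter: surfaces are spatially continuous, so the view-0-to-view-1 pixel
displacement varies smoothly across a surface, and a correspondence whose
displacement jumps away from its neighbors' local median is discarded as a
mismatch before triangulation can turn it into a phantom 3D point.

Exact Hamming search is the reference semantics throughout; there is no
approximate index whose output could drift from the brute force.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .geometry import CameraRig, DegenerateGeometryError, fundamental_matrix, triangulate_points
from .interest_points import InterestPointSet, hamming_cdist

__all__ = [
    "TemporalMatches",
    "StereoCorrespondences",
    "CandidateSet",
    "match_temporal",
    "match_stereo",
    "filter_displacement_map",
    "reconstruct_candidates",
    "refine_subpixel",
    "track_templates",
]

logger = logging.getLogger(__name__)


@dataclass
class TemporalMatches:
    """One-to-one matches from maintained object points to new detections.

    ``source_idx`` indexes the projected object points, ``target_idx`` the
    new :class:`InterestPointSet`; ``pixel_offset`` is new minus predicted.
    ``target_uv`` starts as the detections' integer-grid locations and may
    be replaced by sub-pixel refined positions downstream.
    """

    source_idx: np.ndarray
    target_idx: np.ndarray
    hamming: np.ndarray
    pixel_offset: np.ndarray
    unmatched_sources: np.ndarray
    target_uv: np.ndarray = None

    def __post_init__(self):
        if self.target_uv is None:
            self.target_uv = np.zeros((len(self.source_idx), 2))

    def __len__(self) -> int:
        return len(self.source_idx)


@dataclass
class StereoCorrespondences:
    """Accepted cross-view pairs with their descriptors carried along."""

    uv0: np.ndarray
    uv1: np.ndarray
    idx0: np.ndarray
    idx1: np.ndarray
    hamming: np.ndarray
    epipolar_residual: np.ndarray
    desc0: np.ndarray
    desc1: np.ndarray

    def __len__(self) -> int:
        return len(self.uv0)

    def take(self, idx) -> "StereoCorrespondences":
        return StereoCorrespondences(
            self.uv0[idx], self.uv1[idx], self.idx0[idx], self.idx1[idx],
            self.hamming[idx], self.epipolar_residual[idx],
            self.desc0[idx], self.desc1[idx],
        )

    @classmethod
    def empty(cls, nbytes: int = 64) -> "StereoCorrespondences":
        z = np.zeros(0, dtype=np.intp)
        return cls(np.zeros((0, 2)), np.zeros((0, 2)), z, z,
                   np.zeros(0, np.int64), np.zeros(0),
                   np.zeros((0, nbytes), np.uint8), np.zeros((0, nbytes), np.uint8))

    def to_dataframe(self, frame: int = 0, points3d: np.ndarray | None = None):
        """Export as a table (frame, u0, v0, u1, v1, hamming, residual, X, Y, Z)."""
        import pandas as pd
        n = len(self)
        X = np.full((n, 3), np.nan) if points3d is None else np.asarray(points3d)
        return pd.DataFrame({
            "frame": frame,
            "u0": self.uv0[:, 0], "v0": self.uv0[:, 1],
            "u1": self.uv1[:, 0], "v1": self.uv1[:, 1],
            "hamming": self.hamming,
            "residual": self.epipolar_residual,
            "X": X[:, 0], "Y": X[:, 1], "Z": X[:, 2],
        })


@dataclass
class CandidateSet:
    """Triangulated 3D candidates (camera-0 frame) with per-view descriptors."""

    points: np.ndarray          # (n, 3)
    desc0: np.ndarray
    desc1: np.ndarray
    uv0: np.ndarray
    uv1: np.ndarray
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.points)

    def take(self, idx) -> "CandidateSet":
        return replace(self, points=self.points[idx], desc0=self.desc0[idx],
                       desc1=self.desc1[idx], uv0=self.uv0[idx], uv1=self.uv1[idx])


# ---------------------------------------------------------------------------
# Temporal matching
# ---------------------------------------------------------------------------

def match_temporal(predicted_uv: np.ndarray, descriptors: np.ndarray,
                   new_points: InterestPointSet, gate_radius: float = 40.0,
                   max_hamming_frac: float = 0.5,
                   tie_margin_bits: int = 8) -> TemporalMatches:
    """Match object points to new detections inside a spatial gate.

    For every object point the new detections within ``gate_radius`` pixels
    of its predicted image location are candidate matches; assignment is
    one-to-one by greedy ascending Hamming distance over all gated pairs,
    so each object point ends up with its nearest-Hamming candidate unless
    a better-scoring competitor claims that detection first.  Pairs with a
    normalized Hamming distance above ``max_hamming_frac`` are never
    accepted (a near-random descriptor agreement is no evidence at all).

    Repetitive texture produces several candidates at nearly the same
    Hamming distance; among candidates within ``tie_margin_bits`` of an
    object point's best, the one closest to the predicted location wins.
    Without this tie-break, point identities hop between look-alike
    texture cells and the maintained model slowly slides over the surface.
    """
    if gate_radius <= 0:
        raise ValueError("gate_radius must be positive")
    predicted_uv = np.atleast_2d(np.asarray(predicted_uv, dtype=float))
    if predicted_uv.size == 0:
        predicted_uv = predicted_uv.reshape(0, 2)
    m = len(predicted_uv)
    empty = TemporalMatches(
        np.zeros(0, np.intp), np.zeros(0, np.intp), np.zeros(0, np.int64),
        np.zeros((0, 2)), np.arange(m, dtype=np.intp),
    )
    if m == 0 or len(new_points) == 0:
        return empty

    finite = np.isfinite(predicted_uv).all(axis=1)
    tree = cKDTree(new_points.uv)
    neighborhoods = tree.query_ball_point(predicted_uv[finite], gate_radius)
    src_ids = np.nonzero(finite)[0]

    pair_src, pair_tgt = [], []
    for s, cands in zip(src_ids, neighborhoods):
        pair_src.extend([s] * len(cands))
        pair_tgt.extend(cands)
    if not pair_src:
        return empty
    pair_src = np.asarray(pair_src, dtype=np.intp)
    pair_tgt = np.asarray(pair_tgt, dtype=np.intp)
    ham = _pair_hamming(descriptors, new_points.descriptors, pair_src, pair_tgt)

    limit = max_hamming_frac * new_points.n_bits
    ok = ham <= limit
    pair_src, pair_tgt, ham = pair_src[ok], pair_tgt[ok], ham[ok]
    if len(ham) == 0:
        return empty

    # near-tie resolution: penalize pairs only marginally better in Hamming
    # than a spatially closer alternative, by sorting on (hamming rounded to
    # the tie margin, pixel distance)
    dist = np.linalg.norm(new_points.uv[pair_tgt] - predicted_uv[pair_src], axis=1)
    tie_class = ham // max(tie_margin_bits, 1)
    order = np.lexsort((dist, tie_class))
    used_src = np.zeros(m, bool)
    used_tgt = np.zeros(len(new_points), bool)
    keep = []
    for k in order:
        s, t = pair_src[k], pair_tgt[k]
        if not used_src[s] and not used_tgt[t]:
            used_src[s] = used_tgt[t] = True
            keep.append(k)
    keep = np.asarray(keep, dtype=np.intp)
    s_idx, t_idx = pair_src[keep], pair_tgt[keep]
    return TemporalMatches(
        source_idx=s_idx,
        target_idx=t_idx,
        hamming=ham[keep],
        pixel_offset=new_points.uv[t_idx] - predicted_uv[s_idx],
        unmatched_sources=np.nonzero(~used_src)[0].astype(np.intp),
        target_uv=new_points.uv[t_idx].copy(),
    )


def _pair_hamming(desc_a, desc_b, ia, ib):
    from .interest_points import hamming_pairs
    return hamming_pairs(desc_a[ia], desc_b[ib])


# ---------------------------------------------------------------------------
# Stereo matching
# ---------------------------------------------------------------------------

def match_stereo(pts0: InterestPointSet, pts1: InterestPointSet, rig: CameraRig,
                 epi_tol: float = 3.0,
                 max_hamming_frac: float = 0.5) -> StereoCorrespondences:
    """Epipolar-gated, mutual-best cross-view descriptor matching.

    Candidate pairs are restricted to an epipolar residual (distance of the
    view-1 point from the epipolar line of the view-0 point) of at most
    ``epi_tol`` pixels; among those, each point's best-Hamming partner is
    found in both directions and only mutual best pairs survive.  Inputs
    must be undistorted pixel coordinates.
    """
    if rig.baseline <= 0:
        raise DegenerateGeometryError("zero-baseline rig has no epipolar geometry")
    if len(pts0) == 0 or len(pts1) == 0:
        return StereoCorrespondences.empty()

    F = fundamental_matrix(rig)
    h0 = np.concatenate([pts0.uv, np.ones((len(pts0), 1))], axis=1)
    lines = h0 @ F.T                                    # (n0, 3) lines in view 1
    norms = np.linalg.norm(lines[:, :2], axis=1)
    h1 = np.concatenate([pts1.uv, np.ones((len(pts1), 1))], axis=1)
    residual = np.abs(lines @ h1.T) / norms[:, None]    # (n0, n1)

    allowed = residual <= epi_tol
    if not allowed.any():
        return StereoCorrespondences.empty()
    ham = hamming_cdist(pts0.descriptors, pts1.descriptors).astype(float)
    limit = max_hamming_frac * pts0.n_bits
    ham[~allowed] = np.inf
    ham[ham > limit] = np.inf

    best01 = np.argmin(ham, axis=1)
    best10 = np.argmin(ham, axis=0)
    i0 = np.arange(len(pts0))
    mutual = (best10[best01] == i0) & np.isfinite(ham[i0, best01])
    i0 = i0[mutual]
    i1 = best01[mutual]
    return StereoCorrespondences(
        uv0=pts0.uv[i0], uv1=pts1.uv[i1],
        idx0=i0.astype(np.intp), idx1=i1.astype(np.intp),
        hamming=ham[i0, i1].astype(np.int64),
        epipolar_residual=residual[i0, i1],
        desc0=pts0.descriptors[i0], desc1=pts1.descriptors[i1],
    )


# ---------------------------------------------------------------------------
# Displacement-map filtering
# ---------------------------------------------------------------------------

def filter_displacement_map(corrs: StereoCorrespondences, window: float = 31.0,
                            jump_factor: float = 4.0, mad_floor: float = 2.0,
                            max_removal_fraction: float = 0.5) -> StereoCorrespondences:
    """Reject correspondences whose displacement jumps away from neighbors.

    For each correspondence the component-wise median displacement of its
    view-0 neighbors within ``window`` pixels is computed; a deviation of
    more than ``jump_factor`` times the local median absolute deviation
    (floored at ``mad_floor`` px) removes the correspondence.  At most
    ``max_removal_fraction`` of the input is ever removed — if the rule
    would strike more, only the worst offenders go and the cap is logged —
    so a systematically wrong local statistic cannot wipe out the set.
    Correspondences without neighbors are kept.
    """
    n = len(corrs)
    if n == 0:
        return corrs
    disp = corrs.uv1 - corrs.uv0
    tree = cKDTree(corrs.uv0)
    neighborhoods = tree.query_ball_point(corrs.uv0, window)
    deviation = np.zeros(n)
    threshold = np.full(n, np.inf)
    for i, nb in enumerate(neighborhoods):
        nb = [j for j in nb if j != i]
        if not nb:
            continue
        local = disp[nb]
        med = np.median(local, axis=0)
        deviation[i] = np.linalg.norm(disp[i] - med)
        mad = np.median(np.linalg.norm(local - med, axis=1))
        threshold[i] = jump_factor * max(mad, mad_floor)
    bad = deviation > threshold
    max_remove = int(np.floor(max_removal_fraction * n))
    if bad.sum() > max_remove:
        logger.warning(
            "displacement filter capped: %d flagged, removing worst %d of %d",
            int(bad.sum()), max_remove, n,
        )
        excess = deviation / np.where(np.isfinite(threshold), threshold, np.inf)
        worst = np.argsort(-excess)[:max_remove]
        bad = np.zeros(n, bool)
        bad[worst] = True
    return corrs.take(np.nonzero(~bad)[0])


# ---------------------------------------------------------------------------
# Sub-pixel refinement
# ---------------------------------------------------------------------------

def refine_subpixel(ref_img: np.ndarray, ref_uv: np.ndarray,
                    tgt_img: np.ndarray, tgt_uv: np.ndarray,
                    patch: int = 15, search: int = 3,
                    min_score: float = 0.3,
                    ref_mask: np.ndarray | None = None,
                    min_weight_frac: float = 0.25):
    """Refine matched point locations by normalized cross-correlation.

    Descriptor matching lands on integer detector positions, whose ~1-2 px
    localization noise dominates both triangulation error (hence 3D model
    distortion) and pose jitter.  For each pair, the ``patch`` x ``patch``
    template around ``ref_uv`` in ``ref_img`` is correlated against a
    ``±search`` px window around ``tgt_uv`` in ``tgt_img``; the NCC peak is
    interpolated to sub-pixel precision with a 1D parabola per axis.
    Pairs too close to a border, or whose best correlation falls below
    ``min_score``, are returned unrefined.  Returns ``(refined_uv,
    refined_mask)``.

    ``ref_mask`` (a boolean foreground mask for ``ref_img``) restricts the
    correlation to foreground pixels.  This matters near the silhouette of
    a moving target: a plain patch there is part object, part *static*
    background, and unweighted correlation anchors the match to the
    background — systematically cancelling the very motion (especially the
    rotation-induced flow, largest at the rim) the tracker must observe.
    Pairs whose template retains fewer than ``min_weight_frac`` foreground
    pixels are left unrefined.
    """
    ref_img = np.asarray(ref_img, float)
    tgt_img = np.asarray(tgt_img, float)
    ref_uv = np.atleast_2d(np.asarray(ref_uv, float))
    tgt_uv = np.atleast_2d(np.asarray(tgt_uv, float))
    n = len(ref_uv)
    out = tgt_uv.copy()
    refined = np.zeros(n, bool)
    if n == 0:
        return out, refined
    hp = patch // 2
    hw = hp + search
    H, W = tgt_img.shape
    Hr, Wr = ref_img.shape

    ref_c = np.rint(ref_uv).astype(int)
    tgt_c = np.rint(tgt_uv).astype(int)
    ok = ((ref_c[:, 0] >= hp) & (ref_c[:, 0] < Wr - hp)
          & (ref_c[:, 1] >= hp) & (ref_c[:, 1] < Hr - hp)
          & (tgt_c[:, 0] >= hw) & (tgt_c[:, 0] < W - hw)
          & (tgt_c[:, 1] >= hw) & (tgt_c[:, 1] < H - hw))
    idx = np.nonzero(ok)[0]
    if len(idx) == 0:
        return out, refined

    dy, dx = np.mgrid[-hp:hp + 1, -hp:hp + 1]
    templates = ref_img[ref_c[idx, 1, None, None] + dy,
                        ref_c[idx, 0, None, None] + dx]
    if ref_mask is not None:
        weights = np.asarray(ref_mask)[ref_c[idx, 1, None, None] + dy,
                                       ref_c[idx, 0, None, None] + dx].astype(float)
        wsum = weights.sum(axis=(1, 2))
        enough = wsum >= min_weight_frac * patch * patch
        idx = idx[enough]
        if len(idx) == 0:
            return out, refined
        templates = templates[enough]
        weights = weights[enough]
        wsum = wsum[enough][:, None, None]
    else:
        weights = np.ones_like(templates)
        wsum = np.full((len(idx), 1, 1), float(patch * patch))

    tmean = (templates * weights).sum(axis=(1, 2), keepdims=True) / wsum
    templates = (templates - tmean) * weights
    t_norm = np.sqrt((templates**2 / np.maximum(weights, 1e-12)).sum(axis=(1, 2)))

    n_off = 2 * search + 1
    scores = np.full((len(idx), n_off, n_off), -np.inf)
    for oy in range(-search, search + 1):
        for ox in range(-search, search + 1):
            win = tgt_img[tgt_c[idx, 1, None, None] + oy + dy,
                          tgt_c[idx, 0, None, None] + ox + dx]
            wmean = (win * weights).sum(axis=(1, 2), keepdims=True) / wsum
            winw = (win - wmean) * weights
            w_norm = np.sqrt((winw**2 / np.maximum(weights, 1e-12)).sum(axis=(1, 2)))
            num = (templates * win).sum(axis=(1, 2))
            denom = np.maximum(t_norm * w_norm, 1e-9)
            scores[:, oy + search, ox + search] = num / denom

    flat = scores.reshape(len(idx), -1)
    best = np.argmax(flat, axis=1)
    by, bx = np.unravel_index(best, (n_off, n_off))
    best_score = flat[np.arange(len(idx)), best]

    # parabolic sub-pixel interpolation, per axis, at interior peaks
    for k in range(len(idx)):
        if best_score[k] < min_score:
            continue
        y, x = by[k], bx[k]
        fy = fx = 0.0
        if 0 < x < n_off - 1:
            a, b, c = scores[k, y, x - 1], scores[k, y, x], scores[k, y, x + 1]
            d = a - 2 * b + c
            if d < -1e-12:
                fx = float(np.clip(0.5 * (a - c) / d, -0.5, 0.5))
        if 0 < y < n_off - 1:
            a, b, c = scores[k, y - 1, x], scores[k, y, x], scores[k, y + 1, x]
            d = a - 2 * b + c
            if d < -1e-12:
                fy = float(np.clip(0.5 * (a - c) / d, -0.5, 0.5))
        i = idx[k]
        out[i] = [tgt_c[i, 0] + (x - search) + fx, tgt_c[i, 1] + (y - search) + fy]
        refined[i] = True
    return out, refined


def track_templates(templates: np.ndarray, img: np.ndarray, centers: np.ndarray,
                    search: int = 5, min_score: float = 0.5):
    """Locate stored per-point template patches in the current frame.

    Sparse detections flicker from frame to frame, so a physical surface
    point is often not re-detected at all and descriptor matching then
    latches onto a look-alike texture cell nearby — point identity decays
    within a handful of frames.  A stored canonical patch is an *absolute*
    appearance anchor: correlating it against a ``±search`` px window
    around the predicted location yields an observation tied to the same
    physical surface point for as long as the appearance survives
    perspective change and blur.

    ``templates`` is (n, p, p) with ``nan`` rows for points without a
    stored patch.  Returns ``(uv, score, ok)``; ``ok`` is False where no
    template exists, the window leaves the image, or the best normalized
    correlation falls below ``min_score`` (appearance changed too much —
    the caller should fall back to descriptor matching and schedule a
    template refresh).
    """
    img = np.asarray(img, float)
    centers = np.atleast_2d(np.asarray(centers, float))
    n = len(centers)
    uv = centers.copy()
    score = np.zeros(n)
    ok = np.zeros(n, bool)
    if n == 0:
        return uv, score, ok
    p = templates.shape[-1]
    hp = p // 2
    hw = hp + search
    H, W = img.shape
    c = np.rint(centers).astype(int)
    has = np.isfinite(templates).all(axis=(1, 2))
    valid = (has & (c[:, 0] >= hw) & (c[:, 0] < W - hw)
             & (c[:, 1] >= hw) & (c[:, 1] < H - hw))
    idx = np.nonzero(valid)[0]
    if len(idx) == 0:
        return uv, score, ok

    dy, dx = np.mgrid[-hp:hp + 1, -hp:hp + 1]
    T = templates[idx]
    T = T - T.mean(axis=(1, 2), keepdims=True)
    t_norm = np.sqrt((T**2).sum(axis=(1, 2)))

    n_off = 2 * search + 1
    scores = np.full((len(idx), n_off, n_off), -np.inf)
    for oy in range(-search, search + 1):
        for ox in range(-search, search + 1):
            win = img[c[idx, 1, None, None] + oy + dy,
                      c[idx, 0, None, None] + ox + dx]
            win = win - win.mean(axis=(1, 2), keepdims=True)
            w_norm = np.sqrt((win**2).sum(axis=(1, 2)))
            num = (T * win).sum(axis=(1, 2))
            scores[:, oy + search, ox + search] = num / np.maximum(t_norm * w_norm, 1e-9)

    flat = scores.reshape(len(idx), -1)
    best = np.argmax(flat, axis=1)
    by, bx = np.unravel_index(best, (n_off, n_off))
    best_score = flat[np.arange(len(idx)), best]
    for k in range(len(idx)):
        if best_score[k] < min_score:
            continue
        y, x = by[k], bx[k]
        fy = fx = 0.0
        if 0 < x < n_off - 1:
            a, b_, c_ = scores[k, y, x - 1], scores[k, y, x], scores[k, y, x + 1]
            d = a - 2 * b_ + c_
            if d < -1e-12:
                fx = float(np.clip(0.5 * (a - c_) / d, -0.5, 0.5))
        if 0 < y < n_off - 1:
            a, b_, c_ = scores[k, y - 1, x], scores[k, y, x], scores[k, y + 1, x]
            d = a - 2 * b_ + c_
            if d < -1e-12:
                fy = float(np.clip(0.5 * (a - c_) / d, -0.5, 0.5))
        i = idx[k]
        uv[i] = [c[i, 0] + (x - search) + fx, c[i, 1] + (y - search) + fy]
        score[i] = best_score[k]
        ok[i] = True
    return uv, score, ok


# ---------------------------------------------------------------------------
# Candidate reconstruction
# ---------------------------------------------------------------------------

def reconstruct_candidates(corrs: StereoCorrespondences, rig: CameraRig,
                           min_ray_angle: float = 1e-4) -> CandidateSet:
    """Triangulate filtered correspondences into 3D candidates.

    Degenerate-ray failures (and points landing behind a camera) are
    dropped with a logged count; descriptors pass through bit-identical.
    """
    if len(corrs) == 0:
        return CandidateSet(np.zeros((0, 3)), corrs.desc0, corrs.desc1,
                            corrs.uv0, corrs.uv1, 0)
    X, _, valid = triangulate_points(corrs.uv0, corrs.uv1, rig,
                                     min_ray_angle=min_ray_angle, strict=False)
    ok = valid & np.isfinite(X).all(axis=1) & (X[:, 2] > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("reconstruct_candidates: dropped %d degenerate pair(s)", n_dropped)
    idx = np.nonzero(ok)[0]
    return CandidateSet(
        points=X[idx], desc0=corrs.desc0[idx], desc1=corrs.desc1[idx],
        uv0=corrs.uv0[idx], uv1=corrs.uv1[idx], n_dropped=n_dropped,
    )
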