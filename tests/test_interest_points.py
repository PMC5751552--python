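"""Detector, background-model, descriptor and verification tests."""

import numpy as np
import pytest
from skimage.feature import corner_harris, corner_peaks

from blurtrack.interest_points import (
    BackgroundModel,
    DescriptorExtractor,
    InterestPointSet,
    compute_descriptors,
    detect_candidates,
    gradient_magnitude,
    hamming_cdist,
    hamming_pairs,
    update_background,
    verify_interest_points,
)


def brute_force_candidates(frame, alpha, radius):
    """Per-pixel reference implementation of the candidate rule."""
    img = frame.astype(float)
    g = gradient_magnitude(img)
    H, W = img.shape
    out = np.zeros((H, W), bool)
    for r in range(H):
        for c in range(W):
            y0, y1 = max(r - radius, 0), min(r + radius + 1, H)
            x0, x1 = max(c - radius, 0), min(c + radius + 1, W)
            out[r, c] = g[r, c] > alpha * img[y0:y1, x0:x1].mean()
    return out


class TestDetectCandidates:
    def test_constant_image_yields_nothing(self):
        frame = np.full((64, 64), 120.0)
        uv, g = detect_candidates(frame, None)
        assert len(uv) == 0

    def test_step_edge_matches_brute_force(self):
        frame = np.full((40, 40), 100.0)
        frame[:, 20:] = 150.0
        uv, _ = detect_candidates(frame, None, alpha=0.1, radius=3)
        ref = brute_force_candidates(frame, 0.1, 3)
        got = np.zeros_like(ref)
        got[uv[:, 1].astype(int), uv[:, 0].astype(int)] = True
        assert np.array_equal(got, ref)
        # candidates hug the edge columns only
        assert set(np.unique(uv[:, 0])) <= {19.0, 20.0}

    def test_blurred_edge_beats_corner_detector(self):
        """The full blurred transition band yields candidates where a
        Harris-style detector finds essentially nothing."""
        rng = np.random.default_rng(0)
        frame = np.full((128, 128), 60.0)
        frame[40:90, 40:90] = 210.0
        # horizontal box blur of width 10 emulates motion blur
        kernel = np.ones(10) / 10
        frame = np.apply_along_axis(
            lambda r: np.convolve(r, kernel, mode="same"), 1, frame
        )
        frame += rng.normal(0, 1.0, frame.shape)
        uv, _ = detect_candidates(frame, None, alpha=0.08, radius=7)
        band = uv[(uv[:, 1] > 45) & (uv[:, 1] < 85)]
        left_band = band[(band[:, 0] > 30) & (band[:, 0] < 50)]
        # candidates span the blurred transition (several columns wide)
        assert len(np.unique(left_band[:, 0].astype(int))) >= 6
        harris = corner_peaks(corner_harris(frame / 255.0), min_distance=3,
                              threshold_rel=0.1)
        in_band = harris[(harris[:, 1] > 30) & (harris[:, 1] < 50)]
        assert len(in_band) < len(left_band) / 10 + 1

    def test_mask_restricts_output(self):
        frame = np.full((40, 40), 100.0)
        frame[:, 20:] = 150.0
        mask = np.zeros((40, 40), bool)
        mask[:10] = True
        uv, _ = detect_candidates(frame, mask, alpha=0.1, radius=3)
        assert len(uv) > 0 and np.all(uv[:, 1] < 10)
        uv2, _ = detect_candidates(frame, np.zeros((40, 40), bool))
        assert len(uv2) == 0

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        tex = rng.integers(60, 200, (60, 60)).astype(float)
        big = np.full((120, 120), 100.0)
        big[20:80, 20:80] = tex
        shifted = np.full((120, 120), 100.0)
        shifted[27:87, 25:85] = tex
        uv_a, _ = detect_candidates(big, None, alpha=0.1, radius=5)
        uv_b, _ = detect_candidates(shifted, None, alpha=0.1, radius=5)
        # compare interior detections only (away from patch borders)
        interior = lambda uv, o: uv[
            (uv[:, 0] > o[0] + 8) & (uv[:, 0] < o[0] + 52)
            & (uv[:, 1] > o[1] + 8) & (uv[:, 1] < o[1] + 52)
        ]
        a = interior(uv_a, (20, 20)) + [5, 7]
        b = interior(uv_b, (25, 27))
        a_set = {tuple(p) for p in a}
        b_set = {tuple(p) for p in b}
        assert a_set == b_set


class TestBackgroundModel:
    def test_static_sequence_converges_to_background(self):
        rng = np.random.default_rng(1)
        base = rng.integers(50, 200, (64, 64)).astype(float)
        model = BackgroundModel()
        for _ in range(60):
            frame = base + rng.normal(0, 1.0, base.shape)
            model = update_background(model, frame)
        assert model.foreground_mask.sum() == 0

    def test_moving_blob_detected(self):
        """A bright blob entering from outside the frame is segmented."""
        rng = np.random.default_rng(2)
        base = rng.integers(60, 120, (96, 96)).astype(float)
        model = BackgroundModel()
        yy, xx = np.mgrid[0:96, 0:96]
        ious = []
        for t in range(80):
            cx, cy = -15 + 1.1 * t, 48.0
            disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= 8**2
            frame = base.copy()
            frame[disk] = 230.0
            model = update_background(model, frame + rng.normal(0, 1, base.shape))
            if t >= 40:
                inter = (model.foreground_mask & disk).sum()
                union = (model.foreground_mask | disk).sum()
                ious.append(inter / union)
        assert np.mean(ious) >= 0.7

    def test_illumination_step_decays(self):
        rng = np.random.default_rng(3)
        base = rng.integers(80, 140, (48, 48)).astype(float)
        model = BackgroundModel()
        for _ in range(60):
            model = update_background(model, base + rng.normal(0, 1, base.shape))
        model = update_background(model, base + 40.0)
        assert model.foreground_mask.mean() > 0.5  # transient response
        for _ in range(model.absorb_after + 5):
            model = update_background(model, base + 40.0 + rng.normal(0, 1, base.shape))
        assert model.foreground_mask.sum() == 0  # absorbed after the stale window

    def test_first_frame_initializes_with_empty_mask(self):
        model = update_background(BackgroundModel(), np.zeros((8, 8)))
        assert model.foreground_mask.sum() == 0 and model.frames_seen == 1

    def test_shape_mismatch_rejected(self):
        model = update_background(BackgroundModel(), np.zeros((8, 8)))
        with pytest.raises(ValueError):
            update_background(model, np.zeros((9, 9)))


class TestDescriptors:
    def test_identical_patches_identical_descriptors(self):
        rng = np.random.default_rng(4)
        patch = rng.integers(0, 255, (31, 31)).astype(float)
        frame = np.full((100, 160), 128.0)
        frame[10:41, 10:41] = patch
        frame[60:91, 100:131] = patch
        ext = DescriptorExtractor()
        d, kept = ext.extract(frame, np.array([[25.0, 25.0], [115.0, 75.0]]))
        assert len(kept) == 2
        assert hamming_pairs(d[0], d[1]) == 0

    def test_rotated_patch_differs(self):
        rng = np.random.default_rng(8)
        patch = rng.integers(0, 255, (31, 31)).astype(float)
        frame = np.full((100, 160), 128.0)
        frame[10:41, 10:41] = patch
        frame[60:91, 100:131] = patch[::-1, ::-1]
        ext = DescriptorExtractor()
        d, _ = ext.extract(frame, np.array([[25.0, 25.0], [115.0, 75.0]]))
        assert hamming_pairs(d[0], d[1]) > 0

    def test_deterministic_recomputation(self):
        rng = np.random.default_rng(9)
        frame = rng.integers(0, 255, (80, 80)).astype(float)
        uv = rng.uniform(20, 60, (10, 2))
        a = compute_descriptors(frame, uv)
        b = compute_descriptors(frame, uv)
        assert np.array_equal(a.descriptors, b.descriptors)

    def test_border_points_dropped_and_reported(self):
        frame = np.random.default_rng(10).integers(0, 255, (60, 60)).astype(float)
        ext = DescriptorExtractor(patch_size=25)
        uv = np.array([[2.0, 30.0], [30.0, 30.0]])
        d, kept = ext.extract(frame, uv)
        assert list(kept) == [1] and len(d) == 1

    def test_hamming_cdist_matches_pairs(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 256, (7, 64)).astype(np.uint8)
        b = rng.integers(0, 256, (5, 64)).astype(np.uint8)
        M = hamming_cdist(a, b)
        for i in range(7):
            for j in range(5):
                assert M[i, j] == hamming_pairs(a[i], b[j])


def brute_force_verify(pts, radius, dthresh):
    n = len(pts)
    keep = np.ones(n, bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.linalg.norm(pts.uv[i] - pts.uv[j])
            if d < radius:
                nh = hamming_pairs(pts.descriptors[i], pts.descriptors[j]) / pts.n_bits
                if nh / d <= dthresh:
                    keep[i] = False
                    break
    return keep


class TestVerification:
    def _random_set(self, seed, n=200, extent=120.0):
        rng = np.random.default_rng(seed)
        uv = rng.uniform(0, extent, (n, 2))
        desc = rng.integers(0, 256, (n, 64)).astype(np.uint8)
        # plant a few near-duplicate descriptor clusters to exercise rejection
        for k in range(0, 40, 2):
            desc[k + 1] = desc[k]
            uv[k + 1] = uv[k] + rng.normal(0, 2, 2)
        return InterestPointSet(uv, desc, rng.uniform(1, 10, n))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_all_pairs_brute_force(self, seed):
        pts = self._random_set(seed)
        out = verify_interest_points(pts, radius=7.0, dthresh=0.02)
        ref = brute_force_verify(pts, 7.0, 0.02)
        got = {tuple(p) for p in out.uv}
        expect = {tuple(p) for p in pts.uv[ref]}
        assert got == expect

    def test_identical_close_pair_both_rejected(self):
        desc = np.random.default_rng(0).integers(0, 256, (1, 64)).astype(np.uint8)
        pts = InterestPointSet(np.array([[10.0, 10.0], [11.0, 10.0]]),
                               np.vstack([desc, desc]), np.array([1.0, 1.0]))
        assert len(verify_interest_points(pts, radius=7.0, dthresh=0.02)) == 0

    def test_isolated_candidate_kept(self):
        rng = np.random.default_rng(1)
        desc = rng.integers(0, 256, (2, 64)).astype(np.uint8)
        pts = InterestPointSet(np.array([[10.0, 10.0], [100.0, 100.0]]),
                               desc, np.array([1.0, 1.0]))
        assert len(verify_interest_points(pts, radius=7.0)) == 2

    def test_duplicate_location_tiebreak_by_gradient(self):
        rng = np.random.default_rng(2)
        desc = rng.integers(0, 256, (2, 64)).astype(np.uint8)
        pts = InterestPointSet(np.array([[5.0, 5.0], [5.0, 5.0]]),
                               desc, np.array([1.0, 9.0]))
        out = verify_interest_points(pts, radius=7.0)
        assert len(out) == 1 and out.gradient_mag[0] == 9.0

    def test_output_is_subset_of_input(self):
        pts = self._random_set(7)
        out = verify_interest_points(pts, radius=7.0, dthresh=0.02)
        inset = {tuple(p) for p in pts.uv}
        assert all(tuple(p) in inset for p in out.uv)
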