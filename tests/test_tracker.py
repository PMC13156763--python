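import numpy as np
import pytest

import fishgait as fg
from fishgait.geometry import arc_lengths
from fishgait.tracker import (
    NoFishError,
    binarize_frame,
    centroid,
    estimate_background,
    largest_contour,
    locate_head,
    locate_tail,
    max_entropy_threshold,
    midline_points,
    refine_tail_juvenile,
    window_counts,
)

from conftest import render


def brute_force_max_entropy(hist):
    """Independent oracle: exhaustive search of the Kapur objective."""
    p = hist.astype(float) / hist.sum()
    best_val, best_t = -np.inf, -1
    for t in range(256):
        p1, p2 = p[: t + 1], p[t + 1 :]
        w1, w2 = p1.sum(), p2.sum()
        if w1 <= 0 or w2 <= 0:
            continue
        q1 = p1[p1 > 0] / w1
        q2 = p2[p2 > 0] / w2
        val = -(q1 * np.log(q1)).sum() - (q2 * np.log(q2)).sum()
        if val > best_val + 1e-12:
            best_val, best_t = val, t
    return best_t


class TestMaxEntropyThreshold:
    def test_two_level_histogram_separates_levels(self):
        hist = np.zeros(256)
        hist[10], hist[200] = 500, 500
        t = max_entropy_threshold(hist)
        assert 10 <= t < 200

    def test_matches_exhaustive_search_on_random_histograms(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            hist = rng.integers(0, 1000, size=256).astype(float)
            assert max_entropy_threshold(hist) == brute_force_max_entropy(hist)

    def test_single_bin_rejected(self):
        hist = np.zeros(256)
        hist[42] = 100
        with pytest.raises(ValueError):
            max_entropy_threshold(hist)

    def test_synthetic_frame_threshold_excludes_fin_interior(self, finned_shape):
        # the threshold lands between the pigmented body and the
        # near-background translucent fins, so fin pixels away from the
        # body's blur halo stay in the background class
        res = render(finned_shape, heading=0.4, bend=0.2)
        mask = binarize_frame(res.image, fg.TrackerParams.for_size_class("large_adult"))
        fin_level = finned_shape.fin_gray
        # pixels rendered at the fin gray, at least 4 px from the body
        from scipy import ndimage

        far_from_body = ~ndimage.binary_dilation(res.body_mask, iterations=4)
        fin_px = (res.image >= fin_level - 1) & (res.image <= fin_level + 1) & far_from_body
        assert fin_px.sum() > 50  # fins are actually present
        assert (mask & fin_px).sum() == 0


class TestBackgroundAndBinarize:
    def test_static_scene_background_is_the_frame(self):
        frame = np.full((20, 30), 200, dtype=np.uint8)
        bg = estimate_background([frame] * 5)
        assert np.array_equal(bg, frame)

    def test_median_rejects_transient_fish(self):
        rng = np.random.default_rng(0)
        empty = rng.integers(200, 240, size=(30, 40)).astype(np.uint8)
        stack = []
        for i in range(7):
            f = empty.copy()
            if i < 3:  # fish present in fewer than half the samples per pixel
                f[10 + i : 14 + i, 5:15] = 20
            stack.append(f)
        assert np.array_equal(estimate_background(stack), empty)

    def test_three_frame_median(self):
        frames = [np.full((2, 2), v, dtype=np.uint8) for v in (1, 2, 9)]
        assert estimate_background(frames)[0, 0] == 2

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            estimate_background([np.zeros((4, 4))] * 2)

    def test_blank_frame_yields_no_fish(self, adult_params):
        blank = np.full((100, 100), 230, dtype=np.uint8)
        series = fg.track([blank], adult_params, fps=100, mm_per_px=0.5)
        assert series.frames[0].flag == "no_fish"

    def test_larva_mode_background_subtraction(self):
        # light-bodied larva invisible to direct thresholding becomes a
        # contiguous mask in the subtraction channel
        bg = np.full((120, 160), 230, dtype=np.uint8)
        frame = bg.copy()
        frame[50:58, 60:100] = 180  # faint larva
        params = fg.TrackerParams(mode="larva")
        mask = binarize_frame(frame, params, background=bg)
        assert mask[52, 80]
        from scipy import ndimage

        _, n = ndimage.label(mask)
        assert n == 1


class TestCentroid:
    def test_single_pixel(self):
        m = np.zeros((10, 10), bool)
        m[4, 7] = True
        assert centroid(m) == pytest.approx([7, 4])

    def test_filled_square(self):
        m = np.zeros((5, 5), bool)
        m[0:3, 0:3] = True
        assert centroid(m) == pytest.approx([1, 1])

    def test_l_shape_matches_enumerated_mean(self):
        m = np.zeros((6, 6), bool)
        m[0:5, 0] = True
        m[4, 0:4] = True
        rows, cols = np.nonzero(m)
        assert centroid(m) == pytest.approx([cols.mean(), rows.mean()])

    def test_empty_mask_rejected(self):
        with pytest.raises(NoFishError):
            centroid(np.zeros((5, 5), bool))


class TestLocateTailAndHead:
    def test_triangle_apex_minimizes_window_count(self):
        # tall isoceles triangle with a sharp apex: the apex is the
        # sharpest vertex; verify against exhaustive window sums
        m = np.zeros((110, 80), bool)
        for r in range(90):
            half = max(1, int(round(r * 0.22)))
            m[10 + r, 40 - half : 40 + half + 1] = True
        contour, comp = largest_contour(m)
        idx, _ = locate_tail(contour, comp, 13)
        counts = window_counts(comp, contour, 13)
        assert counts[idx] == counts.min()
        assert np.hypot(contour[idx, 0] - 40, contour[idx, 1] - 10) < 5

    def test_circle_tie_flags_low_confidence(self):
        from skimage.draw import disk

        m = np.zeros((60, 60), bool)
        rr, cc = disk((30, 30), 15)
        m[rr, cc] = True
        contour, comp = largest_contour(m)
        idx, tie = locate_tail(contour, comp, 9)
        assert tie  # rotational symmetry forces distant ties

    def test_capsule_head_is_opposite_end(self):
        # symmetric capsule: restricting to the proximal half forces the
        # head to the end opposite the tail anchor
        m = np.zeros((40, 120), bool)
        from skimage.draw import disk

        m[15:26, 20:100] = True
        rr, cc = disk((20, 20), 5)
        m[rr, cc] = True
        rr, cc = disk((20, 100), 5)
        m[rr, cc] = True
        contour, comp = largest_contour(m)
        i_tail, _ = locate_tail(contour, comp, 9)
        i_head, _ = locate_head(contour, i_tail, comp, 9)
        assert abs(contour[i_tail, 0] - contour[i_head, 0]) > 70

    def test_degenerate_contour_rejected(self):
        with pytest.raises(NoFishError):
            locate_tail(np.zeros((4, 2)), np.zeros((5, 5), bool), 5)

    def test_rendered_fish_tail_within_3px(self, finned_shape, adult_params):
        res = render(finned_shape, heading=1.0, bend=0.3)
        series = fg.track([res.image], adult_params, fps=100, mm_per_px=0.5)
        s1 = series.frames[0].S[0]
        true_tail = res.midline[0]
        assert np.hypot(*(s1 - true_tail)) < 3.0

    def test_rendered_fish_head_within_3px(self, finned_shape, adult_params):
        res = render(finned_shape, heading=-0.8, bend=-0.2)
        series = fg.track([res.image], adult_params, fps=100, mm_per_px=0.5)
        head = series.frames[0].head
        true_head = res.midline[-1]
        assert np.hypot(*(head - true_head)) < 3.0


class TestMidlinePoints:
    def test_straight_capsule_points_on_axis(self):
        m = np.zeros((40, 140), bool)
        m[17:24, 20:120] = True
        from skimage.draw import disk

        rr, cc = disk((20, 20), 4)
        m[rr, cc] = True
        rr, cc = disk((20, 120), 4)
        m[rr, cc] = True
        contour, comp = largest_contour(m)
        i_tail, _ = locate_tail(contour, comp, 9)
        i_head, _ = locate_head(contour, i_tail, comp, 9)
        S, head = midline_points(contour, i_tail, i_head, 5)
        assert np.all(np.abs(S[1:, 1] - 20.0) <= 1.0)  # on the central axis
        gaps = np.hypot(*np.diff(S[1:], axis=0).T)
        assert np.all(np.abs(gaps - gaps.mean()) <= 1.0)  # equally spaced

    def test_bent_fish_points_near_true_midline(self, finned_shape, adult_params):
        from scipy.spatial.distance import cdist

        res = render(finned_shape, heading=0.5, bend=np.deg2rad(20))
        series = fg.track([res.image], adult_params, fps=100, mm_per_px=0.5)
        e = cdist(series.frames[0].S, res.midline).min(axis=1)
        assert e.max() <= 2.5

    def test_unequal_arcs_still_return_n_points(self):
        # cut deliberately asymmetric: tail and "head" not opposite
        m = np.zeros((60, 60), bool)
        from skimage.draw import disk

        rr, cc = disk((30, 30), 20)
        m[rr, cc] = True
        contour, comp = largest_contour(m)
        S, head = midline_points(contour, 0, len(contour) // 3, 7)
        assert S.shape == (7, 2)

    def test_ordering_arc_distance_increases_tailward_to_head(
        self, finned_shape, adult_params
    ):
        res = render(finned_shape, heading=2.2, bend=0.4)
        series = fg.track([res.image], adult_params, fps=100, mm_per_px=0.5)
        fm = series.frames[0]
        chain = np.vstack([fm.S, fm.head])
        s = arc_lengths(chain)
        assert np.all(np.diff(s) > 0)


class TestRefineTailJuvenile:
    def _capsule(self, x0, x1, y=20, r=4, shape=(40, 160)):
        m = np.zeros(shape, bool)
        m[y - r : y + r + 1, x0:x1] = True
        return m

    def test_s0_more_distal_than_s1(self):
        head = np.array([150.0, 20.0])
        mask_main = self._capsule(40, 150)   # eroded tail: starts at x=40
        mask_sub = self._capsule(15, 150)    # subtraction keeps the light tail
        s1 = np.array([40.0, 20.0])
        s0, refined = refine_tail_juvenile(mask_main, mask_sub, s1, head=head)
        assert refined
        assert np.hypot(*(s0 - head)) > np.hypot(*(s1 - head))

    def test_identical_masks_keep_s1(self):
        # rounded caudal cap with S1 already at its tip: no contour point
        # is strictly more distal, so the anchor is unchanged
        from skimage.draw import disk

        mask = self._capsule(40, 150)
        rr, cc = disk((20, 40), 4, shape=mask.shape)
        mask[rr, cc] = True
        s1 = np.array([36.0, 20.0])  # the cap tip
        s0, refined = refine_tail_juvenile(mask, mask, s1, head=np.array([150.0, 20.0]))
        assert np.hypot(*(s0 - s1)) <= 1.5

    def test_pectoral_lobes_never_selected(self):
        # subtraction channel has fin lobes proximal to S1: excluded because
        # only points more distal than S1 are candidates
        head = np.array([150.0, 20.0])
        mask_main = self._capsule(40, 150)
        mask_sub = self._capsule(15, 150)
        from skimage.draw import disk

        rr, cc = disk((8, 100), 6, shape=mask_sub.shape)  # sharp lobe near head
        mask_sub[rr, cc] = True
        s1 = np.array([40.0, 20.0])
        s0, refined = refine_tail_juvenile(mask_main, mask_sub, s1, head=head)
        assert refined
        assert s0[0] < 25  # the true light tail tip, not the lobe


class TestTrackSeriesContracts:
    def test_two_blank_frames_flagged_not_dropped(self, finned_shape, adult_params):
        res = render(finned_shape)
        blank = np.full_like(res.image, 230)
        frames = [res.image, blank, res.image, blank, res.image]
        series = fg.track(frames, adult_params, fps=100, mm_per_px=0.5)
        assert len(series) == 5
        assert [f.flag for f in series.frames] == [
            "ok", "no_fish", "ok", "no_fish", "ok",
        ]

    def test_annotated_output_same_length(self, finned_shape, adult_params):
        res = render(finned_shape)
        series, annotated = fg.track(
            [res.image] * 3, adult_params, fps=100, mm_per_px=0.5, annotate=True
        )
        assert len(annotated) == 3
        assert annotated[0].shape == (*res.image.shape, 3)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            fg.TrackerParams(mode="adult", tail_window=4)
        with pytest.raises(ValueError):
            fg.TrackerParams(mode="whale")
        with pytest.raises(ValueError):
            fg.TrackerParams(n_midline=2)

    def test_size_class_defaults(self):
        assert fg.TrackerParams.for_size_class("large_adult").n_midline == 10
        assert fg.TrackerParams.for_size_class("small_adult").n_midline == 7
        assert fg.TrackerParams.for_size_class("juvenile").n_midline == 6
        assert fg.TrackerParams.for_size_class("larva").n_midline == 5
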