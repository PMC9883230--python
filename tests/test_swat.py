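import itertools

import numpy as np
import pytest

from hemdetect.config import SwatParams
from hemdetect.core_io import Box, SeedPoint
from hemdetect.swat import (
    DegenerateWindowError,
    binarize_window,
    effective_regions,
    grow_box,
    multilevel_otsu,
    select_candidate,
    swat_segment,
)


def brute_force_otsu(window: np.ndarray, rho: int):
    """Exhaustive search over all ascending threshold vectors (16-level)."""
    hist = np.bincount(window.ravel(), minlength=256).astype(float)
    p = hist / hist.sum()
    lv = np.arange(256.0)
    occupied = np.flatnonzero(p)
    mu = (p * lv).sum()
    best, best_t = -np.inf, None
    # only thresholds at occupied levels change the partition
    candidates = [int(v) for v in occupied[:-1]]
    for ts in itertools.combinations(candidates, rho - 1):
        edges = (int(occupied[0]) - 1,) + ts + (255,)
        score = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            m = p[a + 1: b + 1].sum()
            if m > 0:
                s1 = (p[a + 1: b + 1] * lv[a + 1: b + 1]).sum()
                score += s1 * s1 / m
        if score > best + 1e-12:
            best, best_t = score, ts
    sigma_t2 = (p * (lv - mu) ** 2).sum()
    return best - mu * mu, sigma_t2, best_t


class TestMultilevelOtsu:
    def test_two_valued_window_perfect_separation(self):
        win = np.array([[0, 0, 255, 255]] * 4)
        res = multilevel_otsu(win, 2)
        assert res.eta == pytest.approx(1.0)
        assert res.thresholds[0] < 255
        assert res.sigma_b2 == pytest.approx(res.sigma_t2, rel=1e-9)

    @pytest.mark.parametrize("rho", [2, 3, 4])
    def test_dp_matches_exhaustive_search(self, rho, rng):
        for _ in range(100):
            win = (rng.integers(0, 16, (8, 8)) * 17).astype(np.int64)
            if win.max() == win.min():
                continue
            res = multilevel_otsu(win, rho)
            sigma_b2, sigma_t2, _ = brute_force_otsu(win, rho)
            assert res.sigma_b2 == pytest.approx(sigma_b2, rel=1e-9, abs=1e-12)
            assert res.eta == pytest.approx(
                min(sigma_b2 / sigma_t2, 1.0), rel=1e-9
            )

    def test_eta_monotone_in_rho(self, rng):
        win = rng.integers(0, 256, (12, 12))
        etas = [multilevel_otsu(win, rho).eta for rho in range(2, 8)]
        assert all(b >= a - 1e-12 for a, b in zip(etas, etas[1:]))

    def test_eta_invariant_to_affine_rescale(self, rng):
        win = rng.integers(0, 64, (10, 10))
        res1 = multilevel_otsu(win, 3)
        res2 = multilevel_otsu(win * 3 + 50, 3)
        assert res1.eta == pytest.approx(res2.eta, abs=0.02)

    def test_constant_window_degenerate(self):
        with pytest.raises(DegenerateWindowError):
            multilevel_otsu(np.full((8, 8), 42), 2)

    def test_threshold_count(self, rng):
        win = rng.integers(0, 256, (16, 16))
        for rho in (2, 4, 7):
            assert len(multilevel_otsu(win, rho).thresholds) == rho - 1


class TestEffectiveRegions:
    def test_two_valued_window_stops_at_two(self):
        win = np.array([[0, 0, 255, 255]] * 4)
        res = effective_regions(win)
        assert res.rho == 2
        assert res.eta >= 0.8

    def test_many_equal_mass_levels_need_more_regions(self):
        # 21 equally likely distinct levels spread over the gray range
        levels = np.linspace(0, 255, 21).astype(np.int64)
        win = np.repeat(levels, 12).reshape(21, 12)
        res = effective_regions(win)
        assert res.rho > 2

    def test_loop_contract(self, rng):
        for _ in range(10):
            win = rng.integers(0, 256, (10, 10))
            res = effective_regions(win, eta_min=0.8, rho_cap=20)
            assert res.eta >= 0.8 or res.rho == 20


class TestBinarizeWindow:
    def test_all_above_min_threshold_gives_empty(self):
        win = np.full((5, 5), 200)
        w1 = binarize_window(win, (100, 150))
        assert not w1.any()

    def test_exact_pointwise_rule(self, rng):
        win = rng.integers(0, 256, (9, 9))
        thresholds = (80, 160)
        w1 = binarize_window(win, thresholds)
        np.testing.assert_array_equal(w1, win <= 80)
        assert w1.shape == win.shape and w1.dtype == bool

    def test_dark_ellipse_support_recovered(self):
        yy, xx = np.mgrid[0:60, 0:60]
        ellipse = ((yy - 30) / 12.0) ** 2 + ((xx - 30) / 8.0) ** 2 <= 1
        win = np.where(ellipse, 30, 200).astype(np.int64)
        res = effective_regions(win)
        w1 = binarize_window(win, res.thresholds)
        iou = (w1 & ellipse).sum() / (w1 | ellipse).sum()
        assert iou >= 0.9

    def test_empty_thresholds_rejected(self):
        with pytest.raises(ValueError):
            binarize_window(np.zeros((3, 3)), ())


class TestSelectCandidate:
    def test_single_component_always_retained(self):
        w1 = np.zeros((20, 20), dtype=bool)
        w1[5:9, 5:9] = True
        obj, d, q = select_candidate(w1, (18, 18))
        np.testing.assert_array_equal(obj, w1)
        assert d > 0

    def test_distance_rule_beats_size(self):
        w1 = np.zeros((40, 40), dtype=bool)
        w1[2:20, 2:20] = True         # large component
        w1[30:36, 30:36] = True       # small component, seed on its centroid
        obj, d, _ = select_candidate(w1, (32, 32))
        assert obj[32, 32]
        assert not obj[10, 10]
        assert d < 2

    def test_third_smallest_component_never_retained(self):
        w1 = np.zeros((40, 40), dtype=bool)
        w1[0:10, 0:10] = True          # area 100
        w1[20:28, 0:8] = True          # area 64
        w1[35:38, 35:38] = True        # area 9 — seed sits on it
        obj, _, _ = select_candidate(w1, (36, 36))
        assert not obj[36, 36]

    def test_border_flags(self):
        w1 = np.zeros((10, 10), dtype=bool)
        w1[0:4, 0:4] = True            # touches top and left
        _, _, q = select_candidate(w1, (1, 1))
        assert q == (True, True, False, False)

    def test_empty_window_returns_none(self):
        assert select_candidate(np.zeros((5, 5), dtype=bool), (2, 2)) is None


class TestGrowBox:
    def _s(self):
        return np.ones((200, 200), dtype=bool)

    def test_no_flags_no_change(self):
        box = Box(50, 50, 100, 100)
        assert grow_box(box, (False,) * 4, self._s()) == box

    def test_left_touch_moves_left_edge_by_five(self):
        box = Box(50, 50, 100, 100)
        grown = grow_box(box, (True, False, False, False), self._s())
        assert grown == Box(45, 50, 100, 100)

    def test_right_bottom_move_by_ten(self):
        box = Box(50, 50, 100, 100)
        grown = grow_box(box, (False, False, True, True), self._s())
        assert grown == Box(50, 50, 110, 110)

    def test_edge_outside_search_region_stays(self):
        s = self._s()
        s[:, :48] = False              # S ends at column 48
        box = Box(50, 50, 100, 100)
        grown = grow_box(box, (True, False, False, False), s)
        assert grown == box

    def test_clipped_at_image_bounds(self):
        box = Box(0, 0, 197, 197)
        grown = grow_box(box, (True, True, True, True), self._s())
        assert grown == Box(0, 0, 199, 199)

    def test_symmetric_growth_uses_small_step(self):
        box = Box(50, 50, 100, 100)
        grown = grow_box(
            box, (False, False, True, True), self._s(), symmetric=True
        )
        assert grown == Box(50, 50, 105, 105)


class TestSwatSegment:
    def _scene(self, seed_noise=3.0):
        rng = np.random.default_rng(99)
        img = np.full((200, 200), 150.0) + rng.normal(0, seed_noise, (200, 200))
        yy, xx = np.mgrid[0:200, 0:200]
        ellipse = ((yy - 100) / 15.0) ** 2 + ((xx - 100) / 10.0) ** 2 <= 1
        img[ellipse] = 40.0
        return img, ellipse

    def test_planted_ellipse_high_iou_no_border_touch(self):
        img, ellipse = self._scene()
        s_mask = np.ones_like(img, dtype=bool)
        cand = swat_segment(img, SeedPoint(100, 100), s_mask)
        assert cand is not None
        iou = (cand.object_mask & ellipse).sum() / (cand.object_mask | ellipse).sum()
        assert iou >= 0.8
        # the final box encloses the object with margin: no border touch
        sub = cand.object_mask[cand.box.slices]
        assert not sub[0, :].any() and not sub[-1, :].any()
        assert not sub[:, 0].any() and not sub[:, -1].any()

    def test_growth_halts_at_search_region(self):
        # wide ellipse sticking out of the initial window on both sides;
        # S truncated on the right: leftward growth proceeds, rightward
        # growth is blocked, and the candidate is still returned
        rng = np.random.default_rng(99)
        img = np.full((200, 200), 150.0) + rng.normal(0, 3, (200, 200))
        yy, xx = np.mgrid[0:200, 0:200]
        ellipse = ((yy - 100) / 25.0) ** 2 + ((xx - 100) / 38.0) ** 2 <= 1
        img[ellipse] = 40.0
        s_full = np.ones_like(img, dtype=bool)
        s_cut = np.zeros_like(img, dtype=bool)
        s_cut[:, :108] = True
        free = swat_segment(img, SeedPoint(100, 100), s_full)
        clipped = swat_segment(img, SeedPoint(100, 100), s_cut)
        assert clipped is not None
        assert free.box.v3 > clipped.box.v3      # rightward growth blocked
        assert clipped.box.v1 < 100 - 30         # leftward growth proceeded

    def test_uniform_background_dropped(self):
        img = np.full((120, 120), 77.0)
        s_mask = np.ones_like(img, dtype=bool)
        assert swat_segment(img, SeedPoint(60, 60), s_mask) is None

    def test_box_always_inside_image(self):
        img, _ = self._scene()
        s_mask = np.ones_like(img, dtype=bool)
        cand = swat_segment(img, SeedPoint(10, 10), s_mask)
        if cand is not None:
            assert 0 <= cand.box.v1 <= cand.box.v3 < 200
            assert 0 <= cand.box.v2 <= cand.box.v4 < 200

    def test_seed_outside_image_rejected(self):
        img, _ = self._scene()
        with pytest.raises(ValueError):
            swat_segment(img, SeedPoint(500, 10), np.ones_like(img, bool))

    def test_termination_under_max_iter(self):
        img, _ = self._scene()
        s_mask = np.ones_like(img, dtype=bool)
        params = SwatParams(max_iter=4)
        cand = swat_segment(img, SeedPoint(100, 100), s_mask, params)
        assert cand is not None
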