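"""Smart window-based adaptive thresholding (SWAT).

A rectangular window anchored on a seed point is thresholded with an
effectiveness-driven multi-level Otsu: the number of regions rho grows from
2 until the between-region variance explains at least eta_min = 0.8 of the
window's total variance (or rho hits the cap of 20).  The darkest Otsu
region becomes foreground; of the two largest foreground components the one
nearer the seed is kept.  If the kept object touches a window border the
window grows on that side — 5 pixels on left/top, 10 on right/bottom —
as long as the moved edge stays inside the search region S, and the whole
procedure repeats on the enlarged window until the object is fully enclosed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from skimage import measure

from .config import SwatParams
from .core_io import Box, Candidate, SeedPoint

logger = logging.getLogger(__name__)


class DegenerateWindowError(ValueError):
    """Window has zero variance; no threshold exists."""


@dataclass
class OtsuResult:
    """Multi-level Otsu outcome on one window.

    thresholds has rho - 1 ascending gray levels; effectiveness
    eta = sigma_b2 / sigma_t2 is the fraction of total variance explained
    by the partition (1 means perfect separation).
    """

    rho: int
    thresholds: tuple[int, ...]
    eta: float
    sigma_b2: float
    sigma_t2: float


@dataclass
class SwatWindow:
    box: Box
    seed: SeedPoint
    otsu: OtsuResult
    binary: np.ndarray                        # W1, window frame
    q: tuple[bool, bool, bool, bool]          # left, top, right, bottom


def _histogram_moments(window: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    hist = np.bincount(
        np.asarray(window, dtype=np.int64).ravel(), minlength=256
    ).astype(np.float64)
    p = hist / hist.sum()
    lv = np.arange(256, dtype=np.float64)
    mu_t = float((p * lv).sum())
    sigma_t2 = float((p * (lv - mu_t) ** 2).sum())
    return p, lv, mu_t, sigma_t2


class _OtsuDP:
    """Shared dynamic program over cumulative histogram moments.

    The segment score of bin range [i, j] is S1^2 / S0 (first moment squared
    over mass); for a full partition, sigma_b2 = sum_k scores - mu_T^2.
    f_k builds incrementally on f_{k-1}, so escalating the region count rho
    costs one extra DP sweep instead of a recomputation from scratch.
    """

    N = 256

    def __init__(self, window: np.ndarray):
        p, lv, self.mu_t, self.sigma_t2 = _histogram_moments(window)
        if self.sigma_t2 <= 0:
            raise DegenerateWindowError("constant window (zero total variance)")
        c0 = np.concatenate([[0.0], np.cumsum(p)])
        c1 = np.concatenate([[0.0], np.cumsum(p * lv)])
        n = self.N
        i_idx = np.arange(n)[:, None]
        j_idx = np.arange(n)[None, :]
        s0 = c0[j_idx + 1] - c0[i_idx]
        s1 = c1[j_idx + 1] - c1[i_idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            seg = np.where(s0 > 0, s1**2 / np.where(s0 > 0, s0, 1.0), 0.0)
        self.seg = np.where(j_idx >= i_idx, seg, -np.inf)
        self._valid = (np.arange(1, n)[:, None]) <= j_idx
        self.f = self.seg[0, :].copy()       # rho = 1
        self.back: list[np.ndarray] = []
        self.rho = 1

    def advance(self) -> None:
        """Extend the partition by one more region."""
        n = self.N
        cand = self.f[:-1, None] + self.seg[1:, :]   # cand[i-1, j], i=1..n-1
        cand = np.where(self._valid, cand, -np.inf)
        arg = np.argmax(cand, axis=0)
        self.f = cand[arg, np.arange(n)]
        self.back.append(arg + 1)                    # split start i
        self.rho += 1

    def result(self) -> OtsuResult:
        thresholds = []
        j = self.N - 1
        for arg in reversed(self.back):
            i = int(arg[j])
            thresholds.append(i - 1)
            j = i - 1
        sigma_b2 = max(float(self.f[self.N - 1] - self.mu_t**2), 0.0)
        eta = min(sigma_b2 / self.sigma_t2, 1.0)
        return OtsuResult(
            self.rho, tuple(sorted(thresholds)), eta, sigma_b2, self.sigma_t2
        )


def multilevel_otsu(window: np.ndarray, rho: int) -> OtsuResult:
    """Exact multi-level Otsu on the window's 256-bin histogram.

    Finds the ascending (rho-1)-threshold vector maximizing the
    between-region variance sum_k w_k (mu_k - mu_T)^2 by dynamic programming
    over cumulative histogram moments — exact, not a heuristic search.
    Region k at thresholds (t_1..t_{rho-1}) is the bin range
    (t_{k-1}, t_k], with pixels <= t_1 forming the darkest region.
    """
    if not 2 <= rho <= 64:
        raise ValueError("rho must be in [2, 64]")
    dp = _OtsuDP(np.asarray(window))
    while dp.rho < rho:
        dp.advance()
    return dp.result()


def effective_regions(
    window: np.ndarray, eta_min: float = 0.8, rho_cap: int = 20
) -> OtsuResult:
    """Increase rho from 2 while eta < eta_min and rho <= rho_cap.

    Returns the first partition whose effectiveness reaches eta_min, or the
    result at the cap.  eta is non-decreasing in rho (nested optimization),
    so the loop terminates at the smallest adequate region count.
    """
    dp = _OtsuDP(np.asarray(window))
    dp.advance()                      # rho = 2
    result = dp.result()
    while result.eta < eta_min and dp.rho < rho_cap:
        dp.advance()
        result = dp.result()
    return result


def binarize_window(window: np.ndarray, thresholds: tuple[int, ...]) -> np.ndarray:
    """W1: foreground (True) where W <= min(thresholds) — the darkest region."""
    if len(thresholds) == 0:
        raise ValueError("thresholds must be nonempty")
    return np.asarray(window) <= min(thresholds)


def select_candidate(
    w1: np.ndarray, seed_rc: tuple[int, int]
) -> tuple[np.ndarray, float, tuple[bool, bool, bool, bool]] | None:
    """Keep the seed-nearest of the two largest components of W1.

    Oversized dark components are the plausible hemorrhages (dark shades are
    often bigger), so only the two largest components survive; between them
    the Euclidean distance from component centroid to the seed decides.
    Returns (object mask, distance, Q border flags) or None if W1 is empty.
    Q flags are (left, top, right, bottom): True iff the object touches that
    window border.
    """
    labeled = measure.label(w1, connectivity=2)
    regions = measure.regionprops(labeled)
    if not regions:
        return None
    regions.sort(key=lambda r: (-r.area, r.label))
    top2 = regions[:2]
    sr, sc = seed_rc
    best, best_d = None, np.inf
    for reg in top2:
        cr, cc = reg.centroid
        d = float(np.hypot(cr - sr, cc - sc))
        if d < best_d - 1e-12 or best is None:
            best, best_d = reg, d
    obj = labeled == best.label
    h, w = w1.shape
    q = (
        bool(obj[:, 0].any()),
        bool(obj[0, :].any()),
        bool(obj[:, w - 1].any()),
        bool(obj[h - 1, :].any()),
    )
    return obj, best_d, q


def grow_box(
    box: Box,
    q: tuple[bool, bool, bool, bool],
    s_mask: np.ndarray,
    step_small: int = 5,
    step_large: int = 10,
    symmetric: bool = False,
) -> Box:
    """Grow the window toward each touched border, gated by the region S.

    Left/top edges move out by step_small, right/bottom by step_large
    (symmetric=True uses step_small for all four).  An edge moves only if
    its proposed position still lies fully inside S; proposals are clipped
    to the image bounds first, and an edge already at its limit stays put.
    """
    h, w = s_mask.shape
    right_step = step_small if symmetric else step_large
    v1, v2, v3, v4 = box.v1, box.v2, box.v3, box.v4

    def _edge_ok_col(col: int, top: int, bottom: int) -> bool:
        return bool(s_mask[top: bottom + 1, col].all())

    def _edge_ok_row(row: int, left: int, right: int) -> bool:
        return bool(s_mask[row, left: right + 1].all())

    if q[0]:
        new = max(v1 - step_small, 0)
        if new != v1 and _edge_ok_col(new, v2, v4):
            v1 = new
    if q[1]:
        new = max(v2 - step_small, 0)
        if new != v2 and _edge_ok_row(new, v1, v3):
            v2 = new
    if q[2]:
        new = min(v3 + right_step, w - 1)
        if new != v3 and _edge_ok_col(new, v2, v4):
            v3 = new
    if q[3]:
        new = min(v4 + right_step, h - 1)
        if new != v4 and _edge_ok_row(new, v1, v3):
            v4 = new
    return Box(v1, v2, v3, v4)


def _quantize_window(window: np.ndarray) -> np.ndarray:
    """Window contents on a 0..255 integer scale for histogram thresholding.

    Integer windows pass through.  Float windows (the un-rounded calibrated
    channel) are min-max rescaled to the window's own range: multi-level
    Otsu effectiveness is invariant to affine intensity rescaling, and the
    local rescale preserves contrast that a global 8-bit rounding of a
    heavily gamma-compressed image would destroy.
    """
    win = np.asarray(window)
    if np.issubdtype(win.dtype, np.integer):
        return win
    lo, hi = float(win.min()), float(win.max())
    if hi <= lo:
        return np.zeros(win.shape, dtype=np.int64)
    return np.round((win - lo) / (hi - lo) * 255.0).astype(np.int64)


def _initial_box(seed: SeedPoint, size: int, height: int, width: int, min_side: int) -> Box:
    half = size // 2
    box = Box(
        max(seed.col - half, 0),
        max(seed.row - half, 0),
        min(seed.col + half, width - 1),
        min(seed.row + half, height - 1),
    )
    return _pad_box(box, height, width, min_side)


def _pad_box(box: Box, height: int, width: int, min_side: int) -> Box:
    """Expand a too-narrow box outward from the calibrated image."""
    v1, v2, v3, v4 = box.v1, box.v2, box.v3, box.v4
    while v3 - v1 + 1 < min_side and (v1 > 0 or v3 < width - 1):
        v1 = max(v1 - 1, 0)
        if v3 - v1 + 1 < min_side:
            v3 = min(v3 + 1, width - 1)
    while v4 - v2 + 1 < min_side and (v2 > 0 or v4 < height - 1):
        v2 = max(v2 - 1, 0)
        if v4 - v2 + 1 < min_side:
            v4 = min(v4 + 1, height - 1)
    return Box(v1, v2, v3, v4)


def swat_segment(
    calibrated: np.ndarray,
    seed: SeedPoint,
    s_mask: np.ndarray,
    params: SwatParams | None = None,
    image_id: str = "",
) -> Candidate | None:
    """Segment the hemorrhage candidate anchored at one seed.

    Starts from an init_size window centered on the seed and iterates
    effectiveness-driven thresholding, darkest-region binarization,
    seed-nearest object selection and border-gated growth until the object
    no longer touches the window border, growth is blocked by S or the image,
    or max_iter is reached.  Returns a Candidate whose object mask is in the
    full image frame, or None when the window is degenerate / empty
    (logged, not an error).
    """
    params = params or SwatParams()
    cal = np.asarray(calibrated)
    h, w = cal.shape
    if not (0 <= seed.row < h and 0 <= seed.col < w):
        raise ValueError("seed outside image")
    box = _initial_box(seed, params.init_size, h, w, params.min_window)
    last = None
    for _ in range(params.max_iter):
        window = _quantize_window(cal[box.slices])
        try:
            otsu = effective_regions(window, params.eta_min, params.rho_cap)
        except DegenerateWindowError:
            logger.info("seed (%d,%d): degenerate window, dropped", seed.row, seed.col)
            return None
        w1 = binarize_window(window, otsu.thresholds)
        sel = select_candidate(w1, (seed.row - box.v2, seed.col - box.v1))
        if sel is None:
            logger.info("seed (%d,%d): empty binarization, dropped", seed.row, seed.col)
            return None
        obj, dist, q = sel
        last = (box, obj, dist)
        if not any(q):
            break
        grown = grow_box(
            box, q, s_mask, params.step_small, params.step_large,
            params.symmetric_growth,
        )
        if grown == box:
            break
        box = grown
    box, obj, dist = last
    full_mask = np.zeros((h, w), dtype=bool)
    full_mask[box.slices] = obj
    return Candidate(
        box=box, seed=seed, object_mask=full_mask,
        distance=dist, image_id=image_id,
    )


def segment_seeds(
    calibrated: np.ndarray,
    seeds: list[SeedPoint],
    s_mask: np.ndarray,
    params: SwatParams | None = None,
    image_id: str = "",
) -> list[Candidate]:
    """Segment every seed of one image; drops failed seeds silently (logged).

    The calibrated channel is lightly median-filtered (3x3) first: window
    thresholding is a pixel-level operation with no averaging, and speckle
    noise otherwise bridges the darkest Otsu region across the window.
    Seeds outside the search region are skipped.
    """
    params = params or SwatParams()
    smoothed = (
        median_filter(np.asarray(calibrated), size=params.presmooth_median)
        if params.presmooth_median > 1
        else np.asarray(calibrated)
    )
    out = []
    for seed in seeds:
        if not s_mask[seed.row, seed.col]:
            continue
        cand = swat_segment(smoothed, seed, s_mask, params, image_id)
        if cand is not None:
            out.append(cand)
    return out
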