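"""Seed-point extraction for prospective hemorrhage candidates.

Hemorrhages are dark blobs surrounded by brighter retina, sharing intensity
with vessels.  An inverted-Gaussian matched filter (negative Gaussian
cross-section swept over orientations) therefore responds strongly at
hemorrhage and vessel centerlines and weakly to smooth intensity variation.
The response is binarized by a co-occurrence (GLCM) quadrant-entropy
threshold, vessels are broken off by an 11x11 morphological opening — the
SE is wider than a vessel but narrower than a hemorrhage — and the
centroids of the surviving components become seed points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from scipy.ndimage import maximum_filter, minimum_filter
from skimage import measure

from .config import MatchedFilterParams
from .core_io import SeedPoint


class DegenerateGlcmError(ValueError):
    """GLCM has fewer than two occupied gray levels; no threshold exists."""


@dataclass
class MatchedFilterBank:
    """Zero-mean inverted-Gaussian kernels at evenly spaced orientations."""

    sigma: float
    length: int
    n_orient: int
    kernels: list[np.ndarray]


@dataclass
class Glcm:
    """Gray-level co-occurrence counts summed over the given offsets."""

    counts: np.ndarray          # levels x levels, float counts
    levels: int
    offsets: list[tuple[int, int]]


def build_bank(sigma: float = 4.0, length: int = 9, n_orient: int = 12) -> MatchedFilterBank:
    """Build the rotated inverted-Gaussian kernel bank.

    The 0-degree kernel is K(x, y) = -exp(-x^2 / (2 sigma^2)) on the support
    |x| <= 3 sigma (across the line), |y| <= (length-1)/2 (along it), sampled
    on a common odd square grid; rotations are taken analytically at
    180/n_orient degree steps, so the 90-degree kernel is exactly the
    transpose of the 0-degree one.  Each kernel is mean-subtracted over its
    support, hence sums to zero and ignores constant offsets in the image.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if length < 3 or length % 2 == 0:
        raise ValueError("length must be odd and >= 3")
    if n_orient < 1:
        raise ValueError("n_orient must be >= 1")
    half_x = 3.0 * sigma
    half_y = (length - 1) / 2.0
    radius = int(np.ceil(max(half_x, half_y)))
    coords = np.arange(-radius, radius + 1, dtype=np.float64)
    # row index = y (along the line at 0 deg), col index = x (across)
    ygrid, xgrid = np.meshgrid(coords, coords, indexing="ij")
    kernels = []
    for k in range(n_orient):
        theta = np.pi * k / n_orient
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        # snap axis-aligned rotations to exact values so that the 90-degree
        # kernel is the exact transpose of the 0-degree kernel
        cos_t = 0.0 if abs(cos_t) < 1e-12 else cos_t
        sin_t = 0.0 if abs(sin_t) < 1e-12 else sin_t
        u = xgrid * cos_t + ygrid * sin_t     # across
        v = -xgrid * sin_t + ygrid * cos_t    # along
        support = (np.abs(u) <= half_x) & (np.abs(v) <= half_y)
        kern = np.zeros_like(xgrid)
        kern[support] = -np.exp(-(u[support] ** 2) / (2.0 * sigma**2))
        kern[support] -= kern[support].mean()
        kernels.append(kern)
    return MatchedFilterBank(sigma, length, n_orient, kernels)


def filter_response(channel: np.ndarray, bank: MatchedFilterBank) -> np.ndarray:
    """Pixel-wise maximum correlation over all orientations (float image).

    Dark line/blob centers yield high positive response; because every
    kernel is zero-mean the response is invariant to adding a constant to
    the input.
    """
    ch = np.asarray(channel, dtype=np.float64)
    pad = bank.kernels[0].shape[0] // 2
    padded = np.pad(ch, pad, mode="reflect")
    resp = None
    for kern in bank.kernels:
        # correlation == convolution with the doubly-flipped kernel;
        # reflect-padding keeps the zero-mean property at the borders
        r = signal.fftconvolve(padded, kern[::-1, ::-1], mode="same")
        r = r[pad: pad + ch.shape[0], pad: pad + ch.shape[1]]
        resp = r if resp is None else np.maximum(resp, r)
    # fftconvolve leaves ~1e-10 ripple on constant inputs; keep it honest
    resp[np.abs(resp) < 1e-8 * (1.0 + np.abs(ch).max())] = 0.0
    return resp


def compute_glcm(
    image: np.ndarray,
    levels: int = 256,
    offsets: list[tuple[int, int]] | None = None,
) -> Glcm:
    """Co-occurrence counts of an integer-quantized image, summed over offsets.

    counts[i, j] is the number of pixel pairs (p, p + offset) whose gray
    levels are (i, j); the default offsets (0,1) and (1,0) count horizontal
    and vertical neighbors once each.
    """
    offsets = offsets or [(0, 1), (1, 0)]
    img = np.asarray(image)
    if img.min() < 0 or img.max() >= levels:
        raise ValueError("image values must lie in [0, levels)")
    img = img.astype(np.int64)
    counts = np.zeros(levels * levels, dtype=np.float64)
    h, w = img.shape
    for dr, dc in offsets:
        src = img[max(0, -dr): h - max(0, dr), max(0, -dc): w - max(0, dc)]
        dst = img[max(0, dr): h + min(0, dr) or h, max(0, dc): w + min(0, dc) or w]
        counts += np.bincount(
            (src * levels + dst).ravel(), minlength=levels * levels
        )
    return Glcm(counts.reshape(levels, levels), levels, list(offsets))


def quadrant_entropies(glcm: Glcm, t: int) -> tuple[float, float]:
    """Shannon entropies (nats) of the BB and FF quadrants at threshold t.

    At threshold t the GLCM splits into background-background {i<=t, j<=t},
    foreground-foreground {i>t, j>t} and the two edge quadrants BF/FB.  Each
    smooth-region quadrant is renormalized to its own mass before taking the
    entropy; an empty quadrant contributes 0.
    """
    p = glcm.counts / glcm.counts.sum()
    bb = p[: t + 1, : t + 1]
    ff = p[t + 1:, t + 1:]

    def _h(q: np.ndarray) -> float:
        m = q.sum()
        if m <= 0:
            return 0.0
        q = q[q > 0] / m
        return float(-(q * np.log(q)).sum())

    return _h(bb), _h(ff)


def quadrant_threshold(glcm: Glcm) -> int:
    """Optimal threshold t* maximizing H_BB(t) + H_FF(t); ties -> smallest t.

    Uses cumulative-sum identities: for a quadrant with mass m and raw
    plogp-sum S, the renormalized entropy is -S/m + log m.  Equivalent to
    (and tested against) the direct per-threshold summation.
    """
    counts = glcm.counts
    total = counts.sum()
    if total <= 0:
        raise DegenerateGlcmError("empty GLCM")
    occupied_levels = np.flatnonzero(
        (counts.sum(axis=0) + counts.sum(axis=1)) > 0
    )
    if occupied_levels.size < 2:
        raise DegenerateGlcmError("GLCM has a single occupied gray level")
    p = counts / total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    cmass = p.cumsum(axis=0).cumsum(axis=1)
    cplogp = plogp.cumsum(axis=0).cumsum(axis=1)
    n = glcm.levels
    ts = np.arange(n - 1)
    m_bb = cmass[ts, ts]
    s_bb = cplogp[ts, ts]
    m_ff = 1.0 - cmass[ts, -1] - cmass[-1, ts] + m_bb
    s_ff = cplogp[-1, -1] - cplogp[ts, -1] - cplogp[-1, ts] + s_bb
    m_ff = np.maximum(m_ff, 0.0)

    def _entropy(s: np.ndarray, m: np.ndarray) -> np.ndarray:
        h = np.zeros_like(m)
        pos = m > 1e-15
        h[pos] = -s[pos] / m[pos] + np.log(m[pos])
        return h

    score = _entropy(s_bb, m_bb) + _entropy(s_ff, m_ff)
    return int(np.argmax(score))   # argmax returns the smallest tied index


def _sqrt_scale(response: np.ndarray) -> np.ndarray:
    """Square-root compression of the positive response tail.

    Matched-filter responses are heavy-tailed: a handful of high-contrast
    structures (dark vessels crossing the bright optic disc) would otherwise
    claim most of a uniform quantization's levels and drag every threshold
    above the lesion responses.  Negative responses — bright-object edges —
    can never be dark-object centers and are clipped to zero.
    """
    return np.sqrt(np.clip(response, 0.0, None))


def _raw_threshold(values: np.ndarray, levels: int) -> float | None:
    """Quadrant-entropy threshold of a float array, in the array's own units.

    The array is min-max quantized to `levels` gray levels so the GLCM
    threshold always works at full resolution, and t* is mapped back to raw
    units.  Returns None for degenerate (near-constant) input.
    """
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return None
    q = np.round((values - lo) / (hi - lo) * (levels - 1)).astype(np.int64)
    try:
        t_q = quadrant_threshold(compute_glcm(q, levels))
    except DegenerateGlcmError:
        return None
    return lo + t_q * (hi - lo) / (levels - 1)


def local_threshold_map(
    scaled: np.ndarray, levels: int, tile_size: int
) -> np.ndarray | None:
    """Sliding-window local threshold map (minimum over covering windows).

    Windows of side `tile_size` at half-window stride each contribute their
    own quadrant-entropy threshold (computed at full quantization resolution
    in the window's own range); every pixel takes the minimum over the
    windows covering it, with degenerate windows falling back to the
    whole-image threshold.  Local thresholding keeps one extreme-contrast
    structure — typically the optic disc with vessels crossing it — from
    raising the threshold past every lesion elsewhere; the minimum favors
    recall, leaving the downstream opening and classifier to discard the
    extra structure.
    """
    resp = np.asarray(scaled, dtype=np.float64)
    h, w = resp.shape
    t_global = _raw_threshold(resp, levels)
    if t_global is None:
        return None
    if tile_size >= max(h, w):
        return np.full((h, w), t_global)
    stride = max(tile_size // 2, 1)
    t_map = np.full((h, w), np.inf)
    for r_off in (0, -stride):
        for c_off in (0, -stride):
            for r0 in range(r_off, h, tile_size):
                top, bot = max(r0, 0), min(r0 + tile_size, h)
                if bot <= top:
                    continue
                for c0 in range(c_off, w, tile_size):
                    left, right = max(c0, 0), min(c0 + tile_size, w)
                    if right <= left:
                        continue
                    t = _raw_threshold(resp[top:bot, left:right], levels)
                    t = t_global if t is None else t
                    t_map[top:bot, left:right] = np.minimum(
                        t_map[top:bot, left:right], t
                    )
    t_map[np.isinf(t_map)] = t_global
    return t_map


def extract_seeds(
    response: np.ndarray,
    opening_size: int = 11,
    levels: int = 256,
    tile_size: int | None = 64,
) -> list[SeedPoint]:
    """Seeds from a matched-filter response image.

    The positive response, on a square-root scale, is binarized by the GLCM
    quadrant-entropy threshold t* (keep response > t*, the high responses of
    dark objects) — computed per sliding local window of side `tile_size`,
    or once for the whole image when tile_size is None.  Enclosed holes are
    filled (a matched filter responds as a ring on blobs wider than its
    kernel), then strictly negative-response pixels are re-punched: the
    kernel's negative flanks trace the vessels, so this cut is what
    isolates vessel-attached lesions.  A square opening of side
    `opening_size` removes structures thinner than the SE (vessels); seeds
    are the centroids of the 8-connected erosion cores — the vessel stub a
    surviving component may drag along vanishes under erosion, so the core
    centroid stays on the blob — rounded to the nearest pixel.
    """
    resp = np.asarray(response, dtype=np.float64)
    scaled = _sqrt_scale(resp)
    if tile_size is None:
        t_scalar = _raw_threshold(scaled, levels)
        t_map = None if t_scalar is None else np.full(resp.shape, t_scalar)
    else:
        t_map = local_threshold_map(scaled, levels, tile_size)
    if t_map is None:
        return []
    # thresholds never dip below zero response: an inverted-Gaussian kernel
    # is positive only at dark-object centers
    t_map = np.maximum(t_map, 0.0)
    binary = ndimage.binary_fill_holes(scaled > t_map) & (resp > 0)
    core = minimum_filter(binary, size=opening_size)
    labeled = measure.label(core, connectivity=2)
    seeds = []
    for region in measure.regionprops(labeled):
        r, c = region.centroid
        seeds.append(
            SeedPoint(int(round(r)), int(round(c)), int(region.area))
        )
    return seeds


def opened_mask(
    response: np.ndarray,
    opening_size: int = 11,
    levels: int = 256,
    tile_size: int | None = 64,
) -> np.ndarray:
    """The post-opening binary map behind :func:`extract_seeds` (debugging)."""
    resp = np.asarray(response, dtype=np.float64)
    scaled = _sqrt_scale(resp)
    if tile_size is None:
        t_scalar = _raw_threshold(scaled, levels)
        t_map = None if t_scalar is None else np.full(resp.shape, t_scalar)
    else:
        t_map = local_threshold_map(scaled, levels, tile_size)
    if t_map is None:
        return np.zeros(resp.shape, dtype=bool)
    t_map = np.maximum(t_map, 0.0)
    binary = ndimage.binary_fill_holes(scaled > t_map) & (resp > 0)
    return maximum_filter(
        minimum_filter(binary, size=opening_size), size=opening_size
    )


def seeds_from_channel(
    channel: np.ndarray, params: MatchedFilterParams | None = None
) -> tuple[list[SeedPoint], np.ndarray]:
    """Convenience chain: bank -> response -> seeds.  Returns (seeds, response)."""
    params = params or MatchedFilterParams()
    bank = build_bank(params.sigma, params.length, params.n_orient)
    resp = filter_response(channel, bank)
    found = extract_seeds(
        resp, params.opening_size, params.glcm_levels, params.threshold_tile
    )
    return found, resp
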