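"""Quality enhancement: CLAHE, gradient-adaptive gamma, nonlinear unsharp mask.

The adaptive gamma rule reads the overall sharpness of a channel from its
Sobel gradient: phi is the Otsu threshold separating smooth regions from
edges in the normalized gradient-magnitude image, taken as a brightness
interpretation of the channel.  The correction exponent is then

    gamma = alpha * floor(phi * 100) / 10,        alpha = 2 by default

applied as the power law V = Imax * (I / Imax) ** gamma per channel.  A large
phi (sharp, well-exposed channel) yields strong gamma > 1 compression of an
already-bright image; phi near zero leaves the channel nearly untouched.
Note gamma is deliberately not clamped: phi -> 1 can drive gamma up to
2 * alpha * 10, which saturates dark content; callers who need a cap should
bound alpha.

The green channel — the channel carrying most hemorrhage contrast — is
additionally sharpened with a saturating nonlinear unsharp mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from skimage import exposure, filters

from .config import EnhanceParams

IMAX = 255.0


@dataclass
class EnhancedImage:
    """Enhanced RGB image plus the per-channel phi and gamma actually applied.

    `pixels` is the 8-bit rendering for I/O and display; `float_pixels`
    keeps the un-rounded [0, 255] float values, which downstream stages use
    because a large gamma can compress the retinal intensity mass into a
    few 8-bit levels.
    """

    pixels: np.ndarray                     # uint8, HxWx3
    gamma_per_channel: tuple[float, float, float]
    phi_per_channel: tuple[float, float, float]
    float_pixels: np.ndarray | None = None  # float64, HxWx3, [0, 255]

    @property
    def green(self) -> np.ndarray:
        return self.pixels[:, :, 1]

    @property
    def green_float(self) -> np.ndarray:
        if self.float_pixels is None:
            return self.pixels[:, :, 1].astype(np.float64)
        return self.float_pixels[:, :, 1]


def clahe_enhance(image: np.ndarray, params: EnhanceParams | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, per channel.

    Accepts an 8-bit RGB image (or a single channel) and returns the same
    shape/dtype.  Channels with no contrast pass through unchanged.
    """
    params = params or EnhanceParams()
    img = np.asarray(image)
    single = img.ndim == 2
    chans = [img] if single else [img[:, :, c] for c in range(img.shape[2])]
    out = []
    ksize = max(8, min(img.shape[0], img.shape[1]) // params.clahe_tiles)
    for ch in chans:
        if ch.max() == ch.min():
            out.append(ch.copy())
            continue
        eq = exposure.equalize_adapthist(
            ch, kernel_size=ksize, clip_limit=params.clahe_clip
        )
        out.append(np.round(eq * IMAX).astype(np.uint8))
    return out[0] if single else np.stack(out, axis=-1)


def estimate_phi(channel: np.ndarray) -> float:
    """Otsu threshold of the Sobel gradient-magnitude image, in [0, 1].

    `channel` is a single channel scaled to [0, 1], so its Sobel magnitude
    already lives in [0, 1] (a full 0-to-1 step has magnitude 1); the Otsu
    threshold separating smooth regions from edges is therefore directly
    the brightness/sharpness interpretation phi.  Dividing by the observed
    maximum instead would tie phi to the single strongest edge in the image
    and push the correction exponent far from 1 on ordinary images.  A
    constant channel has zero gradient everywhere and returns phi = 0 by
    convention.
    """
    ch = np.asarray(channel, dtype=np.float64)
    grad = filters.sobel(ch)
    if grad.max() <= 0 or np.unique(grad).size < 2:
        return 0.0
    return float(min(filters.threshold_otsu(grad), 1.0))


def gamma_from_phi(phi: float, alpha: float = 2.0) -> float:
    """gamma = alpha * floor(phi * 100) / 10 (exact, including the floor)."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must be in [0, 1], got {phi}")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return alpha * math.floor(phi * 100.0) / 10.0


def apply_gamma(channel: np.ndarray, gamma: float, imax: float = IMAX) -> np.ndarray:
    """Power-law brightness mapping V = imax * (I / imax) ** gamma.

    Monotone non-decreasing in the input for every gamma >= 0; imax is a
    fixed point.  gamma = 0 maps every nonzero intensity to imax (and 0 to 0);
    this degenerate-but-defined case is allowed.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    ch = np.asarray(channel, dtype=np.float64)
    if gamma == 0:
        return np.where(ch > 0, imax, 0.0)
    return imax * (ch / imax) ** gamma


def adaptive_gamma(
    image: np.ndarray, params: EnhanceParams | None = None
) -> EnhancedImage:
    """Per-channel gradient-adaptive gamma correction of an RGB image.

    Each channel gets its own phi (from its own gradient) and hence its own
    gamma; both are recorded on the returned :class:`EnhancedImage`.
    """
    params = params or EnhanceParams()
    img = np.asarray(image, dtype=np.float64)
    gammas, phis, chans = [], [], []
    for c in range(3):
        ch = img[:, :, c]
        phi = estimate_phi(ch / IMAX)
        gamma = gamma_from_phi(phi, params.alpha)
        chans.append(apply_gamma(ch, gamma))
        phis.append(phi)
        gammas.append(gamma)
    float_pixels = np.clip(np.stack(chans, axis=-1), 0.0, 255.0)
    pixels = np.round(float_pixels).astype(np.uint8)
    return EnhancedImage(pixels, tuple(gammas), tuple(phis), float_pixels)


def unsharp_green_float(
    green: np.ndarray, params: EnhanceParams | None = None
) -> np.ndarray:
    """Float version of :func:`unsharp_green` (no 8-bit rounding)."""
    params = params or EnhanceParams()
    ch = np.asarray(green, dtype=np.float64)
    d = ch - uniform_filter(ch, size=3, mode="reflect")
    sat = params.unsharp_saturation
    theta = params.unsharp_noise_floor
    gate = d * d / (d * d + theta * theta) if theta > 0 else 1.0
    boost = params.unsharp_gain * sat * np.tanh(d / sat) * gate
    return np.clip(ch + boost, 0.0, 255.0)


def unsharp_green(
    green: np.ndarray, params: EnhanceParams | None = None
) -> np.ndarray:
    """Fuzzy-style nonlinear unsharp mask of a single channel.

    For each pixel, d = center - mean of its 3x3 neighborhood; the output is
    clip(center + gain * s(d)) with the odd, saturating nonlinearity

        s(d) = saturation * tanh(d / saturation) * d^2 / (d^2 + theta^2).

    The tanh saturates large luminance differences (no ringing past the
    8-bit range); the d^2 / (d^2 + theta^2) gate suppresses differences
    small against the sensor-noise floor theta, so genuine edges sharpen
    while pixel noise is left nearly untouched — the behavior fuzzy
    luminance-difference sharpening rules are built for.
    """
    return np.round(unsharp_green_float(green, params)).astype(np.uint8)


def enhance_image(
    image: np.ndarray, params: EnhanceParams | None = None
) -> EnhancedImage:
    """Full quality-enhancement chain: CLAHE -> adaptive gamma -> unsharp green."""
    params = params or EnhanceParams()
    cl = clahe_enhance(image, params)
    enh = adaptive_gamma(cl, params)
    float_pixels = enh.float_pixels.copy()
    float_pixels[:, :, 1] = unsharp_green_float(float_pixels[:, :, 1], params)
    pixels = np.round(float_pixels).astype(np.uint8)
    return EnhancedImage(
        pixels, enh.gamma_per_channel, enh.phi_per_channel, float_pixels
    )
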