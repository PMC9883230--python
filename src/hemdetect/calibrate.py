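"""Retinal mask, rim, bright-background calibration, and the search region S.

Hemorrhages at the retinal rim blend into the black camera background, which
carries no information but misleads dark-object detection.  Calibration
replaces the background (and the dark rim transition band) with the average
retinal gray so rim lesions sit on a bright field like everywhere else.  The
search region S — the retinal mask dilated 80 pixels in every direction —
bounds all subsequent window growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure
from skimage.filters import rank
from skimage.morphology import convex_hull_image

from .config import CalibrationParams


class EmptyMaskError(ValueError):
    """No retinal disc found (e.g. an all-black image)."""


@dataclass
class CalibratedImage:
    """Single-channel image with background filled by the mean retinal gray.

    `pixels` is the 8-bit rendering; `pixels_float` keeps the un-rounded
    values so a heavily gamma-compressed channel loses no contrast before
    matched filtering and window thresholding.
    """

    pixels: np.ndarray   # uint8
    mean_gray: float
    pixels_float: np.ndarray | None = None


@dataclass
class SearchRegion:
    mask: np.ndarray     # bool
    extension: int


def retinal_mask(
    green: np.ndarray, params: CalibrationParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Retinal disc mask and rim band from the raw green channel.

    The green channel is median-filtered (suppressing background speckle),
    binarized with Otsu's threshold, reduced to its largest connected
    component, and convex-hulled: the camera field of view is convex, and
    the hull reclaims dark lesions at the rim that thresholding would
    otherwise carve out of the disc (a notch open to the background is not
    a fillable hole).  The rim is the mask minus its erosion by a square of
    side `erosion_size` — a band of roughly erosion_size/2 pixels hugging
    the retinal boundary.
    """
    params = params or CalibrationParams()
    g = np.asarray(green)
    if g.dtype != np.uint8:
        g = np.clip(g, 0, 255).astype(np.uint8)
    med = rank.median(g, footprint=np.ones((params.median_size,) * 2, bool))
    if med.max() == med.min():
        raise EmptyMaskError("constant image: no retinal disc found")
    mask = med > filters.threshold_otsu(med)
    if not mask.any():
        raise EmptyMaskError("binarization produced an empty mask")
    labeled = measure.label(mask, connectivity=2)
    largest = np.argmax(np.bincount(labeled.ravel())[1:]) + 1
    mask = convex_hull_image(labeled == largest)
    rim = mask & ~ndimage.binary_erosion(
        mask, structure=np.ones((params.erosion_size,) * 2, bool)
    )
    return mask, rim


def calibrate_image(
    green_enhanced: np.ndarray, mask: np.ndarray, rim: np.ndarray
) -> CalibratedImage:
    """Bright-background calibrated image.

    Background (complemented mask) and the rim band are set to mean_gray,
    the average enhanced-green intensity over the retinal interior
    (mask minus rim); interior pixels keep their enhanced value.  Averaging
    over the interior only makes the operation idempotent: re-calibrating
    the output with the same masks reproduces it exactly.
    """
    g = np.asarray(green_enhanced, dtype=np.float64)
    interior = mask & ~rim
    if not interior.any():
        raise EmptyMaskError("mask interior is empty")
    mean_gray = float(g[interior].mean())
    out = np.clip(np.where(interior, g, mean_gray), 0.0, 255.0)
    return CalibratedImage(
        np.round(out).astype(np.uint8), mean_gray, out
    )


def search_region(mask: np.ndarray, extension: int = 80) -> SearchRegion:
    """S = retinal mask dilated by a square of side 2*extension+1.

    Square (Chebyshev) dilation extends the mask `extension` pixels in every
    direction, clipped at the image borders; extension 0 returns the mask.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    dilated = ndimage.maximum_filter(
        mask.astype(np.uint8), size=2 * extension + 1
    ).astype(bool)
    return SearchRegion(dilated, extension)
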