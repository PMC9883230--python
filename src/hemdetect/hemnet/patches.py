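"""Patch channel composition and candidate labeling.

The classifier does not see raw RGB: each candidate window is resized to
256x256 and recomposed from the three channels that carry hemorrhage
contrast in conventional feature pipelines — the RGB green channel, the HSV
value channel, and the CIE-Lab luminance L — each rescaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color, transform

from ..core_io import Candidate

PATCH_SIZE = 256


@dataclass
class PatchRecord:
    tensor: np.ndarray       # (256, 256, 3) float32: G, HSV-V, Lab-L in [0,1]
    label: int               # 1 = hemorrhage, 0 = not
    image_id: str = ""
    box: tuple[int, int, int, int] | None = None


def compose_channels(rgb_patch: np.ndarray, size: int = PATCH_SIZE) -> np.ndarray:
    """(any H, W, 3) RGB patch -> (size, size, 3) float32 composed tensor.

    The patch is resized with bilinear interpolation; channel 0 is green,
    channel 1 the HSV value max(R,G,B), channel 2 the CIE-Lab L (sRGB, D65)
    rescaled from [0, 100] to [0, 1].
    """
    patch = np.asarray(rgb_patch)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError(f"expected an RGB patch, got shape {patch.shape}")
    rgb = patch.astype(np.float64)
    if patch.dtype == np.uint8:
        rgb = rgb / 255.0
    rgb = np.clip(rgb, 0.0, 1.0)
    if rgb.shape[:2] != (size, size):
        rgb = transform.resize(
            rgb, (size, size), order=1, preserve_range=True,
            anti_aliasing=rgb.shape[0] > size,
        )
    out = np.empty((size, size, 3), dtype=np.float32)
    out[:, :, 0] = rgb[:, :, 1]
    out[:, :, 1] = rgb.max(axis=2)
    out[:, :, 2] = color.rgb2lab(rgb)[:, :, 0] / 100.0
    return np.clip(out, 0.0, 1.0)


def compose_channels_u8(rgb_patch: np.ndarray, size: int = PATCH_SIZE) -> np.ndarray:
    """Composed tensor quantized to uint8 (compact storage for datasets)."""
    return np.round(compose_channels(rgb_patch, size) * 255).astype(np.uint8)


def label_candidates(
    candidates: list[Candidate],
    gt_mask: np.ndarray,
    min_overlap: float = 0.5,
) -> list[Candidate]:
    """Label each candidate HE iff its object overlaps the ground truth enough.

    A candidate is a hemorrhage when |object & gt| / |object| >= min_overlap
    (boundary inclusive).  Candidates are labeled in place and returned.
    """
    gt = np.asarray(gt_mask, dtype=bool)
    for cand in candidates:
        if cand.object_mask is None:
            raise ValueError("candidate has no object mask to label")
        area = int(cand.object_mask.sum())
        inter = int((cand.object_mask & gt).sum())
        cand.label = "HE" if area > 0 and inter / area >= min_overlap else "non-HE"
    return candidates
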