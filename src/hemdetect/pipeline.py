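"""End-to-end hemorrhage detection: enhance -> calibrate -> seeds -> SWAT -> classify."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import calibrate as cal
from . import enhance, hemnet, seeds as seedmod
from .config import Config
from .core_io import Candidate, FundusImage
from .hemnet.model import HemNet


@dataclass
class DetectionResult:
    candidates: list[Candidate]
    enhanced: enhance.EnhancedImage
    calibrated: cal.CalibratedImage
    retina_mask: np.ndarray
    search_mask: np.ndarray
    seeds: list


def detect(
    image: FundusImage | np.ndarray,
    config: Config | None = None,
    model: HemNet | None = None,
    image_id: str = "",
) -> DetectionResult:
    """Run the full detection pipeline on one fundus image.

    Stages: quality enhancement (CLAHE, adaptive gamma, unsharp green);
    retinal mask + bright-background calibration of the enhanced green
    channel; matched-filter seed extraction on the calibrated channel
    (the bright background removes the spurious rim-edge response, which
    is the stated purpose of calibration); SWAT segmentation per seed
    inside the search region; optional HemNet scoring of every candidate
    window cut from the enhanced color image.
    """
    config = config or Config()
    pixels = image.pixels if isinstance(image, FundusImage) else np.asarray(image)

    enhanced = enhance.enhance_image(pixels, config.enhancement)
    raw_green = pixels[:, :, 1]
    mask, rim = cal.retinal_mask(raw_green, config.calibration)
    calibrated = cal.calibrate_image(enhanced.green_float, mask, rim)
    region = cal.search_region(mask, config.calibration.search_extension)

    seed_points, _resp = seedmod.seeds_from_channel(
        calibrated.pixels_float, config.matched_filter
    )
    seed_points = [s for s in seed_points if region.mask[s.row, s.col]]

    from .swat import segment_seeds

    candidates = segment_seeds(
        calibrated.pixels_float, seed_points, region.mask, config.swat, image_id
    )

    if model is not None and candidates:
        # patches are composed from the raw color image: classifier training
        # patches come from the same distribution (generator windows)
        tensors = np.stack(
            [
                hemnet.compose_channels_u8(pixels[c.box.slices])
                for c in candidates
            ]
        )
        scores = hemnet.predict(model, tensors)
        for cand, score in zip(candidates, np.atleast_1d(scores)):
            cand.score = float(score)

    return DetectionResult(
        candidates=candidates,
        enhanced=enhanced,
        calibrated=calibrated,
        retina_mask=mask,
        search_mask=region.mask,
        seeds=seed_points,
    )
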