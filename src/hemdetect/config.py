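"""Configuration schema and YAML loading.

Every stage of the pipeline reads its parameters from one of the dataclasses
below.  Defaults are the pipeline's published operating point: brightness
coefficient alpha = 2, an 11x11 opening structuring element, effectiveness
threshold 0.8 with a 20-region cap, an 80-pixel search-region extension,
window growth steps of 5 (left/top) and 10 (right/bottom), and 256x256
classifier patches.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    """Raised for unknown keys or malformed configuration files."""


@dataclass
class EnhanceParams:
    """Quality-enhancement stage parameters.

    alpha is the brightness adjustment coefficient of the adaptive gamma
    rule gamma = alpha * floor(phi * 100) / 10.  clahe_clip is the CLAHE
    clip limit as a fraction of tile pixel count; clahe_tiles the tile grid
    side.  unsharp_gain and unsharp_saturation (8-bit intensity units)
    control the saturating nonlinear unsharp mask on the green channel.
    """

    alpha: float = 2.0
    clahe_clip: float = 0.01
    clahe_tiles: int = 8
    unsharp_gain: float = 1.5
    unsharp_saturation: float = 30.0
    unsharp_noise_floor: float = 4.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ConfigError("alpha must be > 0")
        if not 0 < self.clahe_clip <= 1:
            raise ConfigError("clahe_clip must be in (0, 1]")


@dataclass
class MatchedFilterParams:
    """Inverted-Gaussian matched filter bank and seed extraction."""

    sigma: float = 4.0       # Gaussian scale across the line, pixels
    length: int = 9          # kernel support along the line, pixels (odd)
    n_orient: int = 12       # rotations over 180 degrees
    opening_size: int = 11   # square SE side for morphological opening
    glcm_levels: int = 256   # quantization for the co-occurrence threshold
    threshold_tile: int | None = 64  # local-threshold window side; None = global


@dataclass
class CalibrationParams:
    """Retinal mask / bright-background calibration / search region."""

    median_size: int = 25       # median filter side on the raw green channel
    erosion_size: int = 10      # rim band width via square erosion
    search_extension: int = 80  # dilation of the retinal mask, pixels


@dataclass
class SwatParams:
    """Smart window-based adaptive thresholding."""

    init_size: int = 61
    eta_min: float = 0.8
    rho_cap: int = 20
    step_small: int = 5     # left/top growth step
    step_large: int = 10    # right/bottom growth step
    max_iter: int = 50
    min_window: int = 16    # windows narrower than this are padded out
    symmetric_growth: bool = False
    presmooth_median: int = 3  # median filter on the channel before windowing


@dataclass
class TrainingParams:
    lr: float = 0.01
    epochs: int = 15
    batch_size: int = 32
    momentum: float = 0.9
    val_fraction: float = 0.1
    patch_size: int = 256


@dataclass
class GeneratorParams:
    """Synthetic fundus generator defaults (see synthfundus.FundusSpec)."""

    image_size: int = 768
    retina_radius: int = 340
    n_hemorrhages: int = 6
    he_size_min: float = 8.0
    he_size_max: float = 25.0
    n_vessels: int = 9
    vessel_width_min: float = 3.0
    vessel_width_max: float = 9.0
    illumination_gradient: float = 0.2
    noise_sd: float = 4.0
    optic_disc: bool = True
    rim_he_fraction: float = 0.25
    vessel_attached_fraction: float = 0.25


@dataclass
class Config:
    enhancement: EnhanceParams = field(default_factory=EnhanceParams)
    matched_filter: MatchedFilterParams = field(default_factory=MatchedFilterParams)
    calibration: CalibrationParams = field(default_factory=CalibrationParams)
    swat: SwatParams = field(default_factory=SwatParams)
    training: TrainingParams = field(default_factory=TrainingParams)
    generator: GeneratorParams = field(default_factory=GeneratorParams)


def _build_section(cls: type, data: Mapping[str, Any], section: str) -> Any:
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{section}'; "
            f"valid keys: {sorted(valid)}"
        )
    return cls(**data)


def load_config(path: str | Path | None = None) -> Config:
    """Load a YAML configuration file; absent keys get documented defaults.

    The file maps section names (enhancement, matched_filter, calibration,
    swat, training, generator) to flat key/value mappings.  An empty or
    missing file yields all defaults.  Unknown sections or keys raise
    :class:`ConfigError` naming the offending key and the valid choices.
    """
    if path is None:
        return Config()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return Config()
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration root must be a mapping of sections")
    sections = {f.name: f for f in dataclasses.fields(Config)}
    unknown = set(raw) - set(sections)
    if unknown:
        raise ConfigError(
            f"unknown section(s) {sorted(unknown)}; "
            f"valid sections: {sorted(sections)}"
        )
    kwargs = {}
    for name, fld in sections.items():
        data = raw.get(name, {})
        if not isinstance(data, Mapping):
            raise ConfigError(f"section '{name}' must be a mapping")
        kwargs[name] = _build_section(fld.default_factory, data, name)  # type: ignore[misc]
    return Config(**kwargs)
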