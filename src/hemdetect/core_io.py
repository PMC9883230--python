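"""Image/annotation I/O, coordinate conventions, and shared record types.

Coordinate convention, used everywhere in the package: (row, col), 0-based.
Bounding boxes are inclusive on both ends and stored as
(v1, v2, v3, v4) = (left col, top row, right col, bottom row).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd


class ImageValidationError(ValueError):
    """Input image violates a structural invariant (size, channels)."""


MIN_SIDE = 64

CANDIDATE_COLUMNS = [
    "image_id", "v1", "v2", "v3", "v4",
    "seed_row", "seed_col", "score", "label",
]


@dataclass
class FundusImage:
    """8-bit RGB fundus image (height x width x 3, channel order R,G,B)."""

    pixels: np.ndarray
    path: str = ""

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3:
            raise ImageValidationError(f"expected HxWx3 array, got {p.shape}")
        if p.shape[0] < MIN_SIDE or p.shape[1] < MIN_SIDE:
            raise ImageValidationError(
                f"image {p.shape[0]}x{p.shape[1]} smaller than "
                f"{MIN_SIDE}x{MIN_SIDE}"
            )
        if p.dtype != np.uint8:
            raise ImageValidationError(f"expected uint8 pixels, got {p.dtype}")

    @property
    def green(self) -> np.ndarray:
        return self.pixels[:, :, 1]


@dataclass(frozen=True)
class Box:
    """Inclusive bounding box: v1=left, v2=top, v3=right, v4=bottom."""

    v1: int
    v2: int
    v3: int
    v4: int

    def __post_init__(self) -> None:
        if not (0 <= self.v1 <= self.v3 and 0 <= self.v2 <= self.v4):
            raise ValueError(f"invalid box {self}")

    @property
    def height(self) -> int:
        return self.v4 - self.v2 + 1

    @property
    def width(self) -> int:
        return self.v3 - self.v1 + 1

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.v2, self.v4 + 1), slice(self.v1, self.v3 + 1)

    def clipped(self, height: int, width: int) -> "Box":
        return Box(
            max(self.v1, 0), max(self.v2, 0),
            min(self.v3, width - 1), min(self.v4, height - 1),
        )


@dataclass(frozen=True)
class SeedPoint:
    """Prospective hemorrhage location (component centroid, pixel indices)."""

    row: int
    col: int
    component_area: int = 0


@dataclass
class Candidate:
    """Final segmented candidate: box, object mask, seed, classifier score."""

    box: Box
    seed: SeedPoint
    object_mask: np.ndarray | None = None  # bool, image frame
    distance: float = 0.0                  # seed-to-object centroid, pixels
    score: float = float("nan")            # p(hemorrhage) once classified
    label: str = ""                        # "HE" / "non-HE" / ""
    image_id: str = ""


def read_image(path: str | Path) -> FundusImage:
    """Read an 8-bit PNG/TIFF/JPEG as RGB; grayscale is promoted by replication."""
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises assorted backend errors
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageValidationError(f"unsupported image shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return FundusImage(pixels=arr, path=str(path))


def write_image(arr: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(arr, dtype=np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Single-channel PNG mask; nonzero pixels are foreground."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    write_image(np.where(mask, 255, 0).astype(np.uint8), path)


def write_candidates(candidates: Sequence[Candidate], path: str | Path) -> None:
    """Write candidates to CSV (boxes/seeds round-trip bit-exactly)."""
    rows = [
        {
            "image_id": c.image_id,
            "v1": c.box.v1, "v2": c.box.v2, "v3": c.box.v3, "v4": c.box.v4,
            "seed_row": c.seed.row, "seed_col": c.seed.col,
            "score": c.score, "label": c.label,
        }
        for c in candidates
    ]
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_candidates(path: str | Path) -> list[Candidate]:
    df = pd.read_csv(path, keep_default_na=False, na_values=["nan", ""])
    out: list[Candidate] = []
    for rec in df.itertuples(index=False):
        out.append(
            Candidate(
                box=Box(int(rec.v1), int(rec.v2), int(rec.v3), int(rec.v4)),
                seed=SeedPoint(int(rec.seed_row), int(rec.seed_col)),
                score=float(rec.score),
                label=str(rec.label) if not pd.isna(rec.label) else "",
                image_id=str(rec.image_id) if not pd.isna(rec.image_id) else "",
            )
        )
    return out
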