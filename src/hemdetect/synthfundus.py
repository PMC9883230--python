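"""Synthetic fundus image generator with exact ground-truth masks.

Emulates the structure the detection pipeline assumes in a color fundus
photograph: a reddish-orange retinal disc on a black camera background,
dark branching vessels radiating from a bright optic disc, dark irregular
hemorrhage blobs (some hugging the retinal rim, some attached to vessels),
a smooth nonuniform illumination field, and additive sensor noise.  Every
structure is rasterized from known geometry, so the hemorrhage / vessel /
retina masks are exact, and everything is a pure function of the spec's RNG
seed.  No photorealism is attempted — the generator exists to make every
pipeline stage testable without external image downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import draw

from .hemnet.patches import compose_channels_u8

RETINA_RGB = (180.0, 90.0, 40.0)
VESSEL_FACTOR = (0.55, 0.35, 0.50)   # multiplicative darkening per channel
HE_FACTOR = (0.45, 0.25, 0.45)       # hemorrhages darken green the most
DISC_RGB = (245.0, 205.0, 130.0)


class PlacementError(RuntimeError):
    """Could not place a structure under the spec's constraints."""


@dataclass(frozen=True)
class FundusSpec:
    """Generator parameters; the defaults are the package's study conditions.

    Sizes are in pixels.  he_size_range bounds the hemorrhage ellipse
    semi-axes; rim_he_fraction of the lesions are planted within 15 px of
    the retinal rim and vessel_attached_fraction are centered on a vessel.
    """

    image_size: int = 768
    retina_radius: int = 340
    n_hemorrhages: int = 6
    he_size_range: tuple[float, float] = (8.0, 25.0)
    n_vessels: int = 9
    vessel_width_range: tuple[float, float] = (3.0, 9.0)
    illumination_gradient: float = 0.2
    noise_sd: float = 4.0
    optic_disc: bool = True
    rim_he_fraction: float = 0.25
    vessel_attached_fraction: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.retina_radius < self.image_size / 2:
            raise ValueError("retina_radius must be < image_size / 2")
        for frac in (self.rim_he_fraction, self.vessel_attached_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class HemorrhageRecord:
    center: tuple[float, float]          # (row, col)
    axes: tuple[float, float]            # semi-axes (a >= b)
    angle: float                         # radians
    mask: np.ndarray = field(repr=False)  # exact support, image frame


@dataclass
class SyntheticSample:
    image: np.ndarray                    # uint8 HxWx3 RGB
    retina_mask: np.ndarray
    vessel_mask: np.ndarray
    he_mask: np.ndarray
    he_records: list[HemorrhageRecord]
    spec: FundusSpec


def _irregular_ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
    rng: np.random.Generator,
    wobble: float = 0.12,
    n_vertices: int = 72,
) -> np.ndarray:
    """Ellipse support with a smooth periodic radial perturbation."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    a, b = axes
    r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    pert = np.zeros_like(theta)
    for harmonic in (2, 3, 4):
        pert += rng.normal(0, 1) * np.cos(harmonic * theta) + rng.normal(
            0, 1
        ) * np.sin(harmonic * theta)
    pert /= max(np.abs(pert).max(), 1e-9)
    r = r * (1.0 + wobble * pert)
    rows = center[0] + r * np.sin(theta + angle)
    cols = center[1] + r * np.cos(theta + angle)
    rr, cc = draw.polygon(rows, cols, shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _draw_vessels(
    shape: tuple[int, int],
    origin: tuple[float, float],
    n_vessels: int,
    width_range: tuple[float, float],
    retina: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random recursive branching polylines stamped as disks."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)

    def walk(pos: np.ndarray, heading: float, width: float, length: float, depth: int) -> None:
        step = 2.0
        traveled = 0.0
        while traveled < length:
            pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
            traveled += step
            r, c = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= r < h and 0 <= c < w) or not retina[r, c]:
                return
            rr, cc = draw.disk((r, c), max(width / 2.0, 1.0), shape=shape)
            mask[rr, cc] = True
            heading += rng.normal(0.0, 0.08)
            if depth < 2 and rng.random() < 0.015:
                walk(
                    pos.copy(),
                    heading + rng.choice([-1, 1]) * rng.uniform(0.4, 0.9),
                    max(width * 0.7, 1.5),
                    length * 0.5,
                    depth + 1,
                )

    # vessels emerge around the optic disc rim (not one point: a common
    # origin would stack them into a solid hub no opening could break)
    disc_r = 0.16 * min(h, w) / 2.0
    for i in range(n_vessels):
        phi = 2.0 * np.pi * i / n_vessels + rng.normal(0.0, 0.25)
        start = np.array(
            [origin[0] + disc_r * np.sin(phi), origin[1] + disc_r * np.cos(phi)]
        )
        heading = phi + rng.normal(0.0, 0.3)
        width = rng.uniform(*width_range)
        length = rng.uniform(0.7, 1.1) * min(h, w) / 2.0
        walk(start, heading, width, length, 0)
    return mask & retina


def generate_fundus(spec: FundusSpec) -> SyntheticSample:
    """Render one synthetic fundus sample, deterministic in spec.rng_seed."""
    rng = np.random.default_rng(spec.rng_seed)
    size = spec.image_size
    center = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dist = np.hypot(yy - center, xx - center)
    retina = dist <= spec.retina_radius

    img = np.zeros((size, size, 3), dtype=np.float64)
    texture = gaussian_filter(rng.normal(0.0, 10.0, (size, size)), 8.0)
    for c, base in enumerate(RETINA_RGB):
        img[:, :, c] = np.where(retina, base + texture, 0.0)

    # optic disc: bright ellipse offset from center; vessels radiate from it
    disc_center = (
        center + 0.1 * spec.retina_radius * rng.normal(),
        center + rng.choice([-1, 1]) * 0.55 * spec.retina_radius,
    )
    disc_mask = np.zeros((size, size), dtype=bool)
    if spec.optic_disc:
        rr, cc = draw.ellipse(
            disc_center[0], disc_center[1],
            0.13 * spec.retina_radius, 0.11 * spec.retina_radius,
            shape=(size, size),
        )
        disc_mask[rr, cc] = True
        disc_mask &= retina
        for c, v in enumerate(DISC_RGB):
            img[:, :, c] = np.where(disc_mask, v + 0.5 * texture, img[:, :, c])

    vessel_mask = _draw_vessels(
        (size, size), disc_center, spec.n_vessels,
        spec.vessel_width_range, retina, rng,
    )
    for c, f in enumerate(VESSEL_FACTOR):
        img[:, :, c] = np.where(vessel_mask, img[:, :, c] * f, img[:, :, c])

    he_mask, he_records = _place_hemorrhages(
        spec, retina, vessel_mask, disc_mask, dist, rng
    )
    jitter = gaussian_filter(rng.normal(0.0, 6.0, (size, size)), 3.0)
    for c, f in enumerate(HE_FACTOR):
        img[:, :, c] = np.where(
            he_mask, np.clip(img[:, :, c] * f + jitter, 0, None), img[:, :, c]
        )

    # multiplicative illumination: tilted plane + mild radial vignette
    beta = rng.uniform(0.0, 2.0 * np.pi)
    amp = spec.illumination_gradient
    plane = ((xx - center) * np.cos(beta) + (yy - center) * np.sin(beta)) / size
    field_map = 1.0 + amp * plane - 0.5 * amp * (dist / max(spec.retina_radius, 1)) ** 2
    img *= np.where(retina, field_map, 1.0)[:, :, None]

    img += rng.normal(0.0, spec.noise_sd, img.shape)
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return SyntheticSample(image, retina, vessel_mask, he_mask, he_records, spec)


def _place_hemorrhages(
    spec: FundusSpec,
    retina: np.ndarray,
    vessel_mask: np.ndarray,
    disc_mask: np.ndarray,
    dist: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> tuple[np.ndarray, list[HemorrhageRecord]]:
    size = spec.image_size
    center = size / 2.0
    n = spec.n_hemorrhages
    n_rim = int(round(spec.rim_he_fraction * n))
    n_vessel = int(round(spec.vessel_attached_fraction * n))
    n_vessel = min(n_vessel, n - n_rim)
    kinds = ["rim"] * n_rim + ["vessel"] * n_vessel + ["interior"] * (
        n - n_rim - n_vessel
    )
    he_mask = np.zeros((size, size), dtype=bool)
    occupied = np.zeros((size, size), dtype=bool)
    records: list[HemorrhageRecord] = []
    vessel_rc = np.argwhere(vessel_mask)
    for kind in kinds:
        a = rng.uniform(*spec.he_size_range)
        b = rng.uniform(spec.he_size_range[0], a)
        angle = rng.uniform(0.0, np.pi)
        placed = False
        for attempt in range(2 * max_tries):
            # a crowded vessel net can leave no vessel-clear spot for a
            # large lesion; after max_tries the clearance rule is relaxed
            require_clear = attempt < max_tries
            if kind == "rim":
                # outer lesion edge ends 2-15 px short of the retinal rim
                gap = rng.uniform(2.0, 15.0)
                radial = spec.retina_radius - gap - a * 1.15
                if radial <= 0:
                    continue
                phi = rng.uniform(0.0, 2.0 * np.pi)
                cr = center + radial * np.sin(phi)
                cc = center + radial * np.cos(phi)
            elif kind == "vessel" and len(vessel_rc):
                idx = rng.integers(len(vessel_rc))
                cr, cc = vessel_rc[idx].astype(float)
                if dist[int(cr), int(cc)] > spec.retina_radius - a * 1.2 - 5:
                    continue
            else:
                radial = rng.uniform(0.0, spec.retina_radius - a * 1.2 - 5)
                phi = rng.uniform(0.0, 2.0 * np.pi)
                cr = center + radial * np.sin(phi)
                cc = center + radial * np.cos(phi)
            mask = _irregular_ellipse_mask(
                (size, size), (cr, cc), (a, b), angle, rng
            ) & retina
            if not mask.any():
                continue
            pad = 8
            rmin, cmin = np.argwhere(mask).min(axis=0)
            rmax, cmax = np.argwhere(mask).max(axis=0)
            region = (
                slice(max(rmin - pad, 0), rmax + pad),
                slice(max(cmin - pad, 0), cmax + pad),
            )
            if occupied[region].any() or (mask & disc_mask).any():
                continue
            # only the vessel-attached fraction may touch a vessel: the
            # rest must keep a clear margin so attachment is controlled
            if kind != "vessel" and require_clear and vessel_mask[region].any():
                continue
            he_mask |= mask
            occupied[region] = True
            records.append(HemorrhageRecord((cr, cc), (a, b), angle, mask))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place a '{kind}' hemorrhage of semi-axes "
                f"({a:.1f}, {b:.1f}) after {2 * max_tries} tries"
            )
    return he_mask, records


# -- patch dataset harness -------------------------------------------------

PATCH_SOURCE_SPEC = FundusSpec(
    image_size=384,
    retina_radius=170,
    n_hemorrhages=8,
    he_size_range=(8.0, 22.0),
    n_vessels=7,
)


def generate_patch_dataset(
    n_pos: int,
    n_neg: int,
    seed: int = 0,
    spec: FundusSpec | None = None,
    jitter: int = 5,
    patches_per_lesion: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced labeled patch tensors for classifier training.

    Positives are windows centered (with a few jittered repeats) on planted
    hemorrhages; negatives sample the classifier's real confusers — vessel
    segments, the retinal rim, and plain retina with its dark shading.
    Source images use a compact spec that preserves absolute lesion pixel
    sizes.  Returns (X, y): X is (n_pos + n_neg, 256, 256, 3) uint8 of
    composed G / HSV-V / Lab-L channels, y the {0,1} labels.
    """
    base = spec or PATCH_SOURCE_SPEC
    rng = np.random.default_rng(seed)
    xs: list[np.ndarray] = []
    ys: list[int] = []
    pos_left, neg_left = n_pos, n_neg
    img_index = 0
    while (pos_left > 0 or neg_left > 0) and img_index < 10_000:
        sample = generate_fundus(
            replace(base, rng_seed=int(rng.integers(2**31 - 1)))
        )
        img_index += 1
        size = base.image_size
        img = sample.image

        def crop(cr: float, cc: float, half: int) -> np.ndarray | None:
            r0, c0 = int(round(cr)) - half, int(round(cc)) - half
            r1, c1 = r0 + 2 * half + 1, c0 + 2 * half + 1
            if r0 < 0 or c0 < 0 or r1 > size or c1 > size:
                return None
            return img[r0:r1, c0:c1]

        for rec in sample.he_records:
            if pos_left <= 0:
                break
            half = int(max(rec.axes[0] * 2.0, 24))
            for _ in range(patches_per_lesion):
                if pos_left <= 0:
                    break
                cr = rec.center[0] + rng.integers(-jitter, jitter + 1)
                cc = rec.center[1] + rng.integers(-jitter, jitter + 1)
                window = crop(cr, cc, half)
                if window is None:
                    continue
                xs.append(compose_channels_u8(window))
                ys.append(1)
                pos_left -= 1

        neg_quota = min(neg_left, len(sample.he_records) * patches_per_lesion)
        vessel_rc = np.argwhere(sample.vessel_mask & ~sample.he_mask)
        retina_rc = np.argwhere(
            sample.retina_mask & ~sample.he_mask & ~sample.vessel_mask
        )
        center = size / 2.0
        tries = 0
        while neg_quota > 0 and tries < 50 * neg_quota:
            tries += 1
            mode = tries % 3
            half = int(rng.integers(24, 56))
            if mode == 0 and len(vessel_rc):        # vessel confuser
                cr, cc = vessel_rc[rng.integers(len(vessel_rc))]
            elif mode == 1:                          # rim confuser
                phi = rng.uniform(0, 2 * np.pi)
                rad = base.retina_radius - rng.uniform(5, 25)
                cr = center + rad * np.sin(phi)
                cc = center + rad * np.cos(phi)
            else:                                    # dark-shade / background
                cr, cc = retina_rc[rng.integers(len(retina_rc))]
            window = crop(cr, cc, half)
            if window is None:
                continue
            # reject windows dominated by a hemorrhage: those are positives
            sl = (
                slice(int(round(cr)) - half, int(round(cr)) + half + 1),
                slice(int(round(cc)) - half, int(round(cc)) + half + 1),
            )
            if sample.he_mask[sl].mean() > 0.05:
                continue
            xs.append(compose_channels_u8(window))
            ys.append(0)
            neg_left -= 1
            neg_quota -= 1
    if pos_left > 0 or neg_left > 0:
        raise PlacementError(
            f"patch quota unmet: {pos_left} positives, {neg_left} negatives left"
        )
    x = np.stack(xs)
    y = np.array(ys, dtype=np.int64)
    order = np.random.default_rng(seed + 1).permutation(len(y))
    return x[order], y[order]
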