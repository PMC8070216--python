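"""Balance random patch sampling and tile/stitch utilities.

Training patches are drawn from the full-resolution image by rejection
sampling under two constraints: a target fraction of tumor-containing patches
(a patch "contains tumor" when its mask foreground reaches
``min_tumor_pixels``), and a bone-focus constraint for the normal patches —
their mean intensity must reach a configurable percentile of the image's
intensities, which keeps them on the bright bone rather than in empty
background. The distance-label patch is *cropped* from the full-image
distance map, never recomputed from the cropped mask, so shells near patch
borders still reflect tumors just outside the patch.

At inference time the image is tiled with overlap and per-patch probability
fields are stitched back by per-pixel arithmetic mean, which preserves the
per-pixel simplex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .distance_labels import MultiLevelDistanceMap

__all__ = [
    "PatchSample",
    "SamplerConfig",
    "SamplingExhaustedError",
    "sample_patches",
    "tile_image",
    "stitch_predictions",
]

logger = logging.getLogger(__name__)


class SamplingExhaustedError(RuntimeError):
    """Rejection sampling could not satisfy a constraint within max_attempts."""


@dataclass(frozen=True)
class PatchSample:
    """A P×P crop linked back to full-image space by its top-left origin."""

    image_patch: np.ndarray
    mask_patch: np.ndarray
    dist_patch: np.ndarray
    origin: tuple  # (row, col), 0-based, extent [row, row+P) x [col, col+P)
    source_id: str
    is_tumor: bool


@dataclass(frozen=True)
class SamplerConfig:
    """Knobs of balance random sampling.

    ``min_tumor_pixels`` defaults to 64 at patch size 416 and scales with the
    patch area; ``bone_percentile`` is the intensity percentile a normal
    patch's mean must reach (bone is bright on a radiograph).
    """

    patch_size: int = 416
    n_patches: int = 32
    tumor_fraction: float = 0.5
    min_tumor_pixels: int | None = None
    bone_percentile: float = 50.0
    max_attempts: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.tumor_fraction <= 1.0):
            raise ValueError(f"tumor_fraction must be in [0, 1], got {self.tumor_fraction}")
        if self.patch_size < 1:
            raise ValueError("patch_size must be positive")

    def resolved_min_tumor_pixels(self) -> int:
        if self.min_tumor_pixels is not None:
            return int(self.min_tumor_pixels)
        return max(1, round(64 * (self.patch_size / 416) ** 2))


def _as_grid(dist_map) -> np.ndarray:
    if isinstance(dist_map, MultiLevelDistanceMap):
        return dist_map.grid
    return np.asarray(dist_map)


def sample_patches(
    image: np.ndarray,
    mask: np.ndarray,
    dist_map,
    config: SamplerConfig,
    source_id: str = "",
) -> list:
    """Draw ``n_patches`` balanced patches from one image.

    The tumor quota is ``round(n_patches * tumor_fraction)``; on an image with
    no tumor the quota silently downgrades to 0 (logged) and all patches are
    normal. Deterministic given ``config.seed``.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    dist = _as_grid(dist_map)
    if not (image.shape == mask.shape == dist.shape):
        raise ValueError(
            f"image/mask/dist shapes differ: {image.shape}, {mask.shape}, {dist.shape}"
        )
    h, w = image.shape
    p = config.patch_size
    if p > h or p > w:
        raise ValueError(f"patch_size {p} exceeds image extent {h}x{w}")

    rng = np.random.default_rng(config.seed)
    min_px = config.resolved_min_tumor_pixels()
    intensity_floor = np.percentile(image, config.bone_percentile)

    n_tumor = round(config.n_patches * config.tumor_fraction)
    if n_tumor > 0 and not mask.any():
        logger.info(
            "source %s has no tumor: downgrading %d tumor patches to normal", source_id, n_tumor
        )
        n_tumor = 0
    wants = [True] * n_tumor + [False] * (config.n_patches - n_tumor)

    patches = []
    for want_tumor in wants:
        for attempt in range(config.max_attempts):
            r = int(rng.integers(0, h - p + 1))
            c = int(rng.integers(0, w - p + 1))
            m = mask[r : r + p, c : c + p]
            fg = int(m.sum())
            if want_tumor:
                if fg < min_px:
                    continue
            else:
                if fg >= min_px:
                    continue
                if image[r : r + p, c : c + p].mean() < intensity_floor:
                    continue
            patches.append(
                PatchSample(
                    image_patch=image[r : r + p, c : c + p].copy(),
                    mask_patch=m.copy(),
                    dist_patch=dist[r : r + p, c : c + p].copy(),
                    origin=(r, c),
                    source_id=source_id,
                    is_tumor=bool(want_tumor),
                )
            )
            break
        else:
            kind = "tumor" if want_tumor else "normal"
            constraint = (
                f"mask foreground >= {min_px} px"
                if want_tumor
                else f"mask foreground < {min_px} px and mean intensity >= "
                f"{config.bone_percentile}th percentile"
            )
            raise SamplingExhaustedError(
                f"could not draw a {kind} patch from {source_id or 'image'} after "
                f"{config.max_attempts} attempts (constraint: {constraint})"
            )
    return patches


def tile_image(image: np.ndarray, patch_size: int, stride: int) -> list:
    """Cover an image with P×P tiles; edge tiles are clamped, never padded.

    Returns a list of ``(patch, (row, col))`` covering every pixel.
    """
    image = np.asarray(image)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = image.shape[:2]
    p = patch_size
    if p > h or p > w:
        raise ValueError(f"patch_size {p} exceeds image extent {h}x{w}")

    def starts(extent):
        s = list(range(0, extent - p + 1, stride))
        if s[-1] != extent - p:
            s.append(extent - p)
        return s

    return [
        (image[r : r + p, c : c + p], (r, c)) for r in starts(h) for c in starts(w)
    ]


def stitch_predictions(
    patch_probs: Sequence[np.ndarray],
    origins: Sequence[tuple],
    full_shape: tuple,
) -> np.ndarray:
    """Average overlapping P×P×C probability patches into a full H×W×C field.

    The arithmetic mean of per-pixel simplexes is a simplex, so channel sums
    stay at 1. Raises if any pixel of ``full_shape`` is left uncovered.
    """
    if len(patch_probs) != len(origins):
        raise ValueError("patch_probs and origins differ in length")
    h, w = full_shape
    first = np.asarray(patch_probs[0])
    n_ch = first.shape[-1]
    acc = np.zeros((h, w, n_ch), dtype=np.float64)
    count = np.zeros((h, w), dtype=np.int64)
    for probs, (r, c) in zip(patch_probs, origins):
        probs = np.asarray(probs)
        ph, pw = probs.shape[:2]
        if r < 0 or c < 0 or r + ph > h or c + pw > w:
            raise ValueError(f"patch at origin {(r, c)} with shape {(ph, pw)} exceeds {full_shape}")
        acc[r : r + ph, c : c + pw] += probs
        count[r : r + ph, c : c + pw] += 1
    if (count == 0).any():
        n_bad = int((count == 0).sum())
        raise ValueError(f"stitching left {n_bad} pixels uncovered")
    return (acc / count[..., None]).astype(np.float32)
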