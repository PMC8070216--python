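"""Synthetic knee-radiograph generator.

The clinical dataset this pipeline was designed around is private, so every
stage is exercised on synthetic images that reproduce its *statistical*
structure rather than its anatomy: a bright elongated bone (a stylized shaft
with a rounded epiphysis) on a darker soft-tissue background, with 1-8 tumor
regions per image confined to the bone, three image-level classes, and
additive acquisition noise.

The two tumor classes are rendered so that they differ in the texture
statistics a classifier can learn from:

* benign — a single smooth bright ellipse with a sharp, well-defined margin
  (the radiographic presentation of a slow-growing lesion);
* malignant — an irregular union of several overlapping small ellipses with
  strong speckle texture and blurred, ill-defined margins (a permeative,
  destructive pattern).

Images are 16-bit grayscale; masks are binary. The generator is fully
deterministic given the config seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "SynthConfig",
    "SynthRecord",
    "generate_dataset",
    "write_manifest",
    "read_manifest",
    "to_float",
    "LABEL_NAMES",
    "NORMAL",
    "BENIGN",
    "MALIGNANT",
]

NORMAL, BENIGN, MALIGNANT = 0, 1, 2
LABEL_NAMES = {NORMAL: "normal", BENIGN: "benign", MALIGNANT: "malignant"}


class SynthesisError(RuntimeError):
    """Raised when tumors cannot be placed under the configured geometry."""


@dataclass(frozen=True)
class SynthConfig:
    """Conditions for one synthetic dataset.

    Defaults are desk-scale: 128x128 canvases with tumor bounding boxes of
    10-36 px, i.e. the same ~8-30% of image side that the clinical lesions
    (roughly 100-1500 px on radiographs up to ~4000 px) occupy. Tumor count
    per image is uniform on ``tumor_count_range`` (the source data reports
    only the 1-8 range, no distribution).
    """

    image_height: int = 128
    image_width: int = 128
    n_images_per_class: int = 10
    tumor_count_range: tuple = (1, 4)
    tumor_size_range: tuple = (10, 36)
    noise_sd: float = 0.02
    bone_width_frac: float = 0.30
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.tumor_count_range
        if not (1 <= lo <= hi <= 8):
            raise ValueError(f"tumor_count_range must satisfy 1 <= min <= max <= 8, got {(lo, hi)}")
        slo, shi = self.tumor_size_range
        if slo < 4:
            raise ValueError(f"tumor_size_range.min must be >= 4 px, got {slo}")
        if slo > shi:
            raise ValueError("tumor_size_range must be (min, max) with min <= max")
        if not (0.0 < self.bone_width_frac < 1.0):
            raise ValueError(f"bone_width_frac must be in (0, 1), got {self.bone_width_frac}")
        if self.image_height < 16 or self.image_width < 16:
            raise ValueError("image extents must be at least 16 px")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SynthRecord:
    """One synthetic case: 16-bit image, binary mask, image-level label."""

    image: np.ndarray  # uint16 (H, W)
    mask: np.ndarray  # uint8 (H, W), values {0, 1}
    label: int  # 0 normal, 1 benign, 2 malignant
    image_id: str = ""

    def __eq__(self, other):
        return (
            isinstance(other, SynthRecord)
            and self.label == other.label
            and self.image_id == other.image_id
            and np.array_equal(self.image, other.image)
            and np.array_equal(self.mask, other.mask)
        )


def to_float(image: np.ndarray) -> np.ndarray:
    """Rescale an integer image to float32 intensities in [0, 1]."""
    image = np.asarray(image)
    if image.dtype == np.uint16:
        return (image / 65535.0).astype(np.float32)
    if image.dtype == np.uint8:
        return (image / 255.0).astype(np.float32)
    return image.astype(np.float32)


def _ellipse_mask(h, w, cy, cx, ry, rx):
    yy, xx = np.ogrid[:h, :w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _render_bone(cfg: SynthConfig, rng: np.random.Generator):
    """Stylized long bone: vertical bright band + elliptical condyle at the top."""
    h, w = cfg.image_height, cfg.image_width
    band_w = max(4, int(round(cfg.bone_width_frac * w)))
    c0 = (w - band_w) // 2 + rng.integers(-w // 16, w // 16 + 1)
    c0 = int(np.clip(c0, 1, w - band_w - 1))
    c1 = c0 + band_w

    img = np.full((h, w), 0.06, dtype=np.float64)
    # faint soft-tissue halo around the bone
    img += 0.05 * np.exp(-(((np.arange(w) - (c0 + c1) / 2) / (0.45 * w)) ** 2))[None, :]

    bone = np.zeros((h, w), dtype=bool)
    bone[:, c0:c1] = True
    # condyle: rounded epiphysis, wider than the shaft
    cond_ry = max(4, int(0.11 * h))
    cond_rx = min(w // 2 - 2, int(0.8 * band_w))
    cond_cy = cond_ry + 2
    cond_cx = (c0 + c1) // 2
    bone |= _ellipse_mask(h, w, cond_cy, cond_cx, cond_ry, cond_rx)

    img[bone] = 0.52
    # cortical rim: slightly brighter band edges
    rim = bone & ~ndimage.binary_erosion(bone, iterations=2)
    img[rim] = 0.62
    # low-amplitude trabecular texture inside the bone
    tex = ndimage.gaussian_filter(rng.standard_normal((h, w)), 1.5)
    img += 0.03 * tex * bone
    img = ndimage.gaussian_filter(img, 0.8)

    # region where tumor bounding boxes may be placed (shaft interior)
    place = np.zeros((h, w), dtype=bool)
    place[2 : h - 2, c0 + 1 : c1 - 1] = True
    return img, place


def _place_boxes(cfg, n, place_region, rng, max_attempts=200):
    """Sample n non-touching tumor bounding boxes inside the bone region."""
    h, w = place_region.shape
    rows = np.flatnonzero(place_region.any(axis=1))
    cols = np.flatnonzero(place_region.any(axis=0))
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    slo, shi = cfg.tumor_size_range
    if slo > (c1 - c0) or slo > (r1 - r0):
        raise SynthesisError(
            f"tumor_size_range min {slo} exceeds bone region extents "
            f"({r1 - r0}x{c1 - c0}); reduce tumor size or enlarge the image"
        )
    # boxes are clamped per dimension: a lesion may be long but no wider than
    # the shaft it sits in
    hi_h = min(shi, r1 - r0)
    hi_w = min(shi, c1 - c0)
    # whole-layout retries: a large early box can make the rest unplaceable,
    # so on failure the layout restarts with sizes biased smaller
    for layout in range(max_attempts // 10):
        boxes = []
        cap_h = max(slo, hi_h - layout * max(1, (hi_h - slo) // 8))
        cap_w = max(slo, hi_w - layout * max(1, (hi_w - slo) // 8))
        for _ in range(n):
            placed = False
            for attempt in range(50):
                bh = int(rng.integers(slo, cap_h + 1))
                bw = int(rng.integers(slo, cap_w + 1))
                top = int(rng.integers(r0, r1 - bh + 1))
                left = int(rng.integers(c0, c1 - bw + 1))
                # 2-px halo keeps separate tumors 8-disconnected
                ok = all(
                    not (top - 2 < t + bh2 and t - 2 < top + bh and left - 2 < l + bw2 and l - 2 < left + bw)
                    for (t, l, bh2, bw2) in boxes
                )
                if ok:
                    boxes.append((top, left, bh, bw))
                    placed = True
                    break
            if not placed:
                break
        if len(boxes) == n:
            return boxes
    raise SynthesisError(
        f"could not place {n} non-overlapping tumors of size "
        f"{cfg.tumor_size_range} in the bone region"
    )


def _draw_benign(img, mask, box, rng):
    top, left, bh, bw = box
    h, w = img.shape
    m = _ellipse_mask(h, w, top + bh / 2 - 0.5, left + bw / 2 - 0.5, bh / 2, bw / 2)
    amp = rng.uniform(0.20, 0.30)
    img[m] += amp  # sharp, well-defined margin: no blurring of the bump
    mask |= m


def _draw_malignant(img, mask, box, rng, max_attempts=50):
    top, left, bh, bw = box
    h, w = img.shape
    for attempt in range(max_attempts):
        k = int(rng.integers(3, 7))
        m = np.zeros((h, w), dtype=bool)
        # anchor lobes near opposite corners so the union spans the box,
        # then chain the rest with guaranteed overlap
        ry = max(2.0, bh / 4)
        rx = max(2.0, bw / 4)
        centers = [
            (top + ry, left + rx),
            (top + bh - ry, left + bw - rx),
        ]
        for _ in range(k - 2):
            prev = centers[int(rng.integers(len(centers)))]
            cy = np.clip(prev[0] + rng.uniform(-ry, ry), top + 2, top + bh - 2)
            cx = np.clip(prev[1] + rng.uniform(-rx, rx), left + 2, left + bw - 2)
            centers.append((cy, cx))
        for cy, cx in centers:
            sy = rng.uniform(0.7, 1.0) * ry
            sx = rng.uniform(0.7, 1.0) * rx
            m |= _ellipse_mask(h, w, cy, cx, max(2.0, sy), max(2.0, sx))
        # bridge the two anchors: a thin connector along the diagonal
        t = np.linspace(0, 1, max(bh, bw))
        yy = np.clip((centers[0][0] * (1 - t) + centers[1][0] * t).astype(int), 0, h - 1)
        xx = np.clip((centers[0][1] * (1 - t) + centers[1][1] * t).astype(int), 0, w - 1)
        bridge = np.zeros_like(m)
        bridge[yy, xx] = True
        m |= ndimage.binary_dilation(bridge, iterations=2)
        n_comp = ndimage.label(m, structure=np.ones((3, 3)))[1]
        rs, cs = np.nonzero(m)
        span_ok = (rs.max() - rs.min() + 1) >= bh - 2 and (cs.max() - cs.min() + 1) >= bw - 2
        inside = rs.min() >= top - 1 and rs.max() <= top + bh and cs.min() >= left - 1 and cs.max() <= left + bw
        if n_comp == 1 and span_ok and inside:
            break
    else:  # pragma: no cover - geometry above converges in a few attempts
        raise SynthesisError("failed to synthesize a connected malignant lesion")

    amp = rng.uniform(0.16, 0.24)
    bump = amp * m.astype(float)
    bump = ndimage.gaussian_filter(bump, 1.2)  # ill-defined margin
    # permeative matrix: strong high-frequency speckle inside the lesion
    speckle = ndimage.gaussian_filter(rng.standard_normal(img.shape), 0.6)
    img += bump + 0.16 * speckle * m
    mask |= m


def generate_dataset(config: SynthConfig) -> list:
    """Generate ``3 * n_images_per_class`` records, deterministic in the seed.

    Classes are emitted in order normal, benign, malignant. Normal images have
    empty masks; tumor images carry 1-8 mutually disconnected lesions whose
    bounding boxes respect ``tumor_size_range``.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    for label in (NORMAL, BENIGN, MALIGNANT):
        for i in range(config.n_images_per_class):
            img, place = _render_bone(config, rng)
            mask = np.zeros(img.shape, dtype=bool)
            if label != NORMAL:
                n_tumors = int(rng.integers(config.tumor_count_range[0], config.tumor_count_range[1] + 1))
                boxes = _place_boxes(config, n_tumors, place, rng)
                for box in boxes:
                    if label == BENIGN:
                        _draw_benign(img, mask, box, rng)
                    else:
                        _draw_malignant(img, mask, box, rng)
            if config.noise_sd > 0:
                img = img + rng.normal(0.0, config.noise_sd, img.shape)
            img16 = (np.clip(img, 0.0, 1.0) * 65535.0).round().astype(np.uint16)
            records.append(
                SynthRecord(
                    image=img16,
                    mask=mask.astype(np.uint8),
                    label=label,
                    image_id=f"{LABEL_NAMES[label]}_{i:04d}",
                )
            )
    return records


def write_manifest(records: Sequence[SynthRecord], out_dir) -> Path:
    """Persist records as 16-bit image PNGs, 0/255 mask PNGs and a CSV manifest.

    The manifest has columns ``image_path,mask_path,label`` with paths
    relative to the manifest's directory; re-reading reproduces the records
    pixel-exactly.
    """
    out_dir = Path(out_dir)
    try:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
        manifest_path = out_dir / "manifest.csv"
        with open(manifest_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image_path", "mask_path", "label"])
            for rec in records:
                img_rel = f"images/{rec.image_id}.png"
                msk_rel = f"masks/{rec.image_id}.png"
                iio.imwrite(out_dir / img_rel, rec.image.astype(np.uint16))
                iio.imwrite(out_dir / msk_rel, (rec.mask.astype(np.uint8) * 255))
                writer.writerow([img_rel, msk_rel, int(rec.label)])
    except OSError as exc:
        raise OSError(f"failed writing dataset under {out_dir}: {exc}") from exc
    return manifest_path


def read_manifest(manifest_path) -> list:
    """Load records written by :func:`write_manifest`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    records = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            label = int(row["label"])
            if label not in LABEL_NAMES:
                raise ValueError(f"invalid label {label!r} in {manifest_path} (expected 0/1/2)")
            img_path = root / row["image_path"]
            try:
                image = iio.imread(img_path)
                mask = iio.imread(root / row["mask_path"])
            except OSError as exc:
                raise OSError(f"failed reading record {row['image_path']}: {exc}") from exc
            records.append(
                SynthRecord(
                    image=np.asarray(image, dtype=np.uint16),
                    mask=(np.asarray(mask) > 0).astype(np.uint8),
                    label=label,
                    image_id=Path(row["image_path"]).stem,
                )
            )
    return records
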