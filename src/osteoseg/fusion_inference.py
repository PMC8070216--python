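"""Whole-image prediction: global model, patch model, and their fusion.

The global route down-scales the full radiograph to the network input size,
runs one forward pass, and bilinearly upsamples the per-pixel probabilities
back to the original resolution (renormalizing each pixel's simplex). The
patch route tiles the full-resolution image with overlap, runs the patch
model per tile, stitches the probability fields by per-pixel mean, and
aggregates the per-tile class simplexes into one image-level simplex.

Fusion implements the division of labor the two models are good at: the
patch model — sensitive to local texture — decides malignancy; otherwise the
global model decides normal-vs-benign. Segmentation probabilities are fused
as a convex combination of the two fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .patch_sampling import stitch_predictions, tile_image
from .segunet_model import SegUnet, forward
from .synthetic_data import BENIGN, MALIGNANT, NORMAL

__all__ = ["FusionConfig", "Prediction", "predict_global", "predict_patch", "fuse"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FusionConfig:
    seg_weights: tuple = (0.5, 0.5)  # (w_global, w_patch), must sum to 1
    patch_class_aggregation: str = "max"  # "max" | "mean" | "top_k_mean"
    top_k: int = 3
    malignant_threshold: float | None = None  # None -> argmax rule

    def __post_init__(self):
        wg, wp = self.seg_weights
        if wg < 0 or wp < 0 or abs(wg + wp - 1.0) > 1e-9:
            raise ValueError(f"seg_weights must be non-negative and sum to 1, got {self.seg_weights}")
        if self.patch_class_aggregation not in ("max", "mean", "top_k_mean"):
            raise ValueError(f"unknown aggregation {self.patch_class_aggregation!r}")


@dataclass
class Prediction:
    """Image-level class plus full-resolution segmentation."""

    label: int
    class_probs: np.ndarray | None  # (3,)
    seg_mask: np.ndarray | None  # (H_O, W_O) uint8, argmax of seg_probs
    seg_probs: np.ndarray | None  # (H_O, W_O, 2)


def _upsample_probs(probs: np.ndarray, shape: tuple) -> np.ndarray:
    """Bilinear upsample a probability field and renormalize each pixel."""
    if probs.shape[:2] == shape:
        return probs
    up = _sk_resize(probs, shape, order=1, preserve_range=True, anti_aliasing=False)
    up = np.clip(up, 0.0, None)
    return (up / up.sum(axis=-1, keepdims=True)).astype(np.float32)


def _finalize(class_probs, seg_probs) -> Prediction:
    if class_probs is not None:
        label = int(np.argmax(class_probs))
    elif seg_probs is not None:
        # no classifier head: tumor presence decided from the segmentation
        label = BENIGN if (np.argmax(seg_probs, axis=-1) == 1).any() else NORMAL
    else:
        raise ValueError("prediction carries neither class nor segmentation output")
    mask = None if seg_probs is None else np.argmax(seg_probs, axis=-1).astype(np.uint8)
    return Prediction(label=label, class_probs=class_probs, seg_mask=mask, seg_probs=seg_probs)


def predict_global(model: SegUnet, image: np.ndarray) -> Prediction:
    """Down-scale, forward, and upsample probabilities back to original size."""
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape
    size = model.config.input_size
    small = image if (h, w) == (size, size) else _sk_resize(
        image, (size, size), order=1, preserve_range=True, anti_aliasing=True
    ).astype(np.float32)
    out = forward(model, small[None])
    class_probs = None if out.y_clas is None else out.y_clas[0]
    seg_probs = None if out.y_seg is None else _upsample_probs(out.y_seg[0], (h, w))
    return _finalize(class_probs, seg_probs)


def _aggregate_class(tile_probs: np.ndarray, cfg: FusionConfig) -> np.ndarray:
    """Collapse per-tile class simplexes (T, 3) to one image-level simplex."""
    if cfg.patch_class_aggregation == "mean":
        return tile_probs.mean(axis=0)
    if cfg.patch_class_aggregation == "max":
        agg = tile_probs.max(axis=0)
    else:  # top_k_mean
        k = min(cfg.top_k, tile_probs.shape[0])
        agg = np.sort(tile_probs, axis=0)[-k:].mean(axis=0)
    return agg / agg.sum()


def predict_patch(
    model: SegUnet,
    image: np.ndarray,
    patch_size: int | None = None,
    stride: int | None = None,
    config: FusionConfig | None = None,
) -> Prediction:
    """Tile, forward per tile, stitch segmentation, aggregate classification.

    Default tiling uses the model input size with 50% overlap. An image
    smaller than the patch size falls back to a single resized tile (logged).
    """
    cfg = config or FusionConfig()
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape
    p = patch_size or model.config.input_size
    if p > h or p > w:
        logger.warning(
            "image %dx%d smaller than patch size %d: falling back to one resized tile", h, w, p
        )
        return predict_global(model, image)
    stride = stride or max(1, p // 2)

    tiles = tile_image(image, p, stride)
    x = np.stack([t for t, _ in tiles])
    out = forward(model, x)

    class_probs = None
    if out.y_clas is not None:
        class_probs = _aggregate_class(out.y_clas, cfg)
    seg_probs = None
    if out.y_seg is not None:
        seg_probs = stitch_predictions(
            [out.y_seg[i] for i in range(len(tiles))], [o for _, o in tiles], (h, w)
        )
    return _finalize(class_probs, seg_probs)


def fuse(global_pred: Prediction, patch_pred: Prediction, config: FusionConfig | None = None) -> Prediction:
    """Combine the two predictions.

    Class rule: the image is malignant iff the patch model says so (argmax,
    or malignant probability >= ``malignant_threshold`` when set); otherwise
    the label is the global model's argmax restricted to {normal, benign}.
    Segmentation rule: convex combination of the two probability fields with
    ``seg_weights``, mask by per-pixel argmax.
    """
    cfg = config or FusionConfig()

    seg_probs = None
    if global_pred.seg_probs is not None and patch_pred.seg_probs is not None:
        if global_pred.seg_probs.shape != patch_pred.seg_probs.shape:
            raise ValueError(
                f"segmentation shapes differ: {global_pred.seg_probs.shape} vs "
                f"{patch_pred.seg_probs.shape}"
            )
        wg, wp = cfg.seg_weights
        seg_probs = (wg * global_pred.seg_probs + wp * patch_pred.seg_probs).astype(np.float32)
    elif global_pred.seg_probs is not None or patch_pred.seg_probs is not None:
        seg_probs = (
            global_pred.seg_probs if global_pred.seg_probs is not None else patch_pred.seg_probs
        )

    class_probs = None
    label = None
    if global_pred.class_probs is not None and patch_pred.class_probs is not None:
        if cfg.malignant_threshold is not None:
            patch_malignant = patch_pred.class_probs[MALIGNANT] >= cfg.malignant_threshold
        else:
            patch_malignant = int(np.argmax(patch_pred.class_probs)) == MALIGNANT
        if patch_malignant:
            label = MALIGNANT
        else:
            label = int(np.argmax(global_pred.class_probs[[NORMAL, BENIGN]]))
        # report a fused simplex consistent with the rule for downstream use
        class_probs = 0.5 * (global_pred.class_probs + patch_pred.class_probs)
        class_probs = class_probs / class_probs.sum()
    elif global_pred.class_probs is not None:
        class_probs = global_pred.class_probs
    elif patch_pred.class_probs is not None:
        class_probs = patch_pred.class_probs

    fused = _finalize(class_probs, seg_probs)
    if label is not None:
        fused.label = label
    return fused
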