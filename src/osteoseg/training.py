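"""Two-stage training: global model on whole resized images, patch model on
balance-sampled crops initialized from the global weights.

The optimization schedule follows the original study setup: Adam at lr 0.001
for the global stage, SGD at lr 0.0004 for the patch stage, learning rate
reduced on a validation-loss plateau, early stopping after 20 stale epochs,
and an 80/20 stratified train/validation split. The multi-task loss is a
weighted sum of per-branch categorical cross-entropies (image-level for the
classifier, pixel-averaged for the two dense heads).

Geometric augmentation (flip / rotation / center-crop-and-zoom) is applied
identically to the image and its labels; categorical label fields use
nearest-neighbor interpolation, and the distance map is *regenerated* from
the transformed mask in the global stage (it is cropped from the full-image
map in the patch stage, where lesions outside the crop still shape the
shells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .distance_labels import make_distance_map, one_hot_encode, N_DISTANCE_LEVELS
from .nn import Adam, SGD, ReduceLROnPlateau, softmax
from .patch_sampling import SamplerConfig, SamplingExhaustedError, sample_patches
from .segunet_model import ModelConfig, ModelOutputs, SegUnet, build_model
from .synthetic_data import SynthRecord, read_manifest, to_float, NORMAL

__all__ = [
    "TrainConfig",
    "AugmentConfig",
    "split_dataset",
    "multitask_loss",
    "train_global",
    "train_patch",
    "augment_sample",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    stage: str = "global"  # "global" | "patch"
    optimizer: str = "adam"  # "adam" | "sgd"
    learning_rate: float = 0.001
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    early_stop_patience: int = 20
    max_epochs: int = 50
    batch_size: int = 4
    loss_weights: tuple = (1.0, 1.0, 1.0)  # (clas, seg, dist)
    split_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in (0, 1)")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be non-negative")

    @classmethod
    def global_stage(cls, **kw) -> "TrainConfig":
        return cls(stage="global", optimizer="adam", learning_rate=0.001, **kw)

    @classmethod
    def patch_stage(cls, **kw) -> "TrainConfig":
        return cls(stage="patch", optimizer="sgd", learning_rate=0.0004, **kw)


@dataclass(frozen=True)
class AugmentConfig:
    rotation_range: float = 15.0  # degrees, uniform in +-range
    flip: bool = True  # horizontal
    crop_scale_range: tuple = (0.8, 1.0)  # center-crop fraction, zoomed back
    apply_probability: float = 0.5  # per transform


# --------------------------------------------------------------------- helpers
def _as_records(data) -> list:
    if isinstance(data, (str,)) or hasattr(data, "__fspath__"):
        return read_manifest(data)
    return list(data)


def _resize_image(img: np.ndarray, size: tuple) -> np.ndarray:
    if img.shape == size:
        return img.astype(np.float32)
    return _sk_resize(img, size, order=1, preserve_range=True, anti_aliasing=True).astype(
        np.float32
    )


def _resize_labels(lab: np.ndarray, size: tuple) -> np.ndarray:
    if lab.shape == size:
        return lab
    return _sk_resize(lab, size, order=0, preserve_range=True, anti_aliasing=False).astype(
        lab.dtype
    )


def split_dataset(data, fraction: float = 0.8, seed: int = 0):
    """Stratified, disjoint, seed-deterministic train/validation split."""
    records = _as_records(data)
    if not records:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    by_class: dict = {}
    for rec in records:
        by_class.setdefault(rec.label, []).append(rec)
    train, val = [], []
    for label in sorted(by_class):
        group = by_class[label]
        if len(group) < 2:
            raise ValueError(
                f"class {label} has only {len(group)} record(s); need >= 2 to stratify"
            )
        order = rng.permutation(len(group))
        n_train = int(round(fraction * len(group)))
        n_train = min(max(n_train, 1), len(group) - 1)
        train.extend(group[i] for i in order[:n_train])
        val.extend(group[i] for i in order[n_train:])
    return train, val


# ------------------------------------------------------------------------ loss
def _ce(probs: np.ndarray, onehot: np.ndarray) -> float:
    return float(-(onehot * np.log(np.clip(probs, 1e-12, 1.0))).sum(axis=-1).mean())


def multitask_loss(outputs: ModelOutputs, targets: dict, loss_weights=(1.0, 1.0, 1.0)) -> float:
    """Weighted sum of branch cross-entropies; terms for absent branches drop out."""
    lc, ls, ld = loss_weights
    if lc < 0 or ls < 0 or ld < 0:
        raise ValueError("loss weights must be non-negative")
    loss = 0.0
    if outputs.y_clas is not None and "clas" in targets:
        loss += lc * _ce(outputs.y_clas, targets["clas"])
    if outputs.y_seg is not None and "seg" in targets:
        loss += ls * _ce(outputs.y_seg, targets["seg"])
    if outputs.y_dist is not None and "dist" in targets:
        loss += ld * _ce(outputs.y_dist, targets["dist"])
    return loss


def _loss_and_grads(logits: dict, targets: dict, loss_weights):
    """Loss and gradients w.r.t. logits (softmax+CE folded analytically)."""
    weights = dict(zip(("clas", "seg", "dist"), loss_weights))
    loss = 0.0
    grads = {}
    for key, z in logits.items():
        lam = weights[key]
        if key not in targets or lam == 0:
            continue
        p = softmax(z)
        y = targets[key]
        loss += lam * _ce(p, y)
        norm = np.prod(p.shape[:-1])  # batch (clas) or batch*H*W (pixel heads)
        grads[key] = (lam * (p - y) / norm).astype(np.float32)
    return loss, grads


# ---------------------------------------------------------------- augmentation
def augment_sample(
    image: np.ndarray,
    mask: np.ndarray,
    dist: np.ndarray | None,
    cfg: AugmentConfig,
    rng: np.random.Generator,
    regenerate_dist: bool = True,
):
    """Apply one random geometric augmentation to (image, mask, dist).

    With ``regenerate_dist`` the distance map is recomputed from the
    transformed mask (global stage); otherwise the given map is transformed
    with nearest-neighbor interpolation (patch stage, where the map was
    cropped from the full image and cannot be recomputed locally).
    """
    img = image
    msk = mask
    dst = dist
    if cfg.flip and rng.random() < cfg.apply_probability:
        img = img[:, ::-1]
        msk = msk[:, ::-1]
        dst = None if dst is None else dst[:, ::-1]
    if cfg.rotation_range > 0 and rng.random() < cfg.apply_probability:
        angle = float(rng.uniform(-cfg.rotation_range, cfg.rotation_range))
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
        msk = ndimage.rotate(msk, angle, reshape=False, order=0, mode="constant")
        if dst is not None:
            dst = ndimage.rotate(dst, angle, reshape=False, order=0, mode="constant")
    if cfg.crop_scale_range is not None and rng.random() < cfg.apply_probability:
        h, w = img.shape
        s = float(rng.uniform(*cfg.crop_scale_range))
        ch, cw = max(4, int(round(s * h))), max(4, int(round(s * w)))
        r0, c0 = (h - ch) // 2, (w - cw) // 2
        img = _resize_image(np.ascontiguousarray(img[r0 : r0 + ch, c0 : c0 + cw]), (h, w))
        msk = _resize_labels(np.ascontiguousarray(msk[r0 : r0 + ch, c0 : c0 + cw]), (h, w))
        if dst is not None:
            dst = _resize_labels(np.ascontiguousarray(dst[r0 : r0 + ch, c0 : c0 + cw]), (h, w))
    msk = np.ascontiguousarray(msk)
    if regenerate_dist:
        dst = make_distance_map(msk.astype(np.uint8)).grid
    return np.ascontiguousarray(img, dtype=np.float32), msk, dst


# -------------------------------------------------------------------- fitting
def _targets_for_batch(samples: list, flags, n_clas: int) -> dict:
    targets = {}
    if flags.clas:
        targets["clas"] = one_hot_encode(np.array([s["label"] for s in samples]), n_clas)
    if flags.seg:
        targets["seg"] = one_hot_encode(np.stack([s["mask"] for s in samples]), 2)
    if flags.dist:
        targets["dist"] = one_hot_encode(np.stack([s["dist"] for s in samples]), N_DISTANCE_LEVELS)
    return targets


def _eval_loss(model: SegUnet, data: list, cfg: TrainConfig) -> float:
    flags = model.config.branch_flags
    losses, counts = [], []
    for i in range(0, len(data), cfg.batch_size):
        chunk = data[i : i + cfg.batch_size]
        x = np.stack([s["image"] for s in chunk])
        logits = model.forward_logits(x, training=False)
        loss, _ = _loss_and_grads(logits, _targets_for_batch(chunk, flags, model.config.n_classes_clas), cfg.loss_weights)
        losses.append(loss)
        counts.append(len(chunk))
    return float(np.average(losses, weights=counts))


def _fit(model: SegUnet, train_data: list, val_data: list, cfg: TrainConfig, aug_cfg, regenerate_dist: bool):
    if not train_data:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    if cfg.optimizer == "adam":
        opt = Adam(model.params(), lr=cfg.learning_rate)
    elif cfg.optimizer == "sgd":
        opt = SGD(model.params(), lr=cfg.learning_rate)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
    sched = ReduceLROnPlateau(opt, factor=cfg.plateau_factor, patience=cfg.plateau_patience)
    flags = model.config.branch_flags

    history = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    best_weights = model.get_weights()
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_data))
        batch_losses, batch_sizes = [], []
        for i in range(0, len(order), cfg.batch_size):
            chunk = []
            for j in order[i : i + cfg.batch_size]:
                s = train_data[j]
                if aug_cfg is not None:
                    img, msk, dst = augment_sample(
                        s["image"], s["mask"], s["dist"], aug_cfg, rng, regenerate_dist
                    )
                    chunk.append({"image": img, "mask": msk, "dist": dst, "label": s["label"]})
                else:
                    chunk.append(s)
            x = np.stack([s["image"] for s in chunk])
            logits = model.forward_logits(x, training=True)
            loss, grads = _loss_and_grads(
                logits, _targets_for_batch(chunk, flags, model.config.n_classes_clas), cfg.loss_weights
            )
            model.backward(grads)
            opt.step()
            opt.zero_grad()
            batch_losses.append(loss)
            batch_sizes.append(len(chunk))
        train_loss = float(np.average(batch_losses, weights=batch_sizes))
        val_loss = _eval_loss(model, val_data, cfg) if val_data else train_loss
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        sched.step(val_loss)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_weights = model.get_weights()
            stale = 0
        else:
            stale += 1
        logger.info(
            "%s epoch %d: train %.4f val %.4f lr %.2e", cfg.stage, epoch, train_loss, val_loss, opt.lr
        )
        if stale >= cfg.early_stop_patience:
            logger.info("early stopping at epoch %d (no improvement for %d)", epoch, stale)
            break
    model.set_weights(best_weights)
    return history


# ----------------------------------------------------------------- global stage
def _prepare_global(records: Sequence[SynthRecord], size: int) -> list:
    data = []
    for rec in records:
        img = _resize_image(to_float(rec.image), (size, size))
        msk = _resize_labels(rec.mask.astype(np.uint8), (size, size))
        data.append(
            {
                "image": img,
                "mask": msk,
                "dist": make_distance_map(msk).grid,
                "label": rec.label,
            }
        )
    return data


def train_global(
    train_data,
    val_data,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    augment_config: AugmentConfig | None = None,
):
    """Train the global model on whole images resized to ``input_size``.

    Masks are resized with nearest-neighbor interpolation and the distance
    map is regenerated from the resized mask. Returns ``(model, history)``
    with the best-validation weights restored.
    """
    cfg = train_config or TrainConfig.global_stage()
    size = model_config.input_size
    train = _prepare_global(_as_records(train_data), size)
    val = _prepare_global(_as_records(val_data), size)
    model = build_model(model_config, seed=cfg.seed)
    history = _fit(model, train, val, cfg, augment_config, regenerate_dist=True)
    return model, history


# ------------------------------------------------------------------ patch stage
def _prepare_patches(records: Sequence[SynthRecord], sampler: SamplerConfig) -> list:
    data = []
    for k, rec in enumerate(records):
        dist = make_distance_map(rec.mask).grid
        per_rec = replace(sampler, seed=(sampler.seed + 9973 * k) % (2**31))
        try:
            patches = sample_patches(to_float(rec.image), rec.mask, dist, per_rec, rec.image_id)
        except SamplingExhaustedError as exc:
            # e.g. a lesion so large that every bright crop contains tumor:
            # fall back to an all-tumor draw for this image
            logger.warning("%s; resampling %s with tumor_fraction=1", exc, rec.image_id)
            try:
                patches = sample_patches(
                    to_float(rec.image), rec.mask, dist, replace(per_rec, tumor_fraction=1.0), rec.image_id
                )
            except SamplingExhaustedError as exc2:
                logger.warning("skipping %s: %s", rec.image_id, exc2)
                continue
        for patch in patches:
            # a crop only inherits the image label when it actually shows tumor
            data.append(
                {
                    "image": patch.image_patch.astype(np.float32),
                    "mask": patch.mask_patch.astype(np.uint8),
                    "dist": patch.dist_patch,
                    "label": rec.label if patch.is_tumor else NORMAL,
                }
            )
    return data


def train_patch(
    train_data,
    val_data,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    augment_config: AugmentConfig | None = None,
    init_weights: dict | None = None,
    sampler_config: SamplerConfig | None = None,
):
    """Fine-tune on balance-sampled patches starting from the global weights.

    ``init_weights`` (from ``SegUnet.get_weights()``) must be structurally
    compatible with ``model_config``; a mismatch raises :class:`TransferError`
    naming the offending tensors. Distance-label patches are cropped from the
    full-image distance map, never recomputed locally.
    """
    cfg = train_config or TrainConfig.patch_stage()
    sampler = sampler_config or SamplerConfig(
        patch_size=32, n_patches=8, min_tumor_pixels=16, seed=cfg.seed
    )
    train = _prepare_patches(_as_records(train_data), sampler)
    val = _prepare_patches(_as_records(val_data), replace(sampler, seed=sampler.seed + 1))
    model = build_model(model_config, seed=cfg.seed)
    if init_weights is not None:
        model.set_weights(init_weights)  # raises TransferError on mismatch
    history = _fit(model, train, val, cfg, augment_config, regenerate_dist=False)
    return model, history
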