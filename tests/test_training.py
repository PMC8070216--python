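"""Splitting, the multi-task loss, augmentation consistency, and the two
training stages (smoke + overfit trend + transfer fidelity)."""

import numpy as np
import pytest

from osteoseg import (
    AugmentConfig,
    ModelConfig,
    ModelOutputs,
    SamplerConfig,
    SynthConfig,
    TrainConfig,
    augment_sample,
    build_model,
    forward,
    generate_dataset,
    make_distance_map,
    multitask_loss,
    one_hot_encode,
    split_dataset,
    train_global,
    train_patch,
)
from osteoseg.training import _loss_and_grads


# ---------------------------------------------------------------------- split
def test_split_ratio_and_stratification():
    cfg = SynthConfig(image_height=64, image_width=64, n_images_per_class=10,
                      tumor_size_range=(8, 20), seed=0)
    records = generate_dataset(cfg)
    train, val = split_dataset(records, 0.8, seed=1)
    assert len(train) == 24 and len(val) == 6
    for label in (0, 1, 2):
        assert sum(r.label == label for r in train) == 8
        assert sum(r.label == label for r in val) == 2
    ids = lambda rs: {r.image_id for r in rs}
    assert ids(train) | ids(val) == ids(records)
    assert ids(train) & ids(val) == set()
    train2, val2 = split_dataset(records, 0.8, seed=1)
    assert [r.image_id for r in train2] == [r.image_id for r in train]


def test_split_errors(small_dataset):
    with pytest.raises(ValueError, match="empty"):
        split_dataset([])
    with pytest.raises(ValueError, match="stratify"):
        split_dataset(small_dataset[:4])  # a class with one record


# ----------------------------------------------------------------------- loss
def _outputs_targets(kind, n=2, s=8):
    rng = np.random.default_rng(0)
    lab = rng.integers(0, 3, n)
    seg = rng.integers(0, 2, (n, s, s))
    dst = rng.integers(0, 5, (n, s, s))
    targets = {
        "clas": one_hot_encode(lab, 3),
        "seg": one_hot_encode(seg, 2),
        "dist": one_hot_encode(dst, 5),
    }
    if kind == "perfect":
        outputs = ModelOutputs(
            y_clas=targets["clas"].copy(), y_seg=targets["seg"].copy(), y_dist=targets["dist"].copy()
        )
    else:  # uniform
        outputs = ModelOutputs(
            y_clas=np.full((n, 3), 1 / 3),
            y_seg=np.full((n, s, s, 2), 1 / 2),
            y_dist=np.full((n, s, s, 5), 1 / 5),
        )
    return outputs, targets


def test_loss_zero_iff_perfect():
    outputs, targets = _outputs_targets("perfect")
    assert multitask_loss(outputs, targets) == pytest.approx(0.0, abs=1e-9)


def test_loss_uniform_closed_form():
    outputs, targets = _outputs_targets("uniform")
    expected = np.log(3) + np.log(2) + np.log(5)
    assert multitask_loss(outputs, targets) == pytest.approx(expected, rel=1e-6)


def test_loss_linearity_and_decomposition():
    outputs, targets = _outputs_targets("uniform")
    base = multitask_loss(outputs, targets, (1, 1, 1))
    doubled = multitask_loss(outputs, targets, (1, 2, 1))
    seg_only = multitask_loss(outputs, targets, (0, 1, 0))
    assert doubled - base == pytest.approx(seg_only, rel=1e-6)
    parts = [
        multitask_loss(outputs, targets, (1, 0, 0)),
        multitask_loss(outputs, targets, (0, 1, 0)),
        multitask_loss(outputs, targets, (0, 0, 1)),
    ]
    assert base == pytest.approx(sum(parts), rel=1e-6)


def test_loss_rejects_negative_weights():
    outputs, targets = _outputs_targets("uniform")
    with pytest.raises(ValueError, match="non-negative"):
        multitask_loss(outputs, targets, (-1, 1, 1))


def test_grad_is_softmax_minus_target():
    rng = np.random.default_rng(1)
    logits = {"clas": rng.normal(size=(4, 3)).astype(np.float32)}
    targets = {"clas": one_hot_encode(np.array([0, 1, 2, 0]), 3)}
    _, grads = _loss_and_grads(logits, targets, (1.0, 1.0, 1.0))
    z = logits["clas"] - logits["clas"].max(-1, keepdims=True)
    p = np.exp(z) / np.exp(z).sum(-1, keepdims=True)
    np.testing.assert_allclose(grads["clas"], (p - targets["clas"]) / 4, atol=1e-6)


# --------------------------------------------------------------- augmentation
def test_flip_applied_identically_to_all_fields():
    cfg = AugmentConfig(rotation_range=0.0, flip=True, crop_scale_range=None,
                        apply_probability=1.0)
    rng = np.random.default_rng(0)
    img = rng.random((16, 16)).astype(np.float32)
    mask = (rng.random((16, 16)) < 0.2).astype(np.uint8)
    dist = make_distance_map(mask).grid
    img2, mask2, dist2 = augment_sample(img, mask, dist, cfg, np.random.default_rng(5),
                                        regenerate_dist=False)
    np.testing.assert_array_equal(img2, img[:, ::-1])
    np.testing.assert_array_equal(mask2, mask[:, ::-1])
    np.testing.assert_array_equal(dist2, dist[:, ::-1])


def test_regenerated_dist_matches_transformed_mask():
    """Global stage: after any transform, dist target == map(transformed mask)."""
    cfg = AugmentConfig(rotation_range=15.0, flip=True, crop_scale_range=(0.8, 1.0),
                        apply_probability=0.7)
    rng = np.random.default_rng(2)
    img = rng.random((32, 32)).astype(np.float32)
    mask = np.zeros((32, 32), dtype=np.uint8)
    mask[10:18, 12:20] = 1
    for trial in range(5):
        _, mask2, dist2 = augment_sample(img, mask, None, cfg,
                                         np.random.default_rng(trial), regenerate_dist=True)
        np.testing.assert_array_equal(dist2, make_distance_map(mask2).grid)


# ------------------------------------------------------------------- training
@pytest.fixture(scope="module")
def tiny_split():
    cfg = SynthConfig(image_height=32, image_width=32, n_images_per_class=3,
                      tumor_size_range=(6, 12), tumor_count_range=(1, 2), seed=8)
    records = generate_dataset(cfg)
    return records[0:2] + records[3:5] + records[6:8], records[2:3] + records[5:6] + records[8:9]


DESK32 = ModelConfig(input_size=32, depth=3, base_filters=4)


def test_train_global_smoke_and_history(tiny_split):
    train, val = tiny_split
    cfg = TrainConfig.global_stage(max_epochs=1, seed=0)
    model, hist = train_global(train, val, DESK32, cfg)
    assert len(hist["train_loss"]) == 1
    assert np.isfinite(hist["train_loss"][0]) and np.isfinite(hist["val_loss"][0])


def test_train_global_empty_raises(tiny_split):
    _, val = tiny_split
    with pytest.raises(ValueError, match="empty"):
        train_global([], val, DESK32, TrainConfig.global_stage(max_epochs=1))


def test_overfit_two_images_loss_decreases(tiny_split):
    train, _ = tiny_split
    two = train[2:4]  # two benign images
    cfg = TrainConfig.global_stage(max_epochs=30, batch_size=1, seed=3)
    _, hist = train_global(two, two, DESK32, cfg)
    tl = hist["train_loss"]
    thirds = [np.mean(tl[:10]), np.mean(tl[10:20]), np.mean(tl[20:])]
    assert thirds[0] > thirds[1] > thirds[2]  # monotone downward trend
    assert thirds[2] < 0.8 * thirds[0]  # memorization clearly under way


def test_training_determinism(tiny_split):
    train, val = tiny_split
    cfg = TrainConfig.global_stage(max_epochs=1, seed=7)
    _, h1 = train_global(train, val, DESK32, cfg)
    _, h2 = train_global(train, val, DESK32, cfg)
    assert h1["train_loss"][0] == h2["train_loss"][0]
    assert h1["val_loss"][0] == h2["val_loss"][0]


def test_patch_transfer_preserves_forward(tiny_split):
    train, val = tiny_split
    gcfg = TrainConfig.global_stage(max_epochs=1, seed=0)
    global_model, _ = train_global(train, val, DESK32, gcfg)

    fresh = build_model(DESK32, seed=123)
    fresh.set_weights(global_model.get_weights())
    x = np.random.default_rng(0).random((1, 32, 32)).astype(np.float32)
    np.testing.assert_array_equal(
        forward(global_model, x).y_seg, forward(fresh, x).y_seg
    )


def test_train_patch_smoke_with_transfer(tiny_split):
    train, val = tiny_split
    gcfg = TrainConfig.global_stage(max_epochs=1, seed=0)
    global_model, _ = train_global(train, val, DESK32, gcfg)
    pcfg = TrainConfig.patch_stage(max_epochs=2, seed=1)
    sampler = SamplerConfig(patch_size=16, n_patches=4, min_tumor_pixels=8, seed=2)
    model, hist = train_patch(
        train, val, DESK32, pcfg, None,
        init_weights=global_model.get_weights(), sampler_config=sampler,
    )
    assert len(hist["train_loss"]) == 2
    assert all(np.isfinite(v) for v in hist["train_loss"] + hist["val_loss"])
    assert hist["train_loss"][-1] < hist["train_loss"][0] * 2  # sane scale
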