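"""The multi-task Seg-Unet network.

The architecture hybridizes the two classic encoder–decoder segmentation
designs: a VGG-style contracting path whose 2×2 max-pool layers *record their
argmax indices* (the SegNet mechanism), and an expanding path that unpools
into those indices and then concatenates the same-level encoder feature map
(the U-Net skip mechanism) before two conv–BN–ReLU blocks. Three heads hang
off the shared trunk:

* classification — global average pooling of the bottleneck feature followed
  by a dense layer and a softmax over {normal, benign, malignant};
* tumor segmentation — 1×1 conv on the decoder map, per-pixel softmax, 2 ch;
* high-risk (multi-level distance) segmentation — 1×1 conv, softmax, 5 ch.

Any branch can be disabled; disabled branches are absent from the graph (a
classification-only model builds no decoder). The trunk is fully
convolutional, so the same weights run at any input size divisible by
2^depth — this is what lets patch fine-tuning reuse global weights at a
smaller input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import (
    ConvBNReLU,
    Conv2D,
    Dense,
    maxpool2x2,
    maxunpool2x2,
    gather2x2,
    softmax,
)

__all__ = [
    "BranchFlags",
    "ModelConfig",
    "ModelOutputs",
    "SegUnet",
    "build_model",
    "forward",
    "TransferError",
    "save_weights",
    "load_weights",
]

N_CLASSES_CLAS = 3
N_CLASSES_SEG = 2
N_CLASSES_DIST = 5


class TransferError(RuntimeError):
    """Weight transfer between structurally incompatible models."""


@dataclass(frozen=True)
class BranchFlags:
    clas: bool = True
    seg: bool = True
    dist: bool = True

    def __post_init__(self):
        if not (self.clas or self.seg or self.dist):
            raise ValueError("at least one branch must be enabled")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture knobs. ``desk()`` is the small CPU-friendly preset."""

    input_size: int = 416
    depth: int = 4
    base_filters: int = 64
    n_classes_clas: int = N_CLASSES_CLAS
    n_classes_seg: int = N_CLASSES_SEG
    n_classes_dist: int = N_CLASSES_DIST
    branch_flags: BranchFlags = field(default_factory=BranchFlags)

    def __post_init__(self):
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^depth = {2**self.depth}"
            )
        if isinstance(self.branch_flags, dict):  # tolerate YAML round trips
            object.__setattr__(self, "branch_flags", BranchFlags(**self.branch_flags))

    @classmethod
    def desk(cls, **overrides) -> "ModelConfig":
        kw = dict(input_size=64, depth=3, base_filters=8)
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ModelOutputs:
    """Per-branch simplex outputs of one forward pass (batch leading dim)."""

    y_clas: np.ndarray | None = None  # (N, 3)
    y_seg: np.ndarray | None = None  # (N, H, W, 2)
    y_dist: np.ndarray | None = None  # (N, H, W, 5)


class SegUnet:
    """Encoder–decoder with pooling indices, skip concatenation, three heads."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        f = config.base_filters
        d = config.depth
        widths = [f * 2**i for i in range(d + 1)]  # encoder widths; widths[d] = bottleneck

        self.enc = []
        cin = 1
        for i in range(d):
            self.enc.append([ConvBNReLU(cin, widths[i], rng), ConvBNReLU(widths[i], widths[i], rng)])
            cin = widths[i]
        self.bott = [ConvBNReLU(widths[d - 1], widths[d], rng), ConvBNReLU(widths[d], widths[d], rng)]

        flags = config.branch_flags
        self.clas_dense = Dense(widths[d], config.n_classes_clas, rng) if flags.clas else None

        self.use_decoder = flags.seg or flags.dist
        self.dec = []
        if self.use_decoder:
            for i in reversed(range(d)):  # deepest level first
                self.dec.append(
                    {
                        "level": i,
                        "reduce": ConvBNReLU(2 * widths[i], widths[i], rng),
                        "post": [
                            ConvBNReLU(2 * widths[i], widths[i], rng),
                            ConvBNReLU(widths[i], widths[i], rng),
                        ],
                    }
                )
        self.seg_head = Conv2D(widths[0], config.n_classes_seg, rng, ksize=1) if flags.seg else None
        self.dist_head = Conv2D(widths[0], config.n_classes_dist, rng, ksize=1) if flags.dist else None

        self._fwd = None  # caches from the last training-mode forward

    # ------------------------------------------------------------------ layers
    def _layers(self):
        for blk in self.enc:
            yield from blk
        yield from self.bott
        if self.clas_dense is not None:
            yield self.clas_dense
        for d in self.dec:
            yield d["reduce"]
            yield from d["post"]
        if self.seg_head is not None:
            yield self.seg_head
        if self.dist_head is not None:
            yield self.dist_head

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def stats(self):
        out = []
        for layer in self._layers():
            out.extend(layer.stats())
        return out

    @property
    def n_params(self) -> int:
        return sum(p.v.size for p in self.params())

    def get_weights(self) -> dict:
        return {
            "params": [p.v.copy() for p in self.params()],
            "stats": [s.copy() for s in self.stats()],
        }

    def set_weights(self, weights: dict):
        params = self.params()
        stats = self.stats()
        mismatches = []
        if len(weights["params"]) != len(params) or len(weights.get("stats", [])) != len(stats):
            raise TransferError(
                f"weight container has {len(weights['params'])} params / "
                f"{len(weights.get('stats', []))} stats, model expects "
                f"{len(params)} / {len(stats)}"
            )
        for i, (p, w) in enumerate(zip(params, weights["params"])):
            if p.v.shape != w.shape:
                mismatches.append(f"param[{i}]: {p.v.shape} vs {w.shape}")
        if mismatches:
            raise TransferError("incompatible weights: " + "; ".join(mismatches))
        for p, w in zip(params, weights["params"]):
            p.v[...] = w
        for s, w in zip(stats, weights["stats"]):
            s[...] = w

    # ----------------------------------------------------------------- forward
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        if x.ndim != 4 or x.shape[-1] != 1:
            raise ValueError(f"expected (N,H,W) or (N,H,W,1) grayscale batch, got {x.shape}")
        step = 2**self.config.depth
        if x.shape[1] % step or x.shape[2] % step:
            raise ValueError(
                f"spatial extents {x.shape[1:3]} must be divisible by 2^depth = {step}"
            )
        if not np.isfinite(x).all():
            raise ValueError("input intensities must be finite")
        return x

    def forward_logits(self, x: np.ndarray, training: bool = False) -> dict:
        """Run the network; returns pre-softmax logits per enabled branch."""
        x = self._check_input(x)
        skips, idxs = [], []
        h = x
        for blk in self.enc:
            for layer in blk:
                h = layer.forward(h, training)
            skips.append(h)
            h, idx = maxpool2x2(h)
            idxs.append(idx)
        for layer in self.bott:
            h = layer.forward(h, training)

        logits = {}
        if self.clas_dense is not None:
            gap = h.mean(axis=(1, 2))
            logits["clas"] = self.clas_dense.forward(gap, training)

        if self.use_decoder:
            z = h
            for d in self.dec:
                i = d["level"]
                z = d["reduce"].forward(z, training)
                z = maxunpool2x2(z, idxs[i])
                z = np.concatenate([z, skips[i]], axis=-1)
                for layer in d["post"]:
                    z = layer.forward(z, training)
            if self.seg_head is not None:
                logits["seg"] = self.seg_head.forward(z, training)
            if self.dist_head is not None:
                logits["dist"] = self.dist_head.forward(z, training)

        self._fwd = {"idxs": idxs, "bott_shape": h.shape} if training else None
        return logits

    def backward(self, grads: dict):
        """Backpropagate gradients w.r.t. the logits of each enabled branch."""
        if self._fwd is None:
            raise RuntimeError("backward requires a preceding training-mode forward")
        idxs = self._fwd["idxs"]
        d_cfg = self.config.depth
        skip_grads = [None] * d_cfg

        g_bott = None
        if self.use_decoder:
            gz = None
            if self.dist_head is not None and "dist" in grads:
                gz = self.dist_head.backward(grads["dist"])
            if self.seg_head is not None and "seg" in grads:
                gs = self.seg_head.backward(grads["seg"])
                gz = gs if gz is None else gz + gs
            if gz is not None:
                for d in reversed(self.dec):
                    i = d["level"]
                    for layer in reversed(d["post"]):
                        gz = layer.backward(gz)
                    c = gz.shape[-1] // 2
                    g_dec, g_skip = gz[..., :c], gz[..., c:]
                    skip_grads[i] = np.ascontiguousarray(g_skip)
                    gz = gather2x2(np.ascontiguousarray(g_dec), idxs[i])
                    gz = d["reduce"].backward(gz)
                g_bott = gz

        if self.clas_dense is not None and "clas" in grads:
            g_gap = self.clas_dense.backward(grads["clas"])
            n, hh, ww, c = self._fwd["bott_shape"]
            g_from_clas = np.broadcast_to(g_gap[:, None, None, :] / (hh * ww), (n, hh, ww, c))
            g_bott = g_from_clas.copy() if g_bott is None else g_bott + g_from_clas

        if g_bott is None:
            raise ValueError("backward received no gradients for any enabled branch")
        g = g_bott
        for layer in reversed(self.bott):
            g = layer.backward(g)
        for i in reversed(range(d_cfg)):
            g = maxunpool2x2(g, idxs[i])
            if skip_grads[i] is not None:
                g = g + skip_grads[i]
            for layer in reversed(self.enc[i]):
                g = layer.backward(g)
        self._fwd = None


def build_model(config: ModelConfig, seed: int = 0) -> SegUnet:
    """Instantiate a Seg-Unet with seeded He-initialized weights."""
    return SegUnet(config, seed=seed)


def forward(model: SegUnet, images: np.ndarray) -> ModelOutputs:
    """Evaluation-mode forward pass; every enabled output is on the simplex."""
    logits = model.forward_logits(images, training=False)
    return ModelOutputs(
        y_clas=softmax(logits["clas"]) if "clas" in logits else None,
        y_seg=softmax(logits["seg"]) if "seg" in logits else None,
        y_dist=softmax(logits["dist"]) if "dist" in logits else None,
    )


def save_weights(model: SegUnet, path):
    """Checkpoint to .npz (weights + running stats) with a JSON config sidecar."""
    path = Path(path)
    w = model.get_weights()
    arrays = {f"p{i}": a for i, a in enumerate(w["params"])}
    arrays.update({f"s{i}": a for i, a in enumerate(w["stats"])})
    np.savez(path, **arrays)
    path.with_suffix(".json").write_text(json.dumps(model.config.to_dict(), indent=2))


def load_weights(path) -> SegUnet:
    path = Path(path)
    cfg_d = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig(
        **{k: (tuple(v) if isinstance(v, list) else v) for k, v in cfg_d.items() if k != "branch_flags"},
        branch_flags=BranchFlags(**cfg_d["branch_flags"]),
    )
    model = SegUnet(cfg)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        n_p = sum(1 for k in data.files if k.startswith("p"))
        n_s = sum(1 for k in data.files if k.startswith("s"))
        weights = {
            "params": [data[f"p{i}"] for i in range(n_p)],
            "stats": [data[f"s{i}"] for i in range(n_s)],
        }
    model.set_weights(weights)
    return model
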