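"""Instance detection on top of the Swin backbone.

The head is a proposal-free decoder: each of the four backbone stages is
projected by a lateral linear layer to a common width, upsampled
(nearest-neighbour) to the stage-1 token grid and summed; a final linear
layer maps every fused token to a 4x4 patch of foreground logits,
recovering full pixel resolution.  Instances are the connected components
of the thresholded foreground probability map, and each instance's
confidence score is its mean foreground probability, so score
thresholding is a simple monotone filter.

:class:`SomaSwinSegmenter` wraps the network in a scikit-learn style
estimator (``fit`` on images + instance masks, ``predict`` to instance
lists) so it composes with sklearn model-selection tooling; the
module-level ``train`` / ``predict_image`` functions and the CLI are thin
wrappers over it.

Training minimises pixel-wise binary cross-entropy against the union of
the ground-truth instance masks, with a positive-class weight countering
the sparse foreground.  AdamW with cosine learning-rate decay; per-step
losses are logged and a NaN loss aborts with a diagnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from . import autograd as ag
from .autograd import Tensor
from .backbone import BackboneConfig, SwinBackbone
from .nn import Adam, LayerNorm, Linear, Module
from .simulate import add_salt_pepper

__all__ = [
    "InstancePrediction",
    "HeadConfig",
    "TrainConfig",
    "SomaSwinNet",
    "SomaSwinSegmenter",
    "build_model",
    "predict_image",
    "filter_by_score",
    "extract_instances",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class InstancePrediction:
    """One detected soma: binary mask, confidence score, tight bounding box."""

    mask: np.ndarray
    score: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")
        if not self.mask.any():
            raise ValueError("instance mask must be nonempty")

    @property
    def box(self) -> tuple[int, int, int, int]:
        """(row, col, height, width), 0-based half-open."""
        ys, xs = np.nonzero(self.mask)
        return (int(ys.min()), int(xs.min()),
                int(ys.max() - ys.min() + 1), int(xs.max() - xs.min() + 1))

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class HeadConfig:
    fuse_dim: int = 64
    prob_threshold: float = 0.5   # foreground binarisation
    min_area: int = 8             # px; suppress speckle components

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 4           # images per optimiser step
    lr: float = 1e-3
    lr_final_fraction: float = 0.1  # cosine decay floor
    weight_decay: float = 1e-4
    pos_weight: float = 4.0
    augment_flips: bool = True
    augment_salt_pepper: float = 0.0   # corruption density, 0 disables
    seed: int = 0
    checkpoint_every: int = 0     # epochs; 0 disables intermediate checkpoints

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


class SegmentationHead(Module):
    """Fuse the four stage feature maps into per-pixel foreground logits."""

    def __init__(self, stage_dims, patch_size: int, fuse_dim: int,
                 rng: np.random.Generator):
        self.patch_size = int(patch_size)
        self.laterals = [Linear(d, fuse_dim, rng) for d in stage_dims]
        self.norm = LayerNorm(fuse_dim)
        self.out = Linear(fuse_dim, patch_size * patch_size, rng)

    def __call__(self, features: list[Tensor]) -> Tensor:
        h1, w1, _ = features[0].shape
        fused = None
        for s, (feat, lateral) in enumerate(zip(features, self.laterals)):
            x = lateral(feat)
            if s > 0:
                x = ag.upsample_nearest2d(x, 2 ** s)
                if x.shape[0] > h1 or x.shape[1] > w1:
                    x = x[:h1, :w1, :]
            fused = x if fused is None else fused + x
        y = self.out(ag.gelu(self.norm(fused)))       # (h1, w1, p*p)
        p = self.patch_size
        y = y.reshape(h1, w1, p, p).transpose(0, 2, 1, 3)
        return y.reshape(h1 * p, w1 * p)


class SomaSwinNet(Module):
    """Backbone + head; maps a grayscale image to foreground logits."""

    def __init__(self, backbone_cfg: BackboneConfig, head_cfg: HeadConfig,
                 rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        self.backbone_cfg = backbone_cfg
        self.head_cfg = head_cfg
        self.backbone = SwinBackbone(backbone_cfg, rng)
        self.head = SegmentationHead(self.backbone.stage_dims,
                                     backbone_cfg.patch_size, head_cfg.fuse_dim, rng)

    def __call__(self, image: np.ndarray) -> Tensor:
        image = np.asarray(image, dtype=np.float32)
        if image.ndim != 2 or image.size == 0:
            raise ValueError("input must be a nonempty 2D grayscale image")
        h, w = image.shape
        logits = self.head(self.backbone(image))
        return logits[:h, :w]

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        logits = self(image).data
        return (0.5 * (1.0 + np.tanh(0.5 * logits))).astype(np.float32)


def build_model(backbone_cfg: BackboneConfig | None = None,
                head_cfg: HeadConfig | None = None, seed: int = 0) -> SomaSwinNet:
    return SomaSwinNet(backbone_cfg or BackboneConfig(), head_cfg or HeadConfig(), seed)


# ---------------------------------------------------------------------------
# instance extraction and filtering


def extract_instances(prob: np.ndarray, prob_threshold: float = 0.5,
                      min_area: int = 8) -> list[InstancePrediction]:
    """Connected components of the thresholded probability map.

    Each component keeps only itself (fragments below ``min_area`` are
    discarded); its confidence is the mean foreground probability over its
    pixels.  Results are sorted by descending score, ties by component
    order.
    """
    fg = prob >= prob_threshold
    labels, n = ndimage.label(fg)
    preds = []
    for k in range(1, n + 1):
        mask = labels == k
        if int(mask.sum()) < min_area:
            continue
        preds.append(InstancePrediction(mask, float(prob[mask].mean())))
    preds.sort(key=lambda p: -p.score)
    return preds


def filter_by_score(preds: list[InstancePrediction],
                    threshold: float) -> list[InstancePrediction]:
    """Keep exactly the predictions with score >= threshold, stable order."""
    return [p for p in preds if p.score >= threshold]


def predict_image(model: SomaSwinNet, image: np.ndarray, threshold: float = 0.05,
                  prob_threshold: float | None = None,
                  min_area: int | None = None) -> list[InstancePrediction]:
    """Segment one image and drop low-confidence instances."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    prob = model.predict_proba(image)
    preds = extract_instances(
        prob,
        model.head_cfg.prob_threshold if prob_threshold is None else prob_threshold,
        model.head_cfg.min_area if min_area is None else min_area)
    return filter_by_score(preds, threshold)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: SomaSwinNet, path) -> None:
    """Weights plus embedded configs in one ``.npz`` file."""
    path = Path(path)
    state = model.state_dict()
    meta = json.dumps({"backbone": model.backbone_cfg.to_dict(),
                       "head": model.head_cfg.to_dict()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **{f"w::{k}": v for k, v in state.items()})


def load_checkpoint(path) -> SomaSwinNet:
    path = Path(path)
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[3:]: data[k] for k in data.files if k.startswith("w::")}
    model = SomaSwinNet(BackboneConfig.from_dict(meta["backbone"]),
                        HeadConfig(**meta["head"]), rng=0)
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------------------
# training


def _instance_masks(y) -> list[np.ndarray]:
    """Accept a list of binary masks or a labelled integer array."""
    if isinstance(y, np.ndarray) and y.ndim == 2 and not y.dtype == bool:
        return [y == k for k in np.unique(y) if k != 0]
    return [np.asarray(m, dtype=bool) for m in y]


def _cosine_lr(base: float, floor_frac: float, step: int, total: int) -> float:
    if total <= 1:
        return base
    t = step / (total - 1)
    floor = base * floor_frac
    return floor + 0.5 * (base - floor) * (1 + np.cos(np.pi * t))


class SomaSwinSegmenter(BaseEstimator):
    """Scikit-learn style estimator for soma instance segmentation.

    Parameters mirror the backbone, head and training configuration; all
    are plain constructor arguments so ``get_params`` / ``set_params``
    and ``clone`` work as usual.  ``fit`` expects a sequence of 2D
    grayscale images and, per image, either a list of binary instance
    masks or a labelled integer mask.

    Attributes set by ``fit`` (trailing underscore):

    ``model_``          the trained network,
    ``loss_history_``   per-optimiser-step training loss,
    ``n_iter_``         number of optimiser steps taken.
    """

    def __init__(self, patch_size: int = 4, embed_dim: int = 96,
                 depths: tuple = (2, 2, 6, 2), num_heads: tuple = (3, 6, 12, 24),
                 window_size: int = 7, mlp_ratio: float = 4.0,
                 use_relative_position_bias: bool = True, fuse_dim: int = 64,
                 prob_threshold: float = 0.5, min_area: int = 8,
                 score_threshold: float = 0.05, epochs: int = 30,
                 batch_size: int = 4, lr: float = 1e-3,
                 lr_final_fraction: float = 0.1, weight_decay: float = 1e-4,
                 pos_weight: float = 4.0, augment_flips: bool = True,
                 augment_salt_pepper: float = 0.0, seed: int = 0):
        self.patch_size = patch_size
        self.embed_dim = embed_dim
        self.depths = depths
        self.num_heads = num_heads
        self.window_size = window_size
        self.mlp_ratio = mlp_ratio
        self.use_relative_position_bias = use_relative_position_bias
        self.fuse_dim = fuse_dim
        self.prob_threshold = prob_threshold
        self.min_area = min_area
        self.score_threshold = score_threshold
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_final_fraction = lr_final_fraction
        self.weight_decay = weight_decay
        self.pos_weight = pos_weight
        self.augment_flips = augment_flips
        self.augment_salt_pepper = augment_salt_pepper
        self.seed = seed

    # -- config assembly ----------------------------------------------------

    def _backbone_config(self) -> BackboneConfig:
        return BackboneConfig(
            patch_size=self.patch_size, embed_dim=self.embed_dim,
            depths=tuple(self.depths), num_heads=tuple(self.num_heads),
            window_size=self.window_size, mlp_ratio=self.mlp_ratio,
            use_relative_position_bias=self.use_relative_position_bias)

    def _head_config(self) -> HeadConfig:
        return HeadConfig(fuse_dim=self.fuse_dim, prob_threshold=self.prob_threshold,
                          min_area=self.min_area)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs, batch_size=self.batch_size, lr=self.lr,
            lr_final_fraction=self.lr_final_fraction, weight_decay=self.weight_decay,
            pos_weight=self.pos_weight, augment_flips=self.augment_flips,
            augment_salt_pepper=self.augment_salt_pepper, seed=self.seed)

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y, model: SomaSwinNet | None = None):
        images = [np.asarray(im, dtype=np.float32) for im in X]
        if len(images) == 0:
            raise ValueError("training set is empty")
        if len(images) != len(y):
            raise ValueError("X and y must have the same length")
        targets = []
        for im, yi in zip(images, y):
            masks = _instance_masks(yi)
            union = np.zeros(im.shape, dtype=np.float32)
            for m in masks:
                if m.shape != im.shape:
                    raise ValueError("instance masks must match their image's shape")
                union[m] = 1.0
            targets.append(union)

        cfg = self._train_config()
        rng = np.random.default_rng(cfg.seed)
        if model is None:
            model = SomaSwinNet(self._backbone_config(), self._head_config(),
                                np.random.default_rng(cfg.seed))
        opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
        n = len(images)
        steps_per_epoch = max(1, -(-n // cfg.batch_size))
        total_steps = cfg.epochs * steps_per_epoch
        losses: list[float] = []
        step = 0
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                opt.zero_grad()
                batch_loss = 0.0
                for idx in batch:
                    im, tgt = images[idx], targets[idx]
                    if cfg.augment_flips:
                        if rng.random() < 0.5:
                            im, tgt = im[:, ::-1].copy(), tgt[:, ::-1].copy()
                        if rng.random() < 0.5:
                            im, tgt = im[::-1, :].copy(), tgt[::-1, :].copy()
                    if cfg.augment_salt_pepper > 0:
                        im = add_salt_pepper(im, cfg.augment_salt_pepper, rng)
                    logits = model(im)
                    loss = ag.bce_with_logits(logits, tgt, pos_weight=cfg.pos_weight)
                    loss.backward()
                    batch_loss += float(loss.data)
                batch_loss /= len(batch)
                if not np.isfinite(batch_loss):
                    raise RuntimeError(
                        f"training aborted: non-finite loss {batch_loss} at step {step} "
                        f"(lr={opt.lr:.3g}); inspect inputs or lower the learning rate")
                for p in opt.params:
                    if p.grad is not None:
                        p.grad /= len(batch)
                opt.lr = _cosine_lr(cfg.lr, cfg.lr_final_fraction, step, total_steps)
                opt.step()
                losses.append(batch_loss)
                step += 1
        self.model_ = model
        self.loss_history_ = losses
        self.n_iter_ = step
        return self

    # -- inference ----------------------------------------------------------

    def predict(self, X, threshold: float | None = None) -> list[list[InstancePrediction]]:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() or load a checkpoint")
        t = self.score_threshold if threshold is None else threshold
        return [predict_image(self.model_, np.asarray(im, dtype=np.float32), t)
                for im in X]

    def predict_proba(self, X) -> list[np.ndarray]:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() or load a checkpoint")
        return [self.model_.predict_proba(np.asarray(im, dtype=np.float32)) for im in X]

    def save(self, path) -> None:
        save_checkpoint(self.model_, path)

    @classmethod
    def from_checkpoint(cls, path) -> "SomaSwinSegmenter":
        model = load_checkpoint(path)
        bc, hc = model.backbone_cfg, model.head_cfg
        est = cls(patch_size=bc.patch_size, embed_dim=bc.embed_dim,
                  depths=bc.depths, num_heads=bc.num_heads,
                  window_size=bc.window_size, mlp_ratio=bc.mlp_ratio,
                  use_relative_position_bias=bc.use_relative_position_bias,
                  fuse_dim=hc.fuse_dim, prob_threshold=hc.prob_threshold,
                  min_area=hc.min_area)
        est.model_ = model
        est.loss_history_ = []
        est.n_iter_ = 0
        return est


def train(images, instance_masks, estimator: SomaSwinSegmenter | None = None,
          checkpoint_path=None, **params) -> SomaSwinSegmenter:
    """Convenience wrapper: fit a (possibly default) estimator and checkpoint it."""
    est = estimator or SomaSwinSegmenter(**params)
    est.fit(images, instance_masks)
    if checkpoint_path is not None:
        est.save(checkpoint_path)
    return est
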