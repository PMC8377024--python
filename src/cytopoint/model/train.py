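"""Training loop with annotation-consistent augmentation.

Geometric augmentations (flips, rotation, shear warp) are expressed as one
affine map applied identically to the image and to the centre-point
annotations; targets are re-encoded from the transformed annotations each
time, so the Gaussian peaks always sit on the augmented cell centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

from ..annotations import AnnotationSet, CentreAnnotation, ClassConfig, scale_class_configs
from ..errors import CytopointError, PreconditionError, ValidationError
from ..heatmap import HeatmapTensor, encode_targets
from .loss import LossConfig, focal_loss
from .network import CentreNet, normalize_images


@dataclass
class AugmentConfig:
    rotation_deg: float = 15.0
    shear: float = 0.1  # max absolute affine shear coefficient ("warp")
    flip_h: float = 0.5  # probability
    flip_v: float = 0.5
    color_jitter: float = 0.1  # max relative channel gain / brightness shift
    enabled: bool = True


@dataclass
class TrainConfig:
    epochs: int = 60
    weight_decay: float = 1e-5
    learning_rate: float = 1e-3
    batch_size: int = 8
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = params
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.v) for p in params]
        self.v = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - b1) * (p.g - m)
            v += (1.0 - b2) * (p.g * p.g - v)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.wd and p.decay:
                update = update + self.wd * p.v
            p.v -= lr * update


def one_cycle_lr(step: int, total: int, lr_max: float, warmup_frac: float = 0.3) -> float:
    """Linear warmup to ``lr_max`` then cosine decay to 5% of it."""
    if total <= 1:
        return lr_max
    warm = max(1, int(total * warmup_frac))
    if step < warm:
        return lr_max * (0.1 + 0.9 * step / warm)
    frac = (step - warm) / max(1, total - warm)
    return lr_max * (0.05 + 0.95 * 0.5 * (1.0 + np.cos(np.pi * frac)))


# ---------------------------------------------------------------------------
# Joint image/annotation augmentation
# ---------------------------------------------------------------------------

def _sample_affine(cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Random 2x2 map in (x, y) coordinates, applied about the tile centre."""
    theta = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    c, s = np.cos(theta), np.sin(theta)
    mat = np.array([[c, -s], [s, c]])
    kx = rng.uniform(-cfg.shear, cfg.shear)
    ky = rng.uniform(-cfg.shear, cfg.shear)
    mat = mat @ np.array([[1.0, kx], [ky, 1.0]])
    if rng.random() < cfg.flip_h:
        mat = np.array([[-1.0, 0.0], [0.0, 1.0]]) @ mat
    if rng.random() < cfg.flip_v:
        mat = np.array([[1.0, 0.0], [0.0, -1.0]]) @ mat
    return mat


def apply_affine(
    image: np.ndarray,
    points_xy: np.ndarray,
    mat_xy: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Warp an (H, W, 3) image and points by ``p' = c + M (p - c)``.

    Returns (warped image, transformed points, in-bounds mask).
    """
    size = image.shape[0]
    centre = (size - 1) / 2.0
    # ndimage works in (row, col) = (y, x): permute the matrix accordingly
    perm = mat_xy[::-1, ::-1]
    inv = np.linalg.inv(perm)
    offset = np.array([centre, centre]) - inv @ np.array([centre, centre])
    warped = np.stack(
        [
            ndimage.affine_transform(image[:, :, ch], inv, offset=offset, order=1,
                                     mode="nearest")
            for ch in range(image.shape[2])
        ],
        axis=-1,
    )
    if len(points_xy):
        moved = (points_xy - centre) @ mat_xy.T + centre
        inside = ((moved >= 0) & (moved < size)).all(axis=1)
    else:
        moved = points_xy
        inside = np.zeros(0, dtype=bool)
    return warped.astype(np.float32), moved, inside


def _color_jitter(image: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    gains = rng.uniform(1.0 - cfg.color_jitter, 1.0 + cfg.color_jitter, size=3)
    shift = rng.uniform(-cfg.color_jitter, cfg.color_jitter)
    return np.clip(image * gains[None, None, :] + shift, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# Dataset preparation
# ---------------------------------------------------------------------------

class _Sample:
    __slots__ = ("image", "points", "class_idx")

    def __init__(self, image, points, class_idx):
        self.image = image  # (S, S, 3) float32 in [0, 1], network resolution
        self.points = points  # (n, 2) x, y at network resolution
        self.class_idx = class_idx  # (n,) int


def _prepare(
    dataset: Sequence[tuple[np.ndarray, AnnotationSet]],
    input_size: int,
    class_names: Sequence[str],
) -> list[_Sample]:
    samples = []
    for image, anns in dataset:
        image = np.asarray(image)
        if image.dtype == np.uint8:
            image = image.astype(np.float32) / 255.0
        sf = image.shape[0] / input_size
        if image.shape[0] != input_size:
            image = resize(image, (input_size, input_size), order=1, anti_aliasing=sf > 1,
                           preserve_range=True).astype(np.float32)
        pts = np.array([(a.x / sf, a.y / sf) for a in anns], dtype=np.float64).reshape(-1, 2)
        idx = np.array([class_names.index(a.cell_class) for a in anns], dtype=np.intp)
        samples.append(_Sample(image.astype(np.float32), pts, idx))
    return samples


def _encode_sample(
    points: np.ndarray,
    class_idx: np.ndarray,
    classes_net: Sequence[ClassConfig],
    input_size: int,
) -> np.ndarray:
    """Target heatmap (H, W, C) from network-resolution points."""
    names = [c.cell_class for c in classes_net]
    s = AnnotationSet("aug", input_size, input_size)
    for (x, y), ci in zip(points, class_idx):
        s.add(CentreAnnotation("aug", float(x), float(y), names[ci], "truth"))
    return encode_targets(s, classes_net, out_size=input_size, scale_factor=1.0).values


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_model(
    net: CentreNet,
    dataset: Sequence[tuple[np.ndarray, AnnotationSet]],
    cfg: TrainConfig,
    classes: Sequence[ClassConfig],
    valid_data: Sequence[tuple[np.ndarray, AnnotationSet]] | None = None,
) -> tuple[CentreNet, pd.DataFrame]:
    """Train ``net`` in place; returns it with a per-epoch loss history.

    ``dataset`` items are ``(rgb image, truth AnnotationSet)`` pairs at any
    native tile size; images are resized to the network input size and class
    sigmas rescaled to match. All stochastic choices derive from ``cfg.seed``.
    """
    if len(dataset) == 0:
        raise PreconditionError("training dataset is empty")
    if len(classes) != net.config.n_classes:
        raise ValidationError("class config count != network output channels")
    input_size = net.config.input_size
    native = np.asarray(dataset[0][0]).shape[0]
    sf = native / input_size
    classes_net = scale_class_configs(classes, 1.0 / sf)
    class_names = [c.cell_class for c in classes]

    samples = _prepare(dataset, input_size, class_names)
    valid_samples = (
        _prepare(valid_data, input_size, class_names) if valid_data else None
    )

    history: list[dict] = []
    if cfg.epochs == 0:
        return net, pd.DataFrame(history, columns=["epoch", "train_loss", "valid_loss"])

    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(net.params(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    n_batches = int(np.ceil(len(samples) / cfg.batch_size))
    total_steps = cfg.epochs * n_batches
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(samples))
        batch_losses = []
        for b in range(n_batches):
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            images, targets = [], []
            for i in idx:
                s = samples[i]
                img, pts, cls = s.image, s.points, s.class_idx
                if cfg.augment.enabled:
                    mat = _sample_affine(cfg.augment, rng)
                    img, pts, inside = apply_affine(img, pts, mat)
                    pts, cls = pts[inside], cls[inside]
                    img = _color_jitter(img, cfg.augment, rng)
                images.append(img)
                targets.append(_encode_sample(pts, cls, classes_net, input_size))
            x = normalize_images(np.stack(images)).transpose(0, 3, 1, 2)
            y = np.stack(targets).transpose(0, 3, 1, 2)
            pred = net.forward(x, train=True)
            loss, grad = focal_loss(pred, y, cfg.loss, return_grad=True)
            if not np.isfinite(loss):
                raise CytopointError(
                    f"non-finite training loss at epoch {epoch}, batch {b}"
                )
            net.zero_grad()
            net.backward(grad.astype(np.float32))
            opt.step(lr=one_cycle_lr(step, total_steps, cfg.learning_rate))
            step += 1
            batch_losses.append(loss)
        valid_loss = float("nan")
        if valid_samples:
            valid_loss = _eval_loss(net, valid_samples, classes_net, cfg.loss, input_size)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(batch_losses)),
                "valid_loss": valid_loss,
            }
        )
    return net, pd.DataFrame(history)


def _eval_loss(net, samples, classes_net, loss_cfg, input_size) -> float:
    losses = []
    for s in samples:
        x = normalize_images(s.image[None]).transpose(0, 3, 1, 2)
        y = _encode_sample(s.points, s.class_idx, classes_net, input_size)[None].transpose(
            0, 3, 1, 2
        )
        losses.append(focal_loss(net.forward(x, train=False), y, loss_cfg))
    return float(np.mean(losses))


def predict_heatmaps(
    net: CentreNet,
    tiles: Sequence[np.ndarray],
    class_names: Sequence[str],
    tile_ids: Sequence[str] | None = None,
) -> list[HeatmapTensor]:
    """Run inference; one heatmap per tile, decoded coordinates native-scale."""
    if len(class_names) != net.config.n_classes:
        raise ValidationError("class name count != network output channels")
    input_size = net.config.input_size
    out = []
    for k, tile in enumerate(tiles):
        tile = np.asarray(tile)
        if tile.ndim != 3 or tile.shape[2] != 3:
            raise ValidationError("each tile must be an (H, W, 3) RGB array")
        if tile.dtype == np.uint8:
            tile = tile.astype(np.float32) / 255.0
        sf = tile.shape[0] / input_size
        if tile.shape[0] != input_size:
            tile = resize(tile, (input_size, input_size), order=1, anti_aliasing=sf > 1,
                          preserve_range=True).astype(np.float32)
        values = net(tile[None])[0]
        out.append(
            HeatmapTensor(
                np.clip(values.astype(np.float64), 0.0, 1.0),
                tuple(class_names),
                sf,
                tile_id=tile_ids[k] if tile_ids else "",
            )
        )
    return out
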