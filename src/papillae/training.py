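"""K-fold cross-validated training of the heatmap-regression networks.

Protocol: k = 5 folds, each fold trained for 500 epochs with batch size 2,
pixelwise MSE loss monitored alongside MAE, Adam at learning rate 1e-3, and
rotation / flip / intensity augmentation of the training pairs. Geometric
augmentations are applied identically to image and target heatmap so the
annotation/heatmap alignment is preserved; intensity adjustments touch the
image only.

A single master seed derives the fold-assignment, weight-initialization and
augmentation streams, so a run is reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import TrainingDivergedError, ValidationError
from .models import (ArchitectureSpec, ModelHandle, forward_padded,
                     instantiate, pad_to_multiple)
from .nn import Adam, F32


@dataclass
class AugmentationConfig:
    """Rotation / flip / intensity augmentation of (image, heatmap) pairs.

    rotation_degrees
        Symmetric free-rotation range; 90-degree multiples are also drawn.
    intensity_scale_range / intensity_shift_range
        Multiplicative and additive photometric jitter, image only,
        clamped back to [0, 1].
    probability
        Chance that a sample is augmented at all in a given epoch.
    """

    rotation_degrees: float = 15.0
    allow_flips: bool = True
    intensity_scale_range: tuple[float, float] = (0.9, 1.1)
    intensity_shift_range: float = 0.05
    probability: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.probability <= 1:
            raise ValidationError("probability must be in [0, 1]")
        lo, hi = self.intensity_scale_range
        if lo > hi:
            raise ValidationError("intensity_scale_range must be ordered")


@dataclass
class TrainingConfig:
    """The training protocol; defaults follow the full-scale study setup."""

    k_folds: int = 5
    epochs: int = 500
    batch_size: int = 2
    learning_rate: float = 1e-3
    optimizer: str = "Adam"
    loss: str = "MSE"
    monitor_metric: str = "MAE"
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValidationError("k_folds must be >= 2")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.optimizer != "Adam" or self.loss != "MSE":
            raise ValidationError("protocol is fixed to Adam + MSE")


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]


@dataclass
class TrainingHistory:
    """Per-epoch MSE/MAE records on the training and validation sets."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    train_mae: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_mse)


def make_folds(sample_ids: list[str], k: int, seed: int) -> list[FoldSplit]:
    """Random k-way partition; every id validates exactly once."""
    ids = list(sample_ids)
    if k > len(ids):
        raise ValidationError(f"k={k} exceeds {len(ids)} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    chunks = np.array_split(perm, k)
    splits = []
    for i, chunk in enumerate(chunks):
        val = tuple(ids[j] for j in chunk)
        train = tuple(ids[j] for j in perm if ids[j] not in set(val))
        splits.append(FoldSplit(fold_index=i, train_ids=train, val_ids=val))
    return splits


def augment_sample(
    image: np.ndarray,
    heatmap: np.ndarray,
    config: AugmentationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly augment an (H,W,C) image and its (H,W) target heatmap."""
    if image.shape[:2] != heatmap.shape:
        raise ValidationError("image and heatmap must share spatial shape")
    if rng.random() >= config.probability:
        return image, heatmap
    img, hm = image, heatmap
    # 90-degree multiples are exact; add a free rotation within the range
    quarter = int(rng.integers(0, 4))
    if quarter:
        img = np.rot90(img, quarter, axes=(0, 1))
        hm = np.rot90(hm, quarter, axes=(0, 1))
    if config.rotation_degrees > 0 and rng.random() < 0.5:
        angle = float(rng.uniform(-config.rotation_degrees, config.rotation_degrees))
        img = ndimage.rotate(img, angle, axes=(1, 0), reshape=False,
                             order=1, mode="reflect")
        hm = ndimage.rotate(hm, angle, axes=(1, 0), reshape=False,
                            order=1, mode="reflect")
    if config.allow_flips:
        if rng.random() < 0.5:
            img, hm = img[::-1], hm[::-1]
        if rng.random() < 0.5:
            img, hm = img[:, ::-1], hm[:, ::-1]
    lo, hi = config.intensity_scale_range
    scale = float(rng.uniform(lo, hi))
    shift = float(rng.uniform(-config.intensity_shift_range,
                              config.intensity_shift_range))
    img = img * scale + shift
    return (np.clip(img, 0.0, 1.0).astype(F32),
            np.clip(hm, 0.0, 1.0).astype(F32))


def _to_batches(images: np.ndarray, targets: np.ndarray, batch_size: int,
                rng: np.random.Generator):
    order = rng.permutation(len(images))
    for start in range(0, len(order), batch_size):
        idx = order[start:start + batch_size]
        yield images[idx], targets[idx]


def _eval_mse_mae(handle_net, images: np.ndarray, targets: np.ndarray,
                  batch_size: int = 4) -> tuple[float, float]:
    se, ae, n = 0.0, 0.0, 0
    for start in range(0, len(images), batch_size):
        x = images[start:start + batch_size]
        t = targets[start:start + batch_size]
        y = forward_padded(handle_net, x, training=False)
        diff = y - t
        se += float((diff ** 2).sum())
        ae += float(np.abs(diff).sum())
        n += diff.size
    return se / n, ae / n


def _stack(dataset) -> tuple[np.ndarray, np.ndarray]:
    """Stack [(image HWC, heatmap HW), ...] into NCHW / N1HW arrays."""
    imgs = np.stack([np.asarray(im, dtype=F32).transpose(2, 0, 1)
                     for im, _ in dataset])
    hms = np.stack([np.asarray(hm, dtype=F32)[None] for _, hm in dataset])
    return imgs, hms


def train_model(
    spec: ArchitectureSpec,
    train_set: list[tuple[np.ndarray, np.ndarray]],
    val_set: list[tuple[np.ndarray, np.ndarray]],
    config: TrainingConfig,
) -> tuple[ModelHandle, TrainingHistory]:
    """Train one network on (image, heatmap) pairs.

    ``train_set``/``val_set`` hold (H,W,C) images and (H,W) heatmaps in
    [0, 1]. Returns the final-epoch weights (no early stopping) and the
    per-epoch history. An empty ``val_set`` reuses the training set for the
    validation curves.
    """
    if not train_set:
        raise ValidationError("train_set must be non-empty")
    if not val_set:
        val_set = train_set
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    init_seed = int(seeds[0].generate_state(1)[0] % (2 ** 31))
    aug_rng = np.random.default_rng(seeds[1])

    handle = instantiate(spec, seed=init_seed)
    net = handle.network
    opt = Adam(net, lr=config.learning_rate)
    train_imgs_raw = [(np.asarray(im, dtype=F32), np.asarray(hm, dtype=F32))
                      for im, hm in train_set]
    val_imgs, val_hms = _stack(val_set)
    history = TrainingHistory()

    for epoch in range(config.epochs):
        pairs = []
        for im, hm in train_imgs_raw:
            aim, ahm = augment_sample(im, hm, config.augmentation, aug_rng)
            pairs.append((aim, ahm))
        imgs, hms = _stack(pairs)
        ep_se, ep_ae, ep_n = 0.0, 0.0, 0
        for xb, tb in _to_batches(imgs, hms, config.batch_size, aug_rng):
            h, w = xb.shape[2], xb.shape[3]
            xp, (ph, pw) = pad_to_multiple(xb, 16)
            y, state = net.forward(xp, training=True, rng=aug_rng)
            y_crop = y[:, :, ph // 2: ph // 2 + h, pw // 2: pw // 2 + w]
            diff = y_crop - tb
            loss = float((diff ** 2).mean())
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch + 1}")
            dy_crop = (2.0 / diff.size) * diff
            dy = np.zeros_like(y)
            dy[:, :, ph // 2: ph // 2 + h, pw // 2: pw // 2 + w] = dy_crop
            pgrads = net.backward(dy, state)
            opt.step(pgrads)
            ep_se += float((diff ** 2).sum())
            ep_ae += float(np.abs(diff).sum())
            ep_n += diff.size
        vmse, vmae = _eval_mse_mae(net, val_imgs, val_hms)
        history.train_mse.append(ep_se / ep_n)
        history.train_mae.append(ep_ae / ep_n)
        history.val_mse.append(vmse)
        history.val_mae.append(vmae)
    return handle, history


def run_cross_validation(
    spec: ArchitectureSpec,
    dataset: dict[str, tuple[np.ndarray, np.ndarray]],
    config: TrainingConfig,
) -> list[tuple[ModelHandle, TrainingHistory, FoldSplit]]:
    """Train one model per fold; each sample validates exactly once."""
    ids = sorted(dataset)
    if len(ids) < config.k_folds:
        raise ValidationError("dataset smaller than k_folds")
    fold_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2 ** 31))
    splits = make_folds(ids, config.k_folds, seed=fold_seed)
    results = []
    for split in splits:
        train = [dataset[i] for i in split.train_ids]
        val = [dataset[i] for i in split.val_ids]
        fold_cfg = TrainingConfig(
            k_folds=config.k_folds, epochs=config.epochs,
            batch_size=config.batch_size, learning_rate=config.learning_rate,
            augmentation=config.augmentation,
            seed=config.seed + 1009 * (split.fold_index + 1),
        )
        try:
            handle, history = train_model(spec, train, val, fold_cfg)
        except TrainingDivergedError as exc:
            raise TrainingDivergedError(
                f"fold {split.fold_index}: {exc}") from exc
        results.append((handle, history, split))
    return results
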