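"""Training harness: scratch training, fine-tuning, grid search, prediction.

The harness trains the small encoder-decoder variants of :mod:`.nn` with
either the generalized Dice loss or the gradient-weighted Dice loss, under
the protocol used for small-dataset transfer learning: pre-train on a
source domain, then fine-tune *all* layers (nothing frozen) on the target
domain with the learning rate scaled down by a factor of 10, so the
pre-trained weights act as an initialization that is gently adapted.
Per-epoch model selection uses the validation Dice at threshold 0.5
without post-processing; the best-epoch weights are what a run returns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .image import USImage
from .losses import gen_dice_loss, gradient_weight_mask, gw_dice_loss
from .metrics import dice_coefficient
from .nn import Adam, SegNet, load_checkpoint, save_checkpoint
from .preprocess import augment

__all__ = ["TrainConfig", "TrainResult", "MODEL_VARIANTS", "build_variant", "train", "grid_search", "predict"]

# Five stand-in "architectures": width/depth/seed variations of the same
# encoder-decoder family. Ensemble and transfer logic only assumes models
# emit probability maps, so the registry is trivially extensible.
MODEL_VARIANTS: dict[str, dict] = {
    "ed8": {"base_channels": 8, "extra_conv": False, "seed": 101},
    "ed12": {"base_channels": 12, "extra_conv": False, "seed": 202},
    "ed16": {"base_channels": 16, "extra_conv": False, "seed": 303},
    "ed8d": {"base_channels": 8, "extra_conv": True, "seed": 404},
    "ed12d": {"base_channels": 12, "extra_conv": True, "seed": 505},
}


def build_variant(variant: str, seed_offset: int = 0) -> SegNet:
    cfg = MODEL_VARIANTS[variant]
    return SegNet(cfg["base_channels"], cfg["extra_conv"], cfg["seed"] + seed_offset)


@dataclass
class TrainConfig:
    variant: str = "ed8"
    loss: str = "gw_dice"  # or "gen_dice"
    learning_rate: float = 1e-3
    fine_tune: bool = False  # scales LR by 0.1; requires source_checkpoint
    source_checkpoint: str | None = None
    batch_size: int = 4
    epochs: int = 15
    optimizer: str = "adam"
    augment_data: bool = True
    # Depth-weight profile used when loss == "gw_dice". The 2->1 prose
    # profile (baseline 0.5, scale 2) keeps every tumor pixel at least at
    # its ordinary Dice weight; the pure 1->0 profile makes the empty
    # prediction a strong local optimum and is unusable for training.
    gw_baseline: float = 0.5
    gw_scale: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss not in ("gen_dice", "gw_dice"):
            raise ValueError("loss must be 'gen_dice' or 'gw_dice'")
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("learning rate, batch size and epochs must be positive")
        if self.fine_tune and self.source_checkpoint is None:
            raise ValueError("fine_tune requires a source checkpoint")

    @property
    def effective_lr(self) -> float:
        return self.learning_rate * (0.1 if self.fine_tune else 1.0)


@dataclass
class TrainResult:
    net: SegNet
    config: TrainConfig
    log: pd.DataFrame  # epoch, split, loss_name, value
    best_epoch: int
    best_val_dice: float
    initial_val_dice: float = field(default=np.nan)


def _loss_and_grad(cfg: TrainConfig, mask: np.ndarray, probs: np.ndarray):
    if cfg.loss == "gen_dice":
        return gen_dice_loss(mask, probs, return_grad=True)
    weights = gradient_weight_mask(mask, baseline=cfg.gw_baseline, scale=cfg.gw_scale)
    return gw_dice_loss(mask, weights, probs, return_grad=True)


def _val_dice(net: SegNet, val: list[tuple[np.ndarray, np.ndarray]]) -> float:
    scores = [dice_coefficient(mask, net.predict(img) >= 0.5) for img, mask in val]
    return float(np.mean(scores)) if scores else np.nan


def _pixels(sample) -> np.ndarray:
    img = sample[0]
    return img.pixels if isinstance(img, USImage) else np.asarray(img)


def train(
    config: TrainConfig,
    train_set: list[tuple],
    val_set: list[tuple],
) -> TrainResult:
    """Train one model; returns the best-validation-Dice epoch's weights.

    ``train_set`` / ``val_set`` are lists of (image, mask) pairs where the
    image is a USImage or a bare [0,1] array and the mask is binary.
    Augmentation (mirror/rotation/gamma) is sampled fresh every epoch from
    the run seed, so two runs with the same config are identical.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation splits must be non-empty")
    if config.source_checkpoint is not None:
        net, _ = load_checkpoint(config.source_checkpoint)
    else:
        net = build_variant(config.variant, seed_offset=config.seed * 1000)
    initial_val = _val_dice(net, [(_pixels(s), s[1]) for s in val_set])

    opt = Adam(net, lr=config.effective_lr)
    rng = np.random.default_rng(config.seed)
    val_pairs = [(_pixels(s), s[1]) for s in val_set]
    rows = []
    best = (-np.inf, 0, net.get_weights())
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            net.zero_grad()
            batch = order[start : start + config.batch_size]
            for idx in batch:
                img, mask = train_set[idx]
                px = _pixels((img, mask))
                m = np.asarray(mask)
                if config.augment_data:
                    wrapped = img if isinstance(img, USImage) else USImage(px)
                    aug_img, m = augment(wrapped, m, int(rng.integers(0, 2**31 - 1)))
                    px = aug_img.pixels
                if not m.any():
                    continue  # rotation can push a sliver lesion out of frame
                probs = net.forward(px)
                loss, grad = _loss_and_grad(config, m, probs)
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                net.backward(grad / len(batch))
                epoch_losses.append(loss)
            opt.step()
        mean_loss = float(np.mean(epoch_losses)) if epoch_losses else np.nan
        vdice = _val_dice(net, val_pairs)
        rows.append({"epoch": epoch, "split": "train", "loss_name": config.loss, "value": mean_loss})
        rows.append({"epoch": epoch, "split": "val", "loss_name": "dice", "value": vdice})
        if vdice > best[0]:
            best = (vdice, epoch, net.get_weights())
    net.set_weights(best[2])
    return TrainResult(
        net=net,
        config=config,
        log=pd.DataFrame(rows),
        best_epoch=best[1],
        best_val_dice=float(best[0]),
        initial_val_dice=initial_val,
    )


def grid_search(
    grid: dict[str, list],
    train_set: list[tuple],
    val_set: list[tuple],
    base_config: TrainConfig | None = None,
) -> tuple[TrainConfig, pd.DataFrame]:
    """Exhaustive grid search; ranks every cell by best validation Dice.

    ``grid`` maps TrainConfig field names to candidate values. Returns the
    winning config and a leaderboard with one row per cell.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    base = base_config or TrainConfig()
    keys = sorted(grid)
    rows = []
    best: tuple[float, TrainConfig] = (-np.inf, base)
    for values in product(*(grid[k] for k in keys)):
        cfg = replace(base, **dict(zip(keys, values)))
        result = train(cfg, train_set, val_set)
        rows.append({**dict(zip(keys, values)), "val_dice": result.best_val_dice})
        if result.best_val_dice > best[0]:
            best = (result.best_val_dice, cfg)
    leaderboard = pd.DataFrame(rows).sort_values("val_dice", ascending=False).reset_index(drop=True)
    return best[1], leaderboard


def predict(net_or_checkpoint, images: list) -> list[np.ndarray]:
    """Probability maps for a list of images (USImage or arrays)."""
    if isinstance(net_or_checkpoint, (str, Path)):
        net, _ = load_checkpoint(net_or_checkpoint)
    else:
        net = net_or_checkpoint
    out = []
    for img in images:
        px = img.pixels if isinstance(img, USImage) else np.asarray(img)
        out.append(net.predict(px))
    return out


def save_result(path: str | Path, result: TrainResult) -> None:
    """Checkpoint + config sidecar + CSV training log."""
    path = Path(path)
    save_checkpoint(
        path,
        result.net,
        extra={
            "train_config": {
                k: v for k, v in result.config.__dict__.items() if not k.startswith("_")
            },
            "best_epoch": result.best_epoch,
            "best_val_dice": result.best_val_dice,
        },
    )
    result.log.to_csv(Path(str(path).replace(".npz", "") + "_log.csv"), index=False)
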