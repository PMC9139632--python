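"""Balanced pool construction, augmentation and the optimization loop.

Whole-brain patch extraction produces vastly more healthy windows than
tumor windows (hundreds of thousands vs tens of thousands), so the pool is
balanced once per run: healthy patches are undersampled uniformly without
replacement down to the per-class target, and tumor patches are resampled
with replacement up to the same count when undersupplied. Augmentation
(flips, small rotations, blur, random gamma) is applied on the fly per
batch; spatial transforms act identically on all five channels and the
label crop, while blur and gamma touch only the image channels.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .nn import Adam, ReduceLROnPlateau, UNet, UNetSpec, dice_bce_loss
from .patching import PatchStack


class DataError(ValueError):
    """Raised when a patch pool cannot support training."""


@dataclass
class BalancedPool:
    healthy: list
    tumor: list
    per_class_target: int
    seed: int

    def __len__(self) -> int:
        return len(self.healthy) + len(self.tumor)


@dataclass
class TrainConfig:
    """Optimization hyper-parameters.

    Defaults: Adam at an initial learning rate of 1e-4, halved (factor 0.5)
    when the validation metric has not improved for more than 2 epochs, up
    to 30 epochs, batch size 256, L2 regularization beta = 1e-5.
    """

    initial_lr: float = 1e-4
    lr_factor: float = 0.5
    lr_patience: int = 2
    max_epochs: int = 30
    batch_size: int = 256
    l2_beta: float = 1e-5
    loss: str = "dice_bce"
    seed: int = 0
    augment_prob: float = 0.5
    rotation_deg: float = 15.0
    blur_sigma_max: float = 1.0
    gamma_range: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        if min(self.initial_lr, self.lr_factor, self.batch_size) <= 0:
            raise ValueError("rates and batch size must be positive")
        if self.lr_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


def balance_pool(
    patches: Iterable[PatchStack], per_class_target: int = 30_000, seed: int = 0
) -> BalancedPool:
    """Split a patch stream by class and balance the two classes.

    Healthy patches are sampled uniformly without replacement down to the
    target (or kept in full if fewer) with a single streaming reservoir
    pass, so arbitrarily large patch streams never need to reside in
    memory; tumor patches are sampled with replacement up to the target
    when undersupplied. Both classes end up with
    ``min(per_class_target, len(healthy))`` members so the pool stays
    balanced even when healthy windows are scarce.
    """
    rng = np.random.default_rng(seed)
    healthy: list = []
    tumor: list = []
    n_healthy_seen = 0
    for p in patches:
        if p.is_tumor:
            tumor.append(p)
            continue
        if n_healthy_seen < per_class_target:
            healthy.append(p)
        else:
            j = int(rng.integers(0, n_healthy_seen + 1))
            if j < per_class_target:
                healthy[j] = p
        n_healthy_seen += 1
    if not tumor:
        raise DataError("pool contains no tumor patches; nothing to learn")
    n = min(per_class_target, n_healthy_seen) if n_healthy_seen else per_class_target
    if len(tumor) > n:
        keep = rng.choice(len(tumor), size=n, replace=False)
        tumor = [tumor[i] for i in sorted(keep)]
    elif len(tumor) < n:
        extra = rng.choice(len(tumor), size=n - len(tumor), replace=True)
        tumor = tumor + [tumor[i] for i in extra]
    return BalancedPool(healthy, tumor, per_class_target, seed)


def augment(
    p: PatchStack,
    rng: np.random.Generator,
    *,
    prob: float = 0.5,
    rotation_deg: float = 15.0,
    blur_sigma_max: float = 1.0,
    gamma_range: tuple[float, float] = (1.0, 1.0),
) -> PatchStack:
    """Randomly perturb one stack; label geometry follows the image exactly."""
    data = p.data
    label = p.label_crop
    if prob > 0 and rng.random() < prob:  # horizontal flip
        data = data[:, :, ::-1]
        label = label[:, ::-1]
    if prob > 0 and rng.random() < prob:  # vertical flip
        data = data[:, ::-1, :]
        label = label[::-1, :]
    if prob > 0 and rotation_deg > 0 and rng.random() < prob:
        angle = rng.uniform(-rotation_deg, rotation_deg)
        data = ndimage.rotate(data, angle, axes=(1, 2), reshape=False,
                              order=1, mode="nearest")
        label = ndimage.rotate(label, angle, reshape=False, order=0,
                               mode="nearest")
    if prob > 0 and blur_sigma_max > 0 and rng.random() < prob:
        sigma = rng.uniform(0, blur_sigma_max)
        data = ndimage.gaussian_filter(data, sigma=(0, sigma, sigma))
    lo, hi = gamma_range
    if prob > 0 and (lo, hi) != (1.0, 1.0) and rng.random() < prob:
        gamma = rng.uniform(lo, hi)
        data = np.clip(data, 0, 1) ** gamma
    return PatchStack(np.ascontiguousarray(data), p.reference_slice, p.row, p.col,
                      np.ascontiguousarray(label))


def build_unet(spec: UNetSpec, patch_size: int, seed: int = 0) -> UNet:
    """Instantiate the U-Net, checking patch-size/depth compatibility."""
    if patch_size % (2**spec.depth):
        raise ValueError(
            f"patch size {patch_size} not divisible by 2^{spec.depth}; "
            "reduce the depth or pad the patches"
        )
    return UNet(spec, np.random.default_rng(seed))


class TrainingError(RuntimeError):
    pass


def _batch_arrays(patches: Sequence[PatchStack]):
    x = np.stack([p.data for p in patches]).astype(np.float32)
    y = np.stack([p.label_crop for p in patches]).astype(np.float32)
    return x, y


def validation_loss(model: UNet, patches: Sequence[PatchStack], loss: str,
                    batch_size: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(patches), batch_size):
        x, y = _batch_arrays(patches[i : i + batch_size])
        logits = model.forward_logits(x, train=False)
        val, _ = dice_bce_loss(logits, y, mode=loss)
        total += val * len(x)
        n += len(x)
    return total / max(n, 1)


def train_model(
    pool: BalancedPool,
    config: TrainConfig,
    validation: Sequence[PatchStack],
    *,
    spec: UNetSpec | None = None,
    model: UNet | None = None,
    verbose: bool = False,
) -> tuple[UNet, list[dict]]:
    """Optimize the U-Net on a balanced pool.

    Returns the trained model and a per-epoch history (loss, learning rate,
    validation metric). Fully reproducible given ``config.seed``.
    """
    patches = pool.healthy + pool.tumor
    if not patches or not len(validation):
        raise DataError("empty training pool or validation set")
    patch_size = patches[0].data.shape[-1]
    if model is None:
        if spec is None:
            spec = UNetSpec()
        model = build_unet(spec, patch_size, seed=config.seed)
    opt = Adam(model.params(), lr=config.initial_lr, weight_decay=config.l2_beta)
    sched = ReduceLROnPlateau(opt, factor=config.lr_factor, patience=config.lr_patience)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(patches))
        epoch_loss, steps = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = [patches[i] for i in order[start : start + config.batch_size]]
            batch = [
                augment(
                    p, rng, prob=config.augment_prob,
                    rotation_deg=config.rotation_deg,
                    blur_sigma_max=config.blur_sigma_max,
                    gamma_range=config.gamma_range,
                )
                for p in batch
            ]
            x, y = _batch_arrays(batch)
            logits = model.forward_logits(x, train=True)
            loss, dlogits = dice_bce_loss(logits, y, mode=config.loss)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            model.backward(dlogits)
            opt.step(model.grads())
            epoch_loss += loss
            steps += 1
        val = validation_loss(model, validation, config.loss, config.batch_size)
        lr_now = opt.lr
        sched.step(val)
        history.append(
            {"epoch": epoch, "loss": epoch_loss / max(steps, 1),
             "val_loss": val, "lr": lr_now}
        )
        if verbose:
            print(f"epoch {epoch}: loss={history[-1]['loss']:.4f} "
                  f"val={val:.4f} lr={lr_now:.2e}")
    return model, history


# ---------------------------------------------------------------- checkpoints


def save_checkpoint(model: UNet, config: TrainConfig, path,
                    history: list[dict] | None = None) -> None:
    """Weights as .npz plus a JSON sidecar with architecture/config/seed."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    spec = model.spec
    sidecar = {
        "unet_spec": {"in_channels": spec.in_channels, "depth": spec.depth,
                      "base_filters": spec.base_filters},
        "train_config": {k: v for k, v in asdict(config).items()},
        "seed": config.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=list))
    if history is not None:
        with open(path.with_suffix(".history.csv"), "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(history[0]))
            writer.writeheader()
            writer.writerows(history)


def load_checkpoint(path) -> tuple[UNet, dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = UNetSpec(**sidecar["unet_spec"])
    model = UNet(spec, np.random.default_rng(0))
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict(dict(data))
    return model, sidecar
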