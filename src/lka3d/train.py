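"""Training and inference loops wiring networks, losses and the pipeline.

Defaults follow the segmentation setup this package implements: Adam at
an initial learning rate of 3e-4, 200 epochs, batch size 1, class-weighted
soft Dice loss (or BCE + Dice for region channels), deep supervision with
geometric head weights, and polynomial learning-rate decay (power 0.9; a
constant schedule is available).  Every source of randomness (weight
initialisation, data order, augmentation) derives from the config seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .augment import AugmentationPolicy, augment
from .io import VolumeSample
from .losses import (
    ClassWeights,
    bce_dice_loss,
    class_weights_from_labels,
    deep_supervision_weights,
    soft_dice_loss,
)
from .unet import LKAUNet3d, NetworkConfig, build_network

__all__ = [
    "TrainConfig",
    "TrainResult",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
    "split_samples",
]

CHECKPOINT_VERSION = 1
LOG_COLUMNS = ["epoch", "step", "loss", "loss_main", "loss_aux", "lr", "seed"]


@dataclass
class TrainConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    lr: float = 3e-4
    epochs: int = 200
    batch_size: int = 1
    loss: str = "weighted_dice"  # or "bce_dice"
    lr_schedule: str = "poly"  # or "const"
    poly_power: float = 0.9
    seed: int = 0
    augment: bool = False
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy.identity)
    checkpoint_dir: str | None = None
    log_path: str | None = None

    def __post_init__(self):
        if self.batch_size != 1:
            raise ValueError("only batch size 1 is supported")
        if self.loss not in ("weighted_dice", "bce_dice"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.lr_schedule not in ("poly", "const"):
            raise ValueError(f"unknown schedule {self.lr_schedule!r}")


@dataclass
class TrainResult:
    net: LKAUNet3d
    log: pd.DataFrame
    class_weights: ClassWeights | None
    best_checkpoint: str | None = None
    last_checkpoint: str | None = None


def _one_hot(label: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((n_classes,) + label.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = label == c
    return out


def _downsample_label(label: np.ndarray, factor: int) -> np.ndarray:
    return label[::factor, ::factor, ::factor]


def _epoch_lr(cfg: TrainConfig, epoch: int) -> float:
    if cfg.lr_schedule == "const":
        return cfg.lr
    return cfg.lr * (1.0 - epoch / cfg.epochs) ** cfg.poly_power


def _case_loss(cfg: TrainConfig, net, sample: VolumeSample,
               weights: ClassWeights | None):
    O = cfg.network.out_channels
    x = nn.Tensor(sample.image[None])
    main, aux, _ = net(x)
    heads = [main] + list(aux)
    ws = deep_supervision_weights(len(heads))
    total = None
    main_val = aux_val = 0.0
    for i, (logits, w) in enumerate(zip(heads, ws)):
        factor = 2**i
        lab = _downsample_label(sample.label, factor)
        if cfg.loss == "weighted_dice":
            # O softmax channels: background + foreground classes
            target = nn.Tensor(_one_hot(lab, O)[None])
            probs = logits.softmax(axis=1)
            li = soft_dice_loss(probs, target, weights)
        else:
            # O sigmoid channels: one binary mask per foreground class/region
            fg = np.stack([(lab == c) for c in range(1, O + 1)]).astype(np.float32)
            target = nn.Tensor(fg[None])
            probs = logits.sigmoid()
            li = bce_dice_loss(probs, target)
        term = li * float(w)
        total = term if total is None else total + term
        if i == 0:
            main_val = float(li.data)
        else:
            aux_val += float(li.data) * float(w)
    return total, main_val, aux_val


def train(cfg: TrainConfig, samples: list[VolumeSample],
          val_samples: list[VolumeSample] | None = None,
          callback=None, callback_every: int = 0) -> TrainResult:
    """Train a network on in-memory samples; returns net + CSV-ready log.

    Raises on NaN loss, naming the offending case and loss components.
    ``callback(net, epoch)`` is invoked every ``callback_every`` epochs
    (when both are given); returning True stops training early.
    """
    for s in samples:
        if s.label is None:
            raise ValueError(f"sample {s.identifier!r} has no label volume")
    net = build_network(cfg.network, seed=cfg.seed)
    opt = nn.Adam(net.parameters(), lr=cfg.lr)
    weights = None
    if cfg.loss == "weighted_dice":
        weights = class_weights_from_labels(
            (s.label for s in samples), cfg.network.out_channels
        )
    order_rng = np.random.default_rng(cfg.seed + 1)
    aug_rng = np.random.default_rng(cfg.seed + 2)

    rows = []
    step = 0
    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
    best_loss, best_path, last_path = np.inf, None, None

    for epoch in range(cfg.epochs):
        opt.lr = _epoch_lr(cfg, epoch)
        idx = order_rng.permutation(len(samples))
        epoch_loss = 0.0
        for i in idx:
            sample = samples[i]
            if cfg.augment:
                sample = augment(sample, cfg.augmentation,
                                 seed=int(aug_rng.integers(2**31)))
            loss, lmain, laux = _case_loss(cfg, net, sample, weights)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, case "
                    f"{samples[i].identifier!r}: total={lval}, "
                    f"main={lmain}, aux={laux}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            step += 1
            epoch_loss += lval
            rows.append({
                "epoch": epoch, "step": step, "loss": lval,
                "loss_main": lmain, "loss_aux": laux,
                "lr": opt.lr, "seed": cfg.seed,
            })
        epoch_loss /= len(samples)
        if ckpt_dir:
            last_path = str(ckpt_dir / "last.npz")
            save_checkpoint(net, cfg, last_path)
            if epoch_loss < best_loss:
                best_loss = epoch_loss
                best_path = str(ckpt_dir / "best.npz")
                save_checkpoint(net, cfg, best_path)
        if callback is not None and callback_every and (epoch + 1) % callback_every == 0:
            if callback(net, epoch):
                break

    log = pd.DataFrame(rows, columns=LOG_COLUMNS)
    if cfg.log_path:
        Path(cfg.log_path).parent.mkdir(parents=True, exist_ok=True)
        log.to_csv(cfg.log_path, index=False)
    return TrainResult(net=net, log=log, class_weights=weights,
                       best_checkpoint=best_path, last_checkpoint=last_path)


def predict(net: LKAUNet3d, samples: list[VolumeSample],
            save_attention: bool = False, threshold: float = 0.5):
    """Segment samples; returns (label volumes, attention maps per case).

    Softmax heads give argmax class labels; sigmoid heads give per-channel
    0.5-threshold region masks stacked as a (C-1, D, H, W) binary volume.
    """
    cfg = net.config
    labels, attentions = [], []
    for s in samples:
        with nn.tensor.no_grad():
            main, _, maps = net(nn.Tensor(s.image[None]))
        if cfg.head_activation == "softmax":
            probs = main.softmax(axis=1).data[0]
            labels.append(np.argmax(probs, axis=0).astype(np.int16))
        else:
            probs = main.sigmoid().data[0]
            labels.append((probs >= threshold).astype(np.int16))
        attentions.append(
            {sc: m.data[0].copy() for sc, m in maps.items()} if save_attention else {}
        )
    return labels, attentions


def save_checkpoint(net: LKAUNet3d, cfg: TrainConfig, path) -> None:
    """Versioned checkpoint: network weights + full config + seed."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "seed": cfg.seed,
        "train": {k: v for k, v in asdict(cfg).items()
                  if k not in ("network", "augmentation")},
        "network": cfg.network.to_dict(),
    }
    state = {f"param/{k}": v for k, v in net.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[LKAUNet3d, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    net = build_network(NetworkConfig.from_dict(meta["network"]), seed=meta["seed"])
    net.load_state_dict(state)
    return net, meta


def split_samples(samples: list[VolumeSample], val_fraction: float = 0.2
                  ) -> tuple[list[VolumeSample], list[VolumeSample]]:
    """Deterministic 80/20 split by identifier hash."""
    train_set, val_set = [], []
    for s in samples:
        h = int(hashlib.md5(s.identifier.encode()).hexdigest(), 16) % 100
        (val_set if h < int(val_fraction * 100) else train_set).append(s)
    return train_set, val_set
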