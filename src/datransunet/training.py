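"""Training loop, evaluation and prediction.

Defaults follow the published protocol: Adam with learning rate 1e-3,
beta1 0.9 and weight decay 1e-4 for the 2-D binary datasets; an SGD
preset (lr 0.01, momentum 0.9, weight decay 1e-4, batch 24, poly decay)
mirrors the multi-organ CT recipe.  The learning-rate schedule is
constant unless ``poly`` (power 0.9) is selected.  Binary models
(``n_classes == 1``) train with the BCE+Dice compound loss on sigmoid
probabilities and predict foreground at probability >= 0.5 (ties go to
foreground); multi-class models train with CE+Dice on logits and predict
by argmax.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import nn
from .losses import bce_dice_loss, ce_dice_loss
from .metrics import evaluate_masks
from .network import (DATransUNet, NetworkConfig, build_model, load_checkpoint,
                      load_pretrained, save_checkpoint, tiny_config)
from .nn import functional as F
from .nn.tensor import Tensor, no_grad
from .phantoms import read_dataset, split_dataset


@dataclass
class TrainConfig:
    network: NetworkConfig = field(default_factory=tiny_config)
    optimizer: Literal["adam", "sgd"] = "adam"
    lr: float = 1e-3
    weight_decay: float = 1e-4
    momentum: float = 0.9          # classical momentum for SGD, beta1 for Adam
    batch_size: int = 4
    epochs: int = 50
    loss: Literal["bce_dice", "ce_dice"] = "bce_dice"
    seed: int = 0
    schedule: Literal["constant", "poly"] = "constant"
    val_fraction: float = 0.25
    stop_at_dice: Optional[float] = None   # early-stop once val dice reaches this
    output_dir: Optional[str] = None
    pretrained: Optional[str] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["network"] = self.network.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if isinstance(d.get("network"), dict):
            d["network"] = NetworkConfig.from_dict(d["network"])
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def synapse_preset(network: NetworkConfig) -> TrainConfig:
    """Multi-organ CT recipe: SGD 0.01, momentum 0.9, wd 1e-4, batch 24."""
    return TrainConfig(network=network, optimizer="sgd", lr=0.01, momentum=0.9,
                       weight_decay=1e-4, batch_size=24, loss="ce_dice",
                       schedule="poly")


def _to_batch(items, in_channels: int):
    images = np.stack([im for im, _ in items]).astype(np.float32)
    if images.ndim == 3:
        images = images[:, None]
    if images.shape[1] == 1 and in_channels == 3:
        images = np.repeat(images, 3, axis=1)
    masks = np.stack([mk for _, mk in items]).astype(np.int64)
    return images, masks


def predict_mask(model: DATransUNet, image: np.ndarray) -> np.ndarray:
    """Label mask for one image (HxW or CxHxW), model in eval mode."""
    model.eval()
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.shape[0] == 1 and model.cfg.in_channels == 3:
        x = np.repeat(x, 3, axis=0)
    with no_grad():
        logits = model(x[None]).numpy()[0]
    if model.cfg.n_classes == 1:
        from scipy.special import expit
        prob = expit(logits[0])
        return (prob >= 0.5).astype(np.int64)
    return logits.argmax(axis=0).astype(np.int64)


def _compute_loss(model: DATransUNet, images: np.ndarray, masks: np.ndarray,
                  loss_name: str) -> Tensor:
    logits = model(Tensor(images))
    if loss_name == "bce_dice":
        if model.cfg.n_classes != 1:
            raise ValueError("bce_dice requires a single-channel (binary) model")
        probs = F.sigmoid(F.reshape(logits, (logits.shape[0],) + logits.shape[2:]))
        return bce_dice_loss(probs, masks.astype(np.float32))
    return ce_dice_loss(logits, masks, model.cfg.n_classes)


def _eval_mean_dice_iou(model, items) -> tuple[float, float]:
    n_classes = max(model.cfg.n_classes, 2)
    dices, ious = [], []
    for image, mask in items:
        report = evaluate_masks(predict_mask(model, image), mask, n_classes)
        dices.append(report.mean_dice)
        ious.append(report.mean_iou)
    return float(np.mean(dices)), float(np.mean(ious))


def train(cfg: TrainConfig, dataset) -> tuple[DATransUNet, pd.DataFrame]:
    """Train a model; returns it with the per-epoch history.

    ``dataset`` is a directory in ``images/ masks/`` layout or an
    in-memory list of (image, mask) pairs.  A ``val_fraction`` split is
    held out for model selection (the best-validation weights are kept
    and, when ``output_dir`` is set, written to ``best.npz``); with
    ``val_fraction = 0`` validation runs on the training set itself.
    """
    if not isinstance(dataset, (list, tuple)):
        dataset = read_dataset(dataset)
    if cfg.val_fraction > 0:
        train_items, val_items = split_dataset(dataset, 1.0 - cfg.val_fraction, cfg.seed)
    else:
        train_items, val_items = list(dataset), list(dataset)

    model = build_model(cfg.network, seed=cfg.seed)
    if cfg.pretrained:
        load_pretrained(model, cfg.pretrained)
    if cfg.optimizer == "adam":
        opt = nn.Adam(model.parameters(), lr=cfg.lr, betas=(cfg.momentum, 0.999),
                      weight_decay=cfg.weight_decay)
    else:
        opt = nn.SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                     weight_decay=cfg.weight_decay)

    out_dir = Path(cfg.output_dir) if cfg.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = []
    history = []
    rng = np.random.default_rng(cfg.seed)
    n_steps_total = cfg.epochs * max(1, int(np.ceil(len(train_items) / cfg.batch_size)))
    step = 0
    best_dice = -1.0
    best_state = None

    for epoch in range(1, cfg.epochs + 1):
        model.train()
        order = rng.permutation(len(train_items))
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            batch = [train_items[i] for i in order[lo:lo + cfg.batch_size]]
            images, masks = _to_batch(batch, cfg.network.in_channels)
            if cfg.schedule == "poly":
                opt.lr = cfg.lr * (1.0 - step / n_steps_total) ** 0.9
            try:
                loss = _compute_loss(model, images, masks, cfg.loss)
            except ValueError as exc:
                if "non-finite" in str(exc):
                    raise RuntimeError(
                        f"non-finite activations at epoch {epoch}, step {step}; "
                        "lower the learning rate or check the data") from exc
                raise
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss {value} at epoch {epoch}, step {step}; "
                    "lower the learning rate or check the data")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(value)
            step += 1
        val_dice, val_iou = _eval_mean_dice_iou(model, val_items)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses)),
               "val_dice": val_dice, "val_iou": val_iou}
        history.append(row)
        log_lines.append(
            f"epoch {epoch:4d}  loss {row['train_loss']:.4f}  "
            f"val_dice {val_dice:.4f}  val_iou {val_iou:.4f}")
        if val_dice > best_dice:
            best_dice = val_dice
            best_state = model.state_dict()
            if out_dir:
                save_checkpoint(model, out_dir / "best.npz")
        if cfg.stop_at_dice is not None and val_dice >= cfg.stop_at_dice:
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    hist = pd.DataFrame(history)
    if out_dir:
        hist.to_csv(out_dir / "history.csv", index=False)
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return model, hist


def evaluate(model_or_checkpoint, dataset, output_dir=None
             ) -> tuple[pd.DataFrame, dict]:
    """Per-image, per-class Dice/IoU/HD/HD95 plus means (CSV + JSON)."""
    if isinstance(model_or_checkpoint, (str, Path)):
        model = load_checkpoint(model_or_checkpoint)
    else:
        model = model_or_checkpoint
    if not isinstance(dataset, (list, tuple)):
        dataset = read_dataset(dataset)
    n_classes = max(model.cfg.n_classes, 2)
    rows = []
    for idx, (image, mask) in enumerate(dataset):
        if mask.max() >= n_classes:
            raise ValueError(
                f"mask {idx} holds label {mask.max()} but the model has "
                f"{n_classes} classes")
        pred = predict_mask(model, image)
        for cm in evaluate_masks(pred, mask, n_classes).per_class:
            rows.append({"image": idx, **vars(cm)})
    frame = pd.DataFrame(rows)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        summary = {
            "mean_dice": float(frame["dice"].mean()),
            "mean_iou": float(frame["iou"].mean()),
            "mean_hd": float(np.nanmean(frame["hd"].to_numpy())) if np.isfinite(frame["hd"]).any() else float("nan"),
            "mean_hd95": float(np.nanmean(frame["hd95"].to_numpy())) if np.isfinite(frame["hd95"]).any() else float("nan"),
            "n_images": int(frame["image"].nunique()),
            "n_undefined_hd": int((~np.isfinite(frame["hd"])).sum()),
            "n_empty_predictions": int(frame["pred_empty"].sum()),
        }
    if output_dir:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "metrics.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return frame, summary


def predict(checkpoint, image_path, out_path, resize: bool = False) -> np.ndarray:
    """Segment one image file and write the label mask as PNG."""
    model = load_checkpoint(checkpoint)
    try:
        pil = Image.open(image_path)
    except OSError as exc:
        raise OSError(f"cannot read image {image_path}: {exc}") from exc
    pil = pil.convert("L" if model.cfg.in_channels == 1 else "RGB")
    size = model.cfg.img_size
    if pil.size != (size, size):
        if not resize:
            raise ValueError(
                f"image is {pil.size}, model expects {size}x{size}; "
                "pass resize=True to auto-resize")
        pil = pil.resize((size, size), Image.BILINEAR)
    arr = np.asarray(pil, dtype=np.float32) / 255.0
    if arr.ndim == 3:
        arr = arr.transpose(2, 0, 1)
    mask = predict_mask(model, arr)
    Image.fromarray(mask.astype(np.uint8), mode="L").save(out_path)
    return mask
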