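"""Training and inference for the segmentation U-Net.

The protocol mirrors the segmentation study: Adam with initial learning rate
1e-3, Dice loss, learning rate multiplied by 0.1 when the validation loss has
not improved for 5 epochs, early stopping with patience 16, at most 200
epochs, and 5-fold cross-validation at the exam level — all frames of one
exam stay in the same fold, never split across training and validation.

``train`` runs the cross-validation and then retrains on all exams (the
returned model); ``fit`` is the single training run it is built from and can
be used directly with an explicit validation set. ``predict_mask`` runs
inference: sigmoid probabilities thresholded at 0.5 with largest-connected-
component postprocessing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import CineSequence, MaskSequence
from .nn import Adam, soft_dice_loss_and_grad
from .preprocess import AugmentParams, augment, center_crop_pad, minmax_normalize
from .unet import UNet, UNetConfig, build_unet

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "PlateauScheduler",
    "EarlyStopping",
    "exam_folds",
    "prepare_exam",
    "fit",
    "train",
    "predict_mask",
]

Exam = tuple[CineSequence, MaskSequence]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (defaults follow the segmentation protocol)."""

    initial_lr: float = 1e-3
    plateau_patience: int = 5
    lr_decay_factor: float = 0.1
    early_stop_patience: int = 16
    max_epochs: int = 200
    k_folds: int = 5
    loss: str = "dice"
    batch_size: int = 8
    seed: int = 0
    augment: bool = True
    augment_params: AugmentParams = field(default_factory=AugmentParams)

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not (0 < self.lr_decay_factor < 1):
            raise ValueError("lr_decay_factor must be in (0, 1)")
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be >= 1")
        if self.loss != "dice":
            raise ValueError(f"loss {self.loss!r} not available; Dice loss is implemented")


class PlateauScheduler:
    """Multiply the LR by ``factor`` when the monitored loss stalls ``patience`` epochs."""

    def __init__(self, initial_lr: float, factor: float, patience: int, min_delta: float = 1e-5):
        self.lr = initial_lr
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.stall = 0

    def step(self, loss: float) -> float:
        """Report this epoch's monitored loss; returns the LR to use next."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.stall = 0
        else:
            self.stall += 1
            if self.stall >= self.patience:
                self.lr *= self.factor
                self.stall = 0
        return self.lr


class EarlyStopping:
    """Stop after ``patience`` epochs without improvement; remembers the best epoch."""

    def __init__(self, patience: int, min_delta: float = 1e-5):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_epoch = -1
        self.stall = 0

    def step(self, loss: float, epoch: int) -> bool:
        """Returns True when training should stop."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.best_epoch = epoch
            self.stall = 0
            return False
        self.stall += 1
        return self.stall >= self.patience


def exam_folds(n_exams: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Shuffled exam-level fold assignment: list of k validation index arrays."""
    if n_exams < k:
        raise ValueError(f"need at least {k} exams for {k}-fold cross-validation")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_exams)
    return [np.sort(chunk) for chunk in np.array_split(order, k)]


def prepare_exam(seq: CineSequence, masks: MaskSequence, input_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess one exam into training tensors (normalize + center-crop-pad)."""
    x = np.stack([center_crop_pad(minmax_normalize(f), input_size) for f in seq.frames])
    y = np.stack([center_crop_pad(f.astype(np.float32), input_size) for f in masks.frames])
    return x.astype(np.float32), y.astype(np.float32)


@dataclass
class TrainedModel:
    """A (possibly untrained) U-Net plus its configs and per-fold history."""

    model: UNet
    config: UNetConfig
    train_config: TrainConfig | None = None
    fold_history: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> Path:
        """Checkpoint: weights as .npz, configs + history as a JSON sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **{f"p{i}": a for i, a in enumerate(self.model.state_arrays())})
        meta = {
            "unet_config": asdict(self.config),
            "train_config": asdict(self.train_config) if self.train_config else None,
            "fold_history": self.fold_history,
        }
        if meta["train_config"]:
            meta["train_config"]["augment_params"] = asdict(self.train_config.augment_params)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        config = UNetConfig(**meta["unet_config"])
        model = UNet(config)
        npz_path = path if path.suffix == ".npz" else Path(str(path) + ".npz")
        with np.load(npz_path) as data:
            model.load_state_arrays([data[f"p{i}"] for i in range(len(data.files))])
        tc = None
        if meta.get("train_config"):
            tc_dict = dict(meta["train_config"])
            ap = tc_dict.pop("augment_params", None)
            if ap is not None:
                ap["scale_range"] = tuple(ap["scale_range"])
                tc_dict["augment_params"] = AugmentParams(**ap)
            tc = TrainConfig(**tc_dict)
        return cls(model=model, config=config, train_config=tc, fold_history=meta.get("fold_history", {}))


def _forward_loss(model: UNet, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    losses = []
    for i in range(0, len(x), batch_size):
        probs = model.forward(x[i : i + batch_size, None])
        loss, _ = soft_dice_loss_and_grad(probs[:, 0], y[i : i + batch_size])
        losses.append(loss * min(batch_size, len(x) - i))
    return float(np.sum(losses) / len(x))


def fit(
    train_exams: list[Exam],
    val_exams: list[Exam] | None,
    unet_cfg: UNetConfig,
    cfg: TrainConfig,
    max_epochs: int | None = None,
    seed_offset: int = 0,
    log: list | None = None,
    fold: int = -1,
) -> tuple[UNet, pd.DataFrame]:
    """One training run; monitors validation loss (training loss if no val set).

    Returns the model restored to its best-monitored-epoch weights, plus a
    per-epoch history (epoch, lr, train_loss, val_loss).
    """
    input_size = unet_cfg.input_size
    xs, ys = [], []
    for seq, masks in train_exams:
        if not masks.frames.any():
            raise ValueError(f"exam {masks.exam_id!r} has empty masks throughout")
        x, y = prepare_exam(seq, masks, input_size)
        xs.append(x)
        ys.append(y)
    x_train = np.concatenate(xs)
    y_train = np.concatenate(ys)
    if val_exams:
        xv, yv = [], []
        for seq, masks in val_exams:
            x, y = prepare_exam(seq, masks, input_size)
            xv.append(x)
            yv.append(y)
        x_val, y_val = np.concatenate(xv), np.concatenate(yv)
    else:
        x_val = y_val = None

    seed = cfg.seed + seed_offset
    model = build_unet(unet_cfg, seed=seed)
    optimizer = Adam(model.params, lr=cfg.initial_lr)
    scheduler = PlateauScheduler(cfg.initial_lr, cfg.lr_decay_factor, cfg.plateau_patience)
    stopper = EarlyStopping(cfg.early_stop_patience)
    rng = np.random.default_rng(seed + 1)
    max_epochs = max_epochs or cfg.max_epochs

    best_state = [a.copy() for a in model.state_arrays()]
    history = []
    n = len(x_train)
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            if cfg.augment:
                xb = np.empty((len(idx), input_size, input_size), dtype=np.float32)
                yb = np.empty_like(xb)
                for j, k in enumerate(idx):
                    xb[j], yb[j] = augment(x_train[k], y_train[k], cfg.augment_params, rng)
            else:
                xb, yb = x_train[idx], y_train[idx]
            probs = model.forward(xb[:, None].astype(np.float32))
            loss, dprobs = soft_dice_loss_and_grad(probs[:, 0], yb)
            optimizer.zero_grad()
            model.backward(dprobs[:, None])
            optimizer.step()
            epoch_loss += loss * len(idx)
        train_loss = epoch_loss / n
        monitored = (
            _forward_loss(model, x_val, y_val, cfg.batch_size) if x_val is not None else train_loss
        )
        history.append(
            {
                "fold": fold,
                "epoch": epoch,
                "lr": optimizer.lr,
                "train_loss": train_loss,
                "val_loss": monitored if x_val is not None else np.nan,
            }
        )
        if log is not None:
            log.append(history[-1])
        improved = monitored < stopper.best - stopper.min_delta
        stop = stopper.step(monitored, epoch)
        if improved:
            best_state = [a.copy() for a in model.state_arrays()]
        optimizer.lr = scheduler.step(monitored)
        if stop:
            break
    model.load_state_arrays(best_state)
    return model, pd.DataFrame(history)


def train(
    exams: list[Exam],
    unet_cfg: UNetConfig,
    cfg: TrainConfig,
    cross_validate: bool = True,
    val_exams: list[Exam] | None = None,
) -> TrainedModel:
    """Train with exam-level K-fold cross-validation, then retrain on all exams.

    With ``cross_validate=False`` a single fit on all ``exams`` is run instead
    (validated on ``val_exams`` when given), which is the economical path when
    no fold-wise generalisation estimate is needed.
    """
    if cross_validate and len(exams) < cfg.k_folds:
        raise ValueError(f"need at least {cfg.k_folds} exams for {cfg.k_folds}-fold CV")
    fold_history: dict = {"folds": [], "history": []}
    log: list = []
    if cross_validate:
        folds = exam_folds(len(exams), cfg.k_folds, cfg.seed)
        for f, val_idx in enumerate(folds):
            val_set = [exams[i] for i in val_idx]
            train_set = [exams[i] for i in range(len(exams)) if i not in set(val_idx)]
            _, hist = fit(train_set, val_set, unet_cfg, cfg, seed_offset=f + 1, log=log, fold=f)
            fold_history["folds"].append(
                {
                    "fold": f,
                    "val_exams": [exams[i][0].exam_id for i in val_idx],
                    "train_exams": [
                        exams[i][0].exam_id for i in range(len(exams)) if i not in set(val_idx)
                    ],
                    "best_val_loss": float(hist["val_loss"].min()),
                    "n_epochs": int(len(hist)),
                }
            )
    model, hist = fit(exams, val_exams, unet_cfg, cfg, seed_offset=0, log=log, fold=-1)
    fold_history["history"] = log
    return TrainedModel(
        model=model, config=unet_cfg, train_config=cfg, fold_history=fold_history
    )


def predict_mask(
    trained: TrainedModel | UNet,
    sequence: CineSequence,
    threshold: float = 0.5,
    batch_size: int = 8,
) -> MaskSequence:
    """Segment every frame: sigmoid map, threshold, keep the largest component.

    Frames are preprocessed exactly as in training (min-max normalisation and
    center-crop-padding to the model's input size). An all-background
    prediction yields a valid empty mask frame.
    """
    model = trained.model if isinstance(trained, TrainedModel) else trained
    input_size = model.config.input_size
    x = np.stack(
        [center_crop_pad(minmax_normalize(f), input_size) for f in sequence.frames]
    ).astype(np.float32)
    out = np.empty((len(x), input_size, input_size), dtype=np.uint8)
    for i in range(0, len(x), batch_size):
        probs = model.forward(x[i : i + batch_size, None])[:, 0]
        for j, p in enumerate(probs):
            binary = p > threshold
            if binary.any():
                labels, n_comp = ndimage.label(binary)
                if n_comp > 1:
                    sizes = ndimage.sum_labels(binary, labels, index=range(1, n_comp + 1))
                    binary = labels == (1 + int(np.argmax(sizes)))
            out[i + j] = binary.astype(np.uint8)
    return MaskSequence(frames=out, pixel_spacing=sequence.pixel_spacing, exam_id=sequence.exam_id)
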