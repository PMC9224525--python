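"""Multi-resolution training (MTM) and SGD plumbing.

The multi-resolution schedule trains coarse-to-fine: half the epochs at a
low resolution cap (667x400), then the standard cap (1333x800), with the
last quarter fine-tuned at a tenfold-reduced learning rate.  Because the
low-resolution phase processes roughly a quarter of the pixels per image,
the schedule touches ~62.5% of the pixels of an equal-length constant
high-resolution run — the hardware-independent core of its training-time
saving.

Mini-batches are a single image; prediction layers are initialized from
N(0, 0.01^2) with a low-prior classification bias.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .detector import Detector
from .head import FCOSHead
from .metrics import MetricsReport, summarize
from .voc import DatasetIndex, ImageRecord, resize_with_boxes

__all__ = ["SchedulePhase", "TrainConfig", "build_mtm_schedule",
           "init_weights", "train_epoch", "fit", "evaluate_detector",
           "schedule_pixel_fraction"]

LOW_RES = (667, 400)
HIGH_RES = (1333, 800)
BASE_LR = 0.0025


@dataclass(frozen=True)
class SchedulePhase:
    first_epoch: int            # 1-based, inclusive
    last_epoch: int
    resolution: tuple[int, int]  # (max_long, max_short) keep-ratio caps
    lr: float

    @property
    def epochs(self) -> int:
        return self.last_epoch - self.first_epoch + 1


def build_mtm_schedule(total_epochs: int = 16, base_lr: float = BASE_LR,
                       low_res: tuple[int, int] = LOW_RES,
                       high_res: tuple[int, int] = HIGH_RES,
                       enabled: bool = True) -> list[SchedulePhase]:
    """Coarse-to-fine phase list partitioning [1, total_epochs].

    With the schedule enabled the epochs split proportionally to the 8/4/4
    pattern (half low-resolution, then high-resolution, then high-resolution
    at 0.1x learning rate).  Disabled, a single-resolution schedule with the
    learning-rate drop at 3/4 of training is returned.
    """
    if total_epochs < 4:
        raise ValueError("need at least 4 epochs")
    if total_epochs % 4:
        raise ValueError("total_epochs must divide into the 8/4/4 pattern "
                         "(multiple of 4)")
    if enabled:
        n1 = total_epochs // 2
        n2 = total_epochs // 4
        return [
            SchedulePhase(1, n1, low_res, base_lr),
            SchedulePhase(n1 + 1, n1 + n2, high_res, base_lr),
            SchedulePhase(n1 + n2 + 1, total_epochs, high_res, base_lr * 0.1),
        ]
    drop = (3 * total_epochs) // 4
    return [
        SchedulePhase(1, drop, high_res, base_lr),
        SchedulePhase(drop + 1, total_epochs, high_res, base_lr * 0.1),
    ]


def schedule_pixel_fraction(schedule: list[SchedulePhase]) -> float:
    """Pixel budget of the schedule relative to all-epochs-at-final-resolution.

    Deterministic arithmetic over the resolution caps; independent of
    hardware, and the quantity behind the training-time saving.
    """
    final = schedule[-1].resolution
    final_pixels = final[0] * final[1]
    total = sum(p.epochs * p.resolution[0] * p.resolution[1] for p in schedule)
    n_epochs = sum(p.epochs for p in schedule)
    return total / (n_epochs * final_pixels)


@dataclass
class TrainConfig:
    total_epochs: int = 16
    base_lr: float = BASE_LR
    momentum: float = 0.9
    weight_decay: float = 1e-4
    init_std: float = 0.01
    warmup_steps: int = 100
    hflip: bool = True
    mtm: bool = True
    low_res: tuple[int, int] = LOW_RES
    high_res: tuple[int, int] = HIGH_RES
    seed: int = 0
    phases: list[SchedulePhase] | None = None   # explicit override

    def __post_init__(self):
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.init_std <= 0:
            raise ValueError("init_std must be positive")

    def schedule(self) -> list[SchedulePhase]:
        if self.phases is not None:
            return self.phases
        return build_mtm_schedule(self.total_epochs, self.base_lr,
                                  self.low_res, self.high_res,
                                  enabled=self.mtm)


def init_weights(model: Detector, init_std: float = 0.01, seed: int = 0,
                 prior: float = 0.01):
    """Gaussian initialization of the prediction layers.

    Classification/regression/centerness prediction convolutions get
    N(0, init_std^2) weights; the classification bias is set so the initial
    positive probability is ``prior`` (keeps the focal loss from being
    swamped by the negatives early on).
    """
    rng = np.random.default_rng(seed)
    head: FCOSHead = model.head
    for layer in head.prediction_layers():
        layer.weight.data[...] = rng.normal(
            0.0, init_std, size=layer.weight.shape).astype(np.float32)
        if layer.bias is not None:
            layer.bias.data[...] = 0.0
    head.cls_pred.bias.data[...] = -math.log((1.0 - prior) / prior)


def _prepare(record: ImageRecord, resolution, class_names, rng,
             hflip: bool):
    rec = resize_with_boxes(record, resolution[0], resolution[1])
    img = rec.image
    boxes = rec.boxes()
    if hflip and rng.random() < 0.5:
        img = img[:, ::-1].copy()
        w = rec.width
        boxes = boxes.copy()
        boxes[:, [0, 2]] = w - boxes[:, [2, 0]]
    labels = np.array([class_names.index(a.label) for a in rec.annotations],
                      dtype=int)
    return img, boxes, labels


def train_epoch(model: Detector, index: DatasetIndex, phase: SchedulePhase,
                optimizer: nn.SGD, rng: np.random.Generator,
                hflip: bool = True, warmup=None) -> dict:
    """One pass over the data at the phase's resolution; returns mean losses.

    ``warmup`` is an optional (step_counter, total_warmup_steps, base_lr)
    list mutated in place for linear warm-up across epochs.
    """
    model.train()
    sums = {"Lcls": 0.0, "Lreg": 0.0, "Lcenter": 0.0, "Ltotal": 0.0}
    order = rng.permutation(len(index.records))
    for i in order:
        img, boxes, labels = _prepare(index.records[i], phase.resolution,
                                      index.class_names, rng, hflip)
        if warmup is not None and warmup[0] < warmup[1]:
            optimizer.lr = phase.lr * (0.33 + 0.67 * (warmup[0] + 1) / warmup[1])
            warmup[0] += 1
        else:
            optimizer.lr = phase.lr
        bundle, _ = model.loss_for(img, boxes, labels)
        values = bundle.as_floats()
        if not all(np.isfinite(v) for v in values.values()):
            raise RuntimeError(f"non-finite loss encountered: {values}")
        optimizer.zero_grad()
        bundle.total.backward()
        optimizer.step()
        for k in sums:
            sums[k] += values[k]
    n = max(len(order), 1)
    return {k: v / n for k, v in sums.items()}


def evaluate_detector(model: Detector, index: DatasetIndex,
                      resolution: tuple[int, int] | None = None
                      ) -> MetricsReport:
    """Run inference over a dataset and summarize detection metrics."""
    detections, truths = [], []
    for record in index.records:
        rec = (resize_with_boxes(record, *resolution)
               if resolution is not None else record)
        detections.append(model.predict(rec.image))
        labels = np.array([index.class_names.index(a.label)
                           for a in rec.annotations], dtype=int)
        truths.append((rec.boxes(), labels))
    return summarize(detections, truths, num_classes=len(index.class_names))


def fit(model: Detector, index: DatasetIndex, config: TrainConfig,
        val_index: DatasetIndex | None = None,
        out_dir: str | Path | None = None,
        max_steps: int | None = None) -> list[dict]:
    """Execute the phase schedule; returns the per-epoch training log.

    With ``val_index`` the log also records AP50 at the final-phase
    resolution after every epoch (the per-epoch performance curve).
    ``max_steps`` truncates training (counted in single-image steps) for
    smoke-scale runs.
    """
    schedule = config.schedule()
    rng = np.random.default_rng(config.seed)
    init_weights(model, config.init_std, seed=config.seed)
    optimizer = nn.SGD(model.parameters(), lr=schedule[0].lr,
                       momentum=config.momentum,
                       weight_decay=config.weight_decay)
    warmup = [0, config.warmup_steps, schedule[0].lr]
    log: list[dict] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    steps_done = 0
    for phase in schedule:
        for epoch in range(phase.first_epoch, phase.last_epoch + 1):
            if max_steps is not None and steps_done >= max_steps:
                break
            epoch_log = train_epoch(model, index, phase, optimizer, rng,
                                    hflip=config.hflip, warmup=warmup)
            steps_done += len(index.records)
            entry = {"epoch": epoch, "resolution": list(phase.resolution),
                     "lr": phase.lr, **epoch_log}
            if val_index is not None:
                report = evaluate_detector(model, val_index,
                                           resolution=None)
                entry["val_AP50"] = report.AP50
            log.append(entry)
            if out_path is not None:
                np.savez(out_path / f"epoch_{epoch:03d}.npz",
                         **model.state_dict())
                with open(out_path / "train_log.jsonl", "a") as fh:
                    fh.write(json.dumps(entry) + "\n")
    return log
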