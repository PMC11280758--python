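"""Training loop, augmentation, evaluation and five-fold cross-validation.

The optimizer protocol: Adam with learning rate 0.01, first-moment
coefficient 0.9, weight decay 1e-4 and batch size 6; inputs are 224 x 224.
The three loss-mixing weights are ordinary parameters of the optimizer, so
they are updated alongside the network.  Training folds are augmented with
random rotation (default up to +/-25 degrees) and horizontal flips;
validation images are never augmented and never seen by the optimizer.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .losses import LossConfig, LossWeights, combined_loss
from .metrics import (
    ConfusionCounts,
    FoldSplit,
    MetricReport,
    confusion,
    fold_summary,
    kfold_split,
    per_image_mean_report,
    pooled_report,
)
from .model import CoatSegNet, ModelConfig, normalize_image
from .nn import Adam, BatchNorm1d, BatchNorm2d
from .nn.autodiff import Tensor
from .synthetic import LabeledImage


@dataclass
class OptimConfig:
    algorithm: str = "adam"
    lr: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-4
    batch_size: int = 6

    def validate(self) -> None:
        if self.algorithm != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.lr <= 0 or self.batch_size < 1:
            raise ValueError("lr must be > 0 and batch_size >= 1")


@dataclass
class AugmentConfig:
    enabled: bool = True
    rotation_deg: float = 25.0
    hflip: bool = True


def augment_sample(
    sample: LabeledImage, cfg: AugmentConfig, rng: np.random.Generator
) -> LabeledImage:
    """Random rotation and horizontal flip; the mask stays hard binary."""
    image, mask = sample.image, sample.mask
    if cfg.hflip and rng.random() < 0.5:
        image = image[:, ::-1]
        mask = mask[:, ::-1]
    if cfg.rotation_deg > 0:
        angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
        image = ndimage.rotate(image, angle, axes=(1, 0), reshape=False,
                               order=1, mode="nearest")
        mask = ndimage.rotate(mask, angle, axes=(1, 0), reshape=False,
                              order=0, mode="constant")
    return LabeledImage(
        image=np.ascontiguousarray(image),
        mask=np.ascontiguousarray(mask).astype(np.uint8),
        id=sample.id,
    )


def recalibrate_batchnorm(
    net: CoatSegNet, samples: Sequence[LabeledImage], batch_size: int = 8,
    passes: int = 2,
) -> None:
    """Re-estimate batch-norm running statistics from the training data.

    During optimization the exponential running statistics lag behind the
    fast-moving weights, so evaluation-mode normalization can differ
    noticeably from the statistics training actually used.  This resets the
    running moments and replaces them with the exact average of the batch
    statistics over ``passes`` sweeps (momentum 1/k on the k-th forward
    call), after which evaluation-mode behaviour matches training closely.
    """
    bns = [m for m in net.modules() if isinstance(m, (BatchNorm1d, BatchNorm2d))]
    saved = [(m.momentum) for m in bns]
    for m in bns:
        m.running_mean = np.zeros_like(m.running_mean)
        m.running_var = np.ones_like(m.running_var)
    net.train()
    call = 0
    try:
        for _ in range(passes):
            for start in range(0, len(samples), batch_size):
                call += 1
                for m in bns:
                    m.momentum = 1.0 / call
                images, _ = _to_batch(samples[start:start + batch_size])
                net.forward_tensor(Tensor(images))
    finally:
        for m, mom in zip(bns, saved):
            m.momentum = mom


def _to_batch(samples: Sequence[LabeledImage]) -> Tuple[np.ndarray, np.ndarray]:
    images = np.stack([normalize_image(s.image) for s in samples])
    masks = np.stack([s.mask.astype(np.int64) for s in samples])
    return images, masks


class Trainer:
    """Optimizes a segmentation network and the loss-mixing weights."""

    def __init__(
        self,
        net: CoatSegNet,
        loss_cfg: Optional[LossConfig] = None,
        optim_cfg: Optional[OptimConfig] = None,
        seed: int = 0,
    ):
        self.net = net
        self.loss_cfg = loss_cfg or LossConfig()
        self.optim_cfg = optim_cfg or OptimConfig()
        self.optim_cfg.validate()
        self.loss_cfg.validate()
        self.loss_weights = LossWeights()
        self.opt = Adam(
            self.net.parameters() + self.loss_weights.parameters(),
            lr=self.optim_cfg.lr,
            beta1=self.optim_cfg.beta1,
            beta2=self.optim_cfg.beta2,
            weight_decay=self.optim_cfg.weight_decay,
        )
        self.rng = np.random.default_rng(seed)
        self.step_idx = 0
        self.log: List[Dict[str, float]] = []

    def step(self, images: np.ndarray, masks: np.ndarray) -> Dict[str, float]:
        """One optimization step on a prepared batch; returns the log row."""
        self.net.train()
        logits = self.net.forward_tensor(Tensor(images))
        total, parts = combined_loss(
            logits, masks, self.loss_weights, self.loss_cfg, return_parts=True
        )
        self.opt.zero_grad()
        total.backward()
        self.opt.step()
        self.step_idx += 1
        w1, w2, w3 = self.loss_weights.values()
        row = {
            "step": self.step_idx,
            "loss": float(total.data),
            "ce": float(parts["ce"].data),
            "dice": float(parts["dice"].data),
            "focal": float(parts["focal"].data),
            "w1": w1, "w2": w2, "w3": w3,
        }
        self.log.append(row)
        return row

    def fit(
        self,
        samples: Sequence[LabeledImage],
        steps: int,
        augment: Optional[AugmentConfig] = None,
        batch_size: Optional[int] = None,
        recalibrate: bool = True,
    ) -> List[Dict[str, float]]:
        """Train for ``steps`` batches drawn with replacement-free shuffling.

        Finishes with a batch-norm statistics re-estimation pass (see
        :func:`recalibrate_batchnorm`) unless ``recalibrate`` is False.
        """
        augment = augment if augment is not None else AugmentConfig(enabled=False)
        bs = batch_size or self.optim_cfg.batch_size
        order: List[int] = []
        for _ in range(steps):
            while len(order) < bs:
                order.extend(self.rng.permutation(len(samples)).tolist())
            idx, order = order[:bs], order[bs:]
            batch = [samples[i] for i in idx]
            if augment.enabled:
                batch = [augment_sample(s, augment, self.rng) for s in batch]
            images, masks = _to_batch(batch)
            self.step(images, masks)
        if recalibrate:
            recalibrate_batchnorm(self.net, list(samples), batch_size=bs)
        return self.log

    def write_log(self, path: Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["step", "loss", "ce", "dice", "focal",
                                "w1", "w2", "w3"]
            )
            writer.writeheader()
            writer.writerows(self.log)


# ------------------------------------------------------------- checkpoints
def save_checkpoint(path: Path, trainer: Trainer) -> None:
    state = {}
    for k, v in trainer.net.state_dict().items():
        state[f"net::{k}"] = v
    for k, v in trainer.loss_weights.state_dict().items():
        state[f"loss::{k}"] = v
    opt = trainer.opt.state_dict()
    state["opt::t"] = np.array(opt["t"])
    for i, m in enumerate(opt["m"]):
        state[f"opt::m{i}"] = m
    for i, v in enumerate(opt["v"]):
        state[f"opt::v{i}"] = v
    state["meta::step"] = np.array(trainer.step_idx)
    np.savez(path, **state)


def load_checkpoint(path: Path, trainer: Trainer) -> None:
    data = np.load(path)
    trainer.net.load_state_dict(
        {k[5:]: data[k] for k in data.files if k.startswith("net::")}
    )
    trainer.loss_weights.load_state_dict(
        {k[6:]: data[k] for k in data.files if k.startswith("loss::")}
    )
    n = len(trainer.opt.params)
    trainer.opt.load_state_dict({
        "t": int(data["opt::t"]),
        "m": [data[f"opt::m{i}"] for i in range(n)],
        "v": [data[f"opt::v{i}"] for i in range(n)],
    })
    trainer.step_idx = int(data["meta::step"])


def load_network(path: Path, cfg: ModelConfig) -> CoatSegNet:
    net = CoatSegNet(cfg)
    data = np.load(path)
    net.load_state_dict(
        {k[5:]: data[k] for k in data.files if k.startswith("net::")}
    )
    return net


# -------------------------------------------------------------- evaluation
def evaluate(
    net: CoatSegNet,
    samples: Sequence[LabeledImage],
    aggregation: str = "pooled",
) -> MetricReport:
    """Metrics of the network's predictions; pooled (micro) by default."""
    counts: List[ConfusionCounts] = []
    for s in samples:
        out = net.predict(normalize_image(s.image))
        counts.append(confusion(out.mask, s.mask))
    if aggregation == "pooled":
        return pooled_report(counts)
    if aggregation == "per-image-mean":
        return per_image_mean_report(counts)
    raise ValueError(f"unknown aggregation {aggregation!r}")


def training_dice(net: CoatSegNet, samples: Sequence[LabeledImage]) -> float:
    return evaluate(net, samples).dice


@dataclass
class CrossValResult:
    split: FoldSplit
    fold_reports: List[MetricReport]
    mean: Dict[str, float]
    std: Dict[str, float]


def crossvalidate(
    samples: Sequence[LabeledImage],
    model_cfg: ModelConfig,
    k: int = 5,
    seed: int = 0,
    steps: int = 100,
    loss_cfg: Optional[LossConfig] = None,
    optim_cfg: Optional[OptimConfig] = None,
    augment: Optional[AugmentConfig] = None,
    aggregation: str = "pooled",
) -> CrossValResult:
    """k-fold cross-validation: train on k-1 folds, score the held-out one.

    Standard deviations across folds use the population convention
    (divide by k).  Augmentation touches training folds only.
    """
    by_id = {s.id: s for s in samples}
    if len(by_id) != len(samples):
        raise ValueError("duplicate sample ids")
    split = kfold_split([s.id for s in samples], k=k, seed=seed)
    augment = augment if augment is not None else AugmentConfig()
    reports: List[MetricReport] = []
    for fold in range(k):
        train_samples = [by_id[i] for i in split.train_ids(fold)]
        val_samples = [by_id[i] for i in split.fold_ids(fold)]
        net = CoatSegNet(model_cfg)
        trainer = Trainer(net, loss_cfg, optim_cfg, seed=seed * 1000 + fold)
        trainer.fit(train_samples, steps=steps, augment=augment)
        reports.append(evaluate(net, val_samples, aggregation=aggregation))
    summary = fold_summary(reports)
    return CrossValResult(
        split=split,
        fold_reports=reports,
        mean=summary["mean"],
        std=summary["std"],
    )
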