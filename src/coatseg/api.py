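"""Model/Results interface for tongue-coating segmentation experiments.

:class:`TongueCoatingSegmentation` bundles a dataset with a model
configuration; :meth:`fit` trains the network and returns a
:class:`TongueCoatingResults` carrying the fitted weights, the loss and
loss-weight trajectories, training-set metrics and prediction /
explanation methods, with a printable :meth:`~TongueCoatingResults.summary`.

    >>> ds = [generate_sample(spec, i) for i in range(8)]
    >>> model = TongueCoatingSegmentation(ds, ModelConfig.tiny(64))
    >>> res = model.fit(steps=200)
    >>> print(res.summary())
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .gradcam import gradcam
from .losses import LossConfig
from .metrics import MetricReport
from .model import CoatSegNet, ModelConfig, SegmentationOutput, normalize_image
from .synthetic import LabeledImage
from .train import (
    AugmentConfig,
    CrossValResult,
    OptimConfig,
    Trainer,
    crossvalidate,
    evaluate,
    load_checkpoint,
    save_checkpoint,
)


class TongueCoatingSegmentation:
    """A segmentation experiment: data plus configuration, ready to fit."""

    def __init__(
        self,
        data: Sequence[LabeledImage],
        config: Optional[ModelConfig] = None,
        loss: Optional[LossConfig] = None,
        optim: Optional[OptimConfig] = None,
        augment: Optional[AugmentConfig] = None,
        seed: int = 0,
    ):
        if len(data) == 0:
            raise ValueError("dataset is empty")
        self.data = list(data)
        self.config = config or ModelConfig()
        self.loss = loss or LossConfig()
        self.optim = optim or OptimConfig()
        self.augment = augment if augment is not None else AugmentConfig(enabled=False)
        self.seed = seed

    @classmethod
    def from_manifest(cls, manifest_path: Path, **kwargs
                      ) -> "TongueCoatingSegmentation":
        from .synthetic import load_dataset

        return cls(load_dataset(manifest_path), **kwargs)

    def fit(self, steps: int = 200,
            batch_size: Optional[int] = None) -> "TongueCoatingResults":
        net = CoatSegNet(self.config)
        trainer = Trainer(net, self.loss, self.optim, seed=self.seed)
        trainer.fit(self.data, steps=steps, augment=self.augment,
                    batch_size=batch_size)
        return TongueCoatingResults(self, trainer)

    def crossvalidate(self, k: int = 5, steps: int = 100) -> CrossValResult:
        return crossvalidate(
            self.data, self.config, k=k, seed=self.seed, steps=steps,
            loss_cfg=self.loss, optim_cfg=self.optim, augment=self.augment,
        )


class TongueCoatingResults:
    """Fitted weights, training history and evaluation utilities."""

    def __init__(self, model: TongueCoatingSegmentation, trainer: Trainer):
        self.model = model
        self.trainer = trainer
        self.net = trainer.net
        self.history: List[Dict[str, float]] = trainer.log

    # ------------------------------------------------------------- queries
    @property
    def loss_weights(self) -> tuple:
        return self.trainer.loss_weights.values()

    def predict(self, image: np.ndarray) -> SegmentationOutput:
        """Segment one RGB uint8 image of the configured input size."""
        return self.net.predict(normalize_image(image))

    def explain(self, image: np.ndarray) -> np.ndarray:
        """GradCAM heat map for one RGB uint8 image."""
        return gradcam(self.net, normalize_image(image))

    def evaluate(self, data: Optional[Sequence[LabeledImage]] = None,
                 aggregation: str = "pooled") -> MetricReport:
        return evaluate(self.net, data if data is not None else self.model.data,
                        aggregation=aggregation)

    def save(self, path: Path) -> None:
        save_checkpoint(path, self.trainer)

    def load(self, path: Path) -> None:
        load_checkpoint(path, self.trainer)

    # ------------------------------------------------------------- summary
    def summary(self) -> str:
        cfg = self.model.config
        report = self.evaluate()
        last = self.history[-1] if self.history else {}
        w1, w2, w3 = self.loss_weights
        lines = [
            "Tongue-Coating Segmentation Results",
            "=" * 51,
            f"{'Encoder levels:':<28}{cfg.backbone.n_levels}",
            f"{'Input size:':<28}{cfg.backbone.input_size}",
            f"{'Transformer grid:':<28}"
            f"{cfg.backbone.grid_size} x {cfg.backbone.grid_size}",
            f"{'SFP:':<28}"
            f"{cfg.sfp_mode if cfg.sfp_enabled else 'disabled'}",
            f"{'VRE:':<28}"
            f"{cfg.vre_arrangement if cfg.vre_enabled else 'disabled'}",
            f"{'Parameters:':<28}{self.net.n_parameters():,}",
            f"{'Optimization steps:':<28}{self.trainer.step_idx}",
            "-" * 51,
            f"{'Final total loss:':<28}{last.get('loss', float('nan')):.4f}",
            f"{'Loss weights (w1,w2,w3):':<28}"
            f"({w1:.3f}, {w2:.3f}, {w3:.3f})",
            "-" * 51,
            "Training-set metrics (pooled over pixels):",
            f"{'  accuracy':<28}{report.accuracy:.4f}",
            f"{'  precision':<28}{report.precision:.4f}",
            f"{'  dice':<28}{report.dice:.4f}",
            f"{'  recall':<28}{report.recall:.4f}",
            f"{'  iou':<28}{report.iou:.4f}",
            "=" * 51,
        ]
        return "\n".join(lines)
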