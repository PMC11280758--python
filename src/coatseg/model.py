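"""Full segmentation network: hybrid encoder + SFP + VRE + U-shaped decoder.

The decoder starts from the transformer output, upsamples stage by stage
(transposed convolution by default, bilinear optionally), and at each stage
concatenates the matching skip feature before two CBR blocks.  Skip features
reach the decoder at fixed widths (the raw encoder widths 64/256/512
shallow -> deep): the baseline routes them unchanged, the SFP variant
reduces them to 64 channels, runs the difference pyramid and restores the
width with a 1x1 projection, and the VRE variant replaces that bare
projection with the codebook enhancer (whose own 1x1 projection restores
the width).  Keeping the decoder geometry identical across ablations makes
the variants comparable and means each addition strictly adds parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .backbone import BackboneConfig, ConfigurationError, HybridEncoder
from .sfp import SFP
from .vre import ARRANGEMENTS, VRE


@dataclass
class ModelConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    sfp_enabled: bool = True
    vre_enabled: bool = True
    sfp_mode: str = "subtract"
    vre_arrangement: str = "series"
    vre_codewords: int = 64
    n_classes: int = 2
    decoder_channels: Tuple[int, ...] = (256, 128, 64)
    head_channels: int = 16
    upsample: str = "deconv"  # or "bilinear"
    seed: int = 0

    def validate(self) -> None:
        self.backbone.validate()
        if self.n_classes != 2:
            raise ConfigurationError("n_classes must be 2 (coating vs background)")
        if self.vre_enabled and not self.sfp_enabled:
            raise ConfigurationError("vre_enabled requires sfp_enabled")
        if self.sfp_mode not in ("subtract", "add"):
            raise ConfigurationError(f"unknown sfp_mode {self.sfp_mode!r}")
        if self.vre_arrangement not in ARRANGEMENTS:
            raise ConfigurationError(
                f"unknown vre_arrangement {self.vre_arrangement!r}"
            )
        if self.upsample not in ("deconv", "bilinear"):
            raise ConfigurationError(f"unknown upsample {self.upsample!r}")
        if len(self.decoder_channels) != 3:
            raise ConfigurationError("decoder_channels must have three stages")

    @classmethod
    def tiny(cls, input_size: int = 64, n_levels: int = 4, seed: int = 0,
             **kwargs) -> "ModelConfig":
        return cls(
            backbone=BackboneConfig.tiny(input_size, n_levels, seed=seed),
            decoder_channels=(32, 16, 8),
            head_channels=8,
            vre_codewords=8,
            seed=seed,
            **kwargs,
        )


@dataclass
class SegmentationOutput:
    """Per-pixel logits, class probabilities and the argmax label mask."""

    logits: np.ndarray  # (2, H, W)
    prob: np.ndarray    # (2, H, W), sums to 1 over classes
    mask: np.ndarray    # (H, W) in {0, 1}; ties resolve to background


class DecoderStage(nn.Module):
    """Upsample 2x, concatenate the skip (if any), then two CBR blocks."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int, upsample: str,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.mode = upsample
        if upsample == "deconv":
            self.up = nn.ConvTranspose2d(in_ch, in_ch, 2, stride=2, rng=rng)
        else:
            self.up = None
        self.cbr1 = nn.CBR(in_ch + skip_ch, out_ch, rng=rng)
        self.cbr2 = nn.CBR(out_ch, out_ch, rng=rng)

    def forward(self, x: Tensor, skip: Optional[Tensor]) -> Tensor:
        if self.up is not None:
            x = self.up(x)
        else:
            x = ad.upsample_bilinear(x, 2 * x.shape[2], 2 * x.shape[3])
        if skip is not None:
            if skip.shape[2:] != x.shape[2:]:
                x = ad.upsample_bilinear(x, skip.shape[2], skip.shape[3])
            x = ad.concat([x, skip], axis=1)
        return self.cbr2(self.cbr1(x))


class CoatSegNet(nn.Module):
    """The assembled tongue-coating segmentation network."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        bb = cfg.backbone
        self.encoder = HybridEncoder(bb, rng=rng)
        skip_ch = list(bb.skip_channels)  # shallow -> deep (strides 2, 4, 8)

        if cfg.sfp_enabled:
            self.sfp = SFP(skip_ch, reduced=64, mode=cfg.sfp_mode, rng=rng)
            if cfg.vre_enabled:
                self.vre = [
                    VRE(64, skip_ch[l], k=cfg.vre_codewords,
                        arrangement=cfg.vre_arrangement, rng=rng)
                    for l in range(3)
                ]
                self.skip_proj = None
            else:
                self.vre = None
                self.skip_proj = [
                    nn.Conv2d(64, skip_ch[l], 1, rng=rng) for l in range(3)
                ]
        else:
            self.sfp = None
            self.vre = None
            self.skip_proj = None

        dch = cfg.decoder_channels
        hidden = bb.transformer_hidden
        self.bridge = nn.CBR(hidden, dch[0] * 2, rng=rng)
        cur = dch[0] * 2
        if bb.n_levels == 5:
            # extra skip-free stage: stride 32 -> 16
            self.stage_pre = DecoderStage(cur, 0, cur, cfg.upsample, rng=rng)
        else:
            self.stage_pre = None
        # three skip stages: stride 16 -> 8 -> 4 -> 2 (skips deep -> shallow)
        self.stages = []
        for i, out_ch in enumerate(dch):
            s_ch = skip_ch[2 - i]
            self.stages.append(DecoderStage(cur, s_ch, out_ch, cfg.upsample, rng=rng))
            cur = out_ch
        # final 2x to full resolution, then the classification head
        self.stage_final = DecoderStage(cur, 0, cfg.head_channels, cfg.upsample,
                                        rng=rng)
        self.head = nn.Conv2d(cfg.head_channels, cfg.n_classes, 1, rng=rng)
        # activation of the last convolutional block, kept for GradCAM
        self._cam_activation: Optional[Tensor] = None

    # --------------------------------------------------------------- forward
    def forward_tensor(self, x: Tensor) -> Tensor:
        """Logits (N, 2, H, W) from a normalized image batch (N, 3, H, W)."""
        skips, deep = self.encoder(x)
        if self.sfp is not None:
            skips = self.sfp(skips)
            if self.vre is not None:
                skips = [self.vre[l](s) for l, s in enumerate(skips)]
            else:
                skips = [self.skip_proj[l](s) for l, s in enumerate(skips)]
        d = self.bridge(deep)
        if self.stage_pre is not None:
            d = self.stage_pre(d, None)
        for i, stage in enumerate(self.stages):
            d = stage(d, skips[2 - i])
        d = self.stage_final(d, None)
        self._cam_activation = d
        return self.head(d)

    def predict(self, image: np.ndarray) -> SegmentationOutput:
        """Inference on one normalized image (3, H, W) in evaluation mode."""
        was_training = self.training
        self.eval()
        try:
            logits = self.forward_tensor(Tensor(image[None].astype(np.float32)))
        finally:
            self.train(was_training)
        lg = logits.data[0]
        e = np.exp(lg - lg.max(axis=0, keepdims=True))
        prob = e / e.sum(axis=0, keepdims=True)
        # argmax with ties resolving to background (class 0 wins ties)
        mask = (prob[1] > prob[0]).astype(np.uint8)
        return SegmentationOutput(logits=lg, prob=prob, mask=mask)

    def n_parameters(self) -> int:
        return super().n_parameters()


def normalize_image(image: np.ndarray) -> np.ndarray:
    """uint8 H x W x 3 -> float32 (3, H, W), scaled to roughly [-1, 1]."""
    x = image.astype(np.float32) / 255.0
    x = (x - 0.5) / 0.5
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def ablation_grid(
    base: Optional[ModelConfig] = None,
    modules: Sequence[str] = ("baseline", "sfp", "sfp+vre"),
    sfp_modes: Sequence[str] = ("subtract",),
    vre_arrangements: Sequence[str] = ("series",),
    n_levels: Sequence[int] = (4,),
) -> List[Tuple[str, ModelConfig]]:
    """Enumerate ablation configurations as (name, config) pairs.

    The default emits exactly the baseline / +SFP / +SFP+VRE trio; widening
    the other axes reproduces the subtract-vs-add, series/parallel/single
    and 4-vs-5-level comparisons.  The grid size is the product of the axis
    cardinalities and every emitted config validates.
    """
    base = base or ModelConfig()
    out: List[Tuple[str, ModelConfig]] = []
    for mod, mode, arr, nl in product(modules, sfp_modes, vre_arrangements,
                                      n_levels):
        cfg = replace(
            base,
            backbone=replace(base.backbone, n_levels=nl),
            sfp_enabled=mod in ("sfp", "sfp+vre"),
            vre_enabled=mod == "sfp+vre",
            sfp_mode=mode,
            vre_arrangement=arr,
        )
        cfg.validate()
        name = f"{mod}|{mode}|{arr}|{nl}lvl"
        out.append((name, cfg))
    return out
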