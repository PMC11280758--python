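"""Hybrid convolution/transformer encoder.

A residual (bottleneck) convolutional stem extracts a feature pyramid at
strides 2/4/8/16 (optionally 32 with a fifth level); the three shallowest
maps become the skip connections, and the deepest map is flattened to a
token sequence, given learned position embeddings, and processed by a stack
of pre-norm self-attention blocks to model long-range dependencies between
regions of the tongue surface.  With a 224 px input the transformer grid is
14 x 14 in the 4-level configuration and 7 x 7 in the 5-level one.

Weights can be loaded from a local checkpoint (``pretrained_path``); random
initialisation is the default and is what every test uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import nn
from .nn import autodiff as ad
from .nn.autodiff import Tensor


class ConfigurationError(ValueError):
    pass


@dataclass
class BackboneConfig:
    """Geometry of the encoder.

    ``stage_widths`` are bottleneck base widths; stage outputs carry
    ``4 * width`` channels.  The defaults reproduce the ResNet-50 / ViT-Base
    hybrid; :meth:`tiny` gives a CPU-friendly variant with the same strides.
    """

    n_levels: int = 4
    input_size: int = 224
    stem_channels: int = 64
    stage_widths: Tuple[int, ...] = (64, 128, 256, 512)
    blocks_per_stage: Tuple[int, ...] = (3, 4, 6, 3)
    transformer_depth: int = 12
    transformer_heads: int = 12
    transformer_hidden: int = 768
    transformer_mlp_ratio: float = 4.0
    pretrained: bool = False
    pretrained_path: Optional[str] = None
    interpolate_pos_embed: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_levels not in (4, 5):
            raise ConfigurationError("n_levels must be 4 or 5")
        if self.input_size % 32 != 0:
            raise ConfigurationError("input_size must be a multiple of 32")
        if self.transformer_hidden % self.transformer_heads != 0:
            raise ConfigurationError("transformer_hidden must divide by heads")
        if self.pretrained and not self.pretrained_path:
            raise ConfigurationError(
                "pretrained=True requires pretrained_path (local checkpoint)"
            )

    @property
    def skip_channels(self) -> Tuple[int, int, int]:
        """Channels of the three skip levels (strides 2, 4, 8)."""
        return (
            self.stem_channels,
            4 * self.stage_widths[0],
            4 * self.stage_widths[1],
        )

    @property
    def deepest_stride(self) -> int:
        return 16 if self.n_levels == 4 else 32

    @property
    def grid_size(self) -> int:
        return self.input_size // self.deepest_stride

    @classmethod
    def tiny(cls, input_size: int = 64, n_levels: int = 4,
             seed: int = 0) -> "BackboneConfig":
        """A small configuration for CPU experiments and tests."""
        return cls(
            n_levels=n_levels,
            input_size=input_size,
            stem_channels=8,
            stage_widths=(4, 8, 16, 32),
            blocks_per_stage=(1, 1, 1, 1),
            transformer_depth=1,
            transformer_heads=2,
            transformer_hidden=32,
            transformer_mlp_ratio=2.0,
            seed=seed,
        )


@dataclass
class FeaturePyramid:
    """Ordered encoder feature maps, shallow -> deep, with stride metadata."""

    levels: List[Tensor]
    strides: List[int]

    @property
    def skips(self) -> List[Tensor]:
        return self.levels[:3]

    @property
    def deepest(self) -> Tensor:
        return self.levels[-1]


class Bottleneck(nn.Module):
    """1x1 -> 3x3 -> 1x1 residual block with expansion 4."""

    EXPANSION = 4

    def __init__(self, in_ch: int, width: int, stride: int = 1,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        out_ch = width * self.EXPANSION
        self.conv1 = nn.Conv2d(in_ch, width, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(width)
        self.conv2 = nn.Conv2d(width, width, 3, stride=stride, pad=1,
                               bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(width)
        self.conv3 = nn.Conv2d(width, out_ch, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride,
                                       bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: Tensor) -> Tensor:
        out = ad.relu(self.bn1(self.conv1(x)))
        out = ad.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        identity = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return ad.relu(out + identity)


class MultiHeadSelfAttention(nn.Module):
    def __init__(self, dim: int, heads: int,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.heads = heads
        self.dim = dim
        self.head_dim = dim // heads
        self.qkv = nn.Linear(dim, 3 * dim, rng=rng)
        self.proj = nn.Linear(dim, dim, rng=rng)
        self.last_attention: Optional[np.ndarray] = None

    def forward(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        qkv = self.qkv(x).reshape(b, t, 3, self.heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)           # (3, B, H, T, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = ad.matmul(q, k.transpose(0, 1, 3, 2)) * (self.head_dim ** -0.5)
        attn = ad.softmax(scores, axis=-1)           # rows sum to 1 over keys
        self.last_attention = attn.data
        out = ad.matmul(attn, v)                     # (B, H, T, dh)
        out = out.transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.proj(out)


class TransformerBlock(nn.Module):
    def __init__(self, dim: int, heads: int, mlp_ratio: float,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        hidden = int(dim * mlp_ratio)
        self.norm1 = nn.LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng=rng)
        self.norm2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(ad.relu(self.fc1(self.norm2(x))))


class TransformerEncoder(nn.Module):
    """ViT-style encoder over the deepest pyramid level (1x1 patches)."""

    def __init__(self, in_ch: int, cfg: BackboneConfig,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(cfg.seed)
        self.cfg = cfg
        d = cfg.transformer_hidden
        self.patch_embed = nn.Conv2d(in_ch, d, 1, rng=rng)
        n_tokens = cfg.grid_size ** 2
        self.pos_embed = nn.Parameter(
            rng.normal(0, 0.02, size=(n_tokens, d)).astype(np.float32)
        )
        self.blocks = [
            TransformerBlock(d, cfg.transformer_heads, cfg.transformer_mlp_ratio,
                             rng=rng)
            for _ in range(cfg.transformer_depth)
        ]
        self.norm = nn.LayerNorm(d)

    def _pos_for(self, h: int, w: int) -> Tensor:
        n_tokens = h * w
        if n_tokens == self.pos_embed.shape[0]:
            return self.pos_embed
        if not self.cfg.interpolate_pos_embed:
            raise ConfigurationError(
                f"{n_tokens} tokens incompatible with position embeddings of "
                f"size {self.pos_embed.shape[0]}"
            )
        g = int(round(np.sqrt(self.pos_embed.shape[0])))
        grid = self.pos_embed.reshape(g, g, -1).transpose(2, 0, 1)
        grid = grid.reshape(1, *grid.shape)
        resized = ad.upsample_bilinear(grid, h, w)
        return resized.reshape(-1, h * w).transpose(1, 0)

    def encode_tokens(self, tokens: Tensor, pos: Tensor) -> Tensor:
        """Run the attention stack on an explicit token sequence."""
        x = tokens + pos
        for blk in self.blocks:
            x = blk(x)
        return self.norm(x)

    def forward(self, deepest: Tensor) -> Tensor:
        b, c, h, w = deepest.shape
        emb = self.patch_embed(deepest)                      # (B, D, h, w)
        tokens = emb.reshape(b, -1, h * w).transpose(0, 2, 1)  # (B, T, D)
        x = self.encode_tokens(tokens, self._pos_for(h, w))
        d = x.shape[-1]
        return x.transpose(0, 2, 1).reshape(b, d, h, w)


class HybridEncoder(nn.Module):
    """Convolutional pyramid + transformer over the deepest level."""

    def __init__(self, cfg: BackboneConfig,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        cfg.validate()
        rng = rng or np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.stem_conv = nn.Conv2d(3, cfg.stem_channels, 7, stride=2, pad=3,
                                   bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(cfg.stem_channels)
        self.pool = nn.MaxPool2d(3, 2, 1)
        n_stages = cfg.n_levels - 1  # stages after the stem level
        self.stages = []
        in_ch = cfg.stem_channels
        for s in range(n_stages):
            width = cfg.stage_widths[s]
            blocks = [
                Bottleneck(in_ch, width, stride=(2 if s > 0 else 1), rng=rng)
            ]
            for _ in range(cfg.blocks_per_stage[s] - 1):
                blocks.append(Bottleneck(width * 4, width, rng=rng))
            self.stages.append(nn.Sequential(*blocks))
            in_ch = width * 4
        self.transformer = TransformerEncoder(in_ch, cfg, rng=rng)
        if cfg.pretrained:
            state = np.load(cfg.pretrained_path, allow_pickle=False)
            self.load_state_dict(dict(state))

    def extract_pyramid(self, x: Tensor) -> FeaturePyramid:
        n, c, h, w = x.shape
        if h != self.cfg.input_size or w != self.cfg.input_size:
            raise ValueError(
                f"expected {self.cfg.input_size}px input, got {h}x{w}"
            )
        levels, strides = [], []
        out = ad.relu(self.stem_bn(self.stem_conv(x)))   # stride 2
        levels.append(out)
        strides.append(2)
        out = self.pool(out)                             # stride 4 (pre-stage1)
        stride = 4
        for i, stage in enumerate(self.stages):
            out = stage(out)
            levels.append(out)
            strides.append(stride)
            stride *= 2
        return FeaturePyramid(levels=levels, strides=strides)

    def transform_deepest(self, deepest: Tensor) -> Tensor:
        return self.transformer(deepest)

    def forward(self, x: Tensor) -> Tuple[List[Tensor], Tensor]:
        pyr = self.extract_pyramid(x)
        return pyr.skips, self.transform_deepest(pyr.deepest)
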