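"""Visual Regional Enhancer (VRE): codebook-based local feature encoding.

The enhancer's unit is the learnable visual center (LVC).  An input map
C x H x W is read as N = H*W feature vectors x_i.  A codebook holds K
learnable codewords b_k with learnable smoothing factors s_k; each pixel is
softly assigned to the codewords,

    a_ik = exp(-s_k ||x_i - b_k||^2) / sum_j exp(-s_j ||x_i - b_j||^2),

and the weighted residuals a_ik (x_i - b_k) are fused by BRM — batch norm
over the channel axis, ReLU, then the mean over the N pixel positions —
giving one C-vector per codeword.  The K vectors are summed, mapped through
a linear layer, and squashed with a sigmoid into per-channel gating weights
w in (0,1); the output is the input scaled channel-wise by w.  The gate can
only attenuate channels, never amplify them, which is what makes it a
detail *selector* rather than a new feature extractor.

The enhancer runs two LVCs in series by default; parallel (two LVCs fused
by elementwise sum, then a third) and single-LVC arrangements exist for
ablation.  A final 1x1 convolution projects the 64-channel stream back to
the decoder width of the level (512/256/64 deep -> shallow).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import nn
from .nn import autodiff as ad
from .nn.autodiff import Tensor


class Codebook(nn.Module):
    """K learnable codeword vectors plus K learnable smoothing factors."""

    def __init__(self, k: int, channels: int,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        if k < 1:
            raise ValueError("codebook needs K >= 1 codewords")
        rng = rng or np.random.default_rng()
        self.k = k
        self.channels = channels
        scale = 1.0 / np.sqrt(channels)
        self.codewords = nn.Parameter(
            rng.normal(0.0, scale, size=(k, channels)).astype(np.float32)
        )
        self.factors = nn.Parameter(np.ones(k, dtype=np.float32))


class LVC(nn.Module):
    """One learnable-visual-center gating unit."""

    def __init__(self, channels: int, k: int = 64,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.codebook = Codebook(k, channels, rng=rng)
        self.brm_bn = nn.BatchNorm1d(channels)
        self.linear = nn.Linear(channels, channels, rng=rng)

    def lvc_weights(self, x: Tensor) -> Tensor:
        """Gating weights w in (0,1)^C from features x of shape (B, N, C)."""
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        b, n, c = x.shape
        if c != self.codebook.channels:
            raise ValueError(
                f"feature dim {c} != codeword dim {self.codebook.channels}"
            )
        cw = self.codebook.codewords                 # (K, C)
        diff = x.reshape(b, n, 1, c) - cw.reshape(1, 1, self.codebook.k, c)
        sq = (diff * diff).sum(axis=-1)              # (B, N, K)
        logits = -(self.codebook.factors * sq)       # scaled distances
        assign = ad.softmax(logits, axis=-1)         # (B, N, K), sums to 1 over k
        resid = assign.reshape(b, n, self.codebook.k, 1) * diff  # (B, N, K, C)
        fused = ad.relu(self.brm_bn(resid))          # BN over C, shared across k
        per_codeword = fused.mean(axis=1)            # mean over the N pixels
        summed = per_codeword.sum(axis=1)            # sum over the K codewords
        return ad.sigmoid(self.linear(summed))       # (B, C)

    def forward(self, f: Tensor) -> Tensor:
        """Scale the map channel-wise: out[c, h, w] = f[c, h, w] * w[c]."""
        if f.ndim == 3:
            f = f.reshape(1, *f.shape)
        b, c, h, w = f.shape
        x = f.reshape(b, c, h * w).transpose(0, 2, 1)  # (B, N, C)
        gate = self.lvc_weights(x)                     # (B, C)
        return f * gate.reshape(b, c, 1, 1)


ARRANGEMENTS = ("series", "parallel", "single")


class VRE(nn.Module):
    """Visual regional enhancer for one skip level."""

    def __init__(
        self,
        channels: int,
        out_channels: int,
        k: int = 64,
        arrangement: str = "series",
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        if arrangement not in ARRANGEMENTS:
            raise ValueError(
                f"unknown arrangement {arrangement!r}; choose from {ARRANGEMENTS}"
            )
        self.arrangement = arrangement
        if arrangement == "series":
            self.lvcs = [LVC(channels, k, rng), LVC(channels, k, rng)]
        elif arrangement == "parallel":
            self.lvcs = [LVC(channels, k, rng) for _ in range(3)]
        else:
            self.lvcs = [LVC(channels, k, rng)]
        self.proj = nn.Conv2d(channels, out_channels, 1, rng=rng)

    def forward(self, f: Tensor) -> Tensor:
        if self.arrangement == "series":
            out = self.lvcs[1](self.lvcs[0](f))
        elif self.arrangement == "parallel":
            out = self.lvcs[2](self.lvcs[0](f) + self.lvcs[1](f))
        else:
            out = self.lvcs[0](f)
        return self.proj(out)
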