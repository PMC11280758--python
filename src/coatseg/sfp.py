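"""Subtraction Feature Pyramid (SFP).

Skip connections in U-shaped networks forward each encoder level unchanged,
so neighbouring levels carry largely redundant content.  The SFP removes
that redundancy: each skip level is first reduced to 64 channels with a CBR
block, pairwise *subtraction units*

    SU(LA, LB) = CBR(|LA - LB|)

are computed level by level to form a triangular difference pyramid, and
each level then subtracts its accumulated difference sum under a learnable
scalar weight:

    out_l = F_l - alpha_l * D_l        (subtract mode, the default)
    out_l = F_l + alpha_l * D_l        (add mode, ablation)

where D_l is the sum of every difference map that involves level l,
resampled to level l's resolution.  With three skips the pyramid has two
rounds: round 1 yields SU(F0,F1) and SU(F1,F2); round 2 yields the SU of
those two.  The round-2 map involves every level and contributes to all
three D_l.

alpha_l is initialised to zero, so at step 0 the module is an exact
identity and training starts from vanilla skip connections.  Resolution
alignment always bilinearly resamples the coarser map to the finer target.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from . import nn
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import CBR


class SubtractionUnit(nn.Module):
    """CBR of the elementwise absolute difference of two same-shape maps."""

    def __init__(self, channels: int = 64, rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.cbr = CBR(channels, channels, rng=rng)

    def forward(self, la: Tensor, lb: Tensor) -> Tensor:
        if la.shape != lb.shape:
            raise ValueError(f"shape mismatch: {la.shape} vs {lb.shape}")
        return self.cbr(ad.absolute(la - lb))


def _align(x: Tensor, h: int, w: int) -> Tensor:
    return ad.upsample_bilinear(x, h, w)


class SFP(nn.Module):
    """Subtraction feature pyramid over three skip levels (shallow -> deep)."""

    def __init__(
        self,
        in_channels: Sequence[int],
        reduced: int = 64,
        mode: str = "subtract",
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        if len(in_channels) < 2:
            raise ValueError("SFP needs at least two skip levels")
        if mode not in ("subtract", "add"):
            raise ValueError(f"unknown SFP mode {mode!r}")
        self.mode = mode
        self.n_levels = len(in_channels)
        self.reduce_blocks = [CBR(c, reduced, rng=rng) for c in in_channels]
        # round 1: one SU per adjacent pair; round 2: SU of the round-1 maps
        self.su_round1 = [
            SubtractionUnit(reduced, rng=rng) for _ in range(self.n_levels - 1)
        ]
        self.su_round2 = [
            SubtractionUnit(reduced, rng=rng) for _ in range(self.n_levels - 2)
        ]
        self.level_weights = [
            nn.Parameter(np.zeros(())) for _ in range(self.n_levels)
        ]

    # ----------------------------------------------------------- operations
    def reduce_channels(self, skip: Tensor, level: int) -> Tensor:
        if not 0 <= level < self.n_levels:
            raise IndexError(f"level {level} out of range")
        return self.reduce_blocks[level](skip)

    def subtraction_unit(self, la: Tensor, lb: Tensor, unit: int = 0) -> Tensor:
        return self.su_round1[unit](la, lb)

    def sfp_forward(self, skips: Sequence[Tensor]) -> List[Tensor]:
        """Apply the difference pyramid to channel-reduced skips."""
        if len(skips) != self.n_levels:
            raise ValueError(f"expected {self.n_levels} skips, got {len(skips)}")
        sizes = [(s.shape[2], s.shape[3]) for s in skips]
        # round 1: adjacent pairs, evaluated at the finer (shallower) size
        d1 = []
        for i, su in enumerate(self.su_round1):
            la = skips[i]
            lb = _align(skips[i + 1], *sizes[i])
            d1.append(su(la, lb))
        # round 2: adjacent pairs of round-1 maps
        d2 = []
        for i, su in enumerate(self.su_round2):
            la = d1[i]
            lb = _align(d1[i + 1], *sizes[i])
            d2.append(su(la, lb))
        # accumulate, per level, the differences that involve it
        outs: List[Tensor] = []
        sign = -1.0 if self.mode == "subtract" else 1.0
        for level in range(self.n_levels):
            parts: List[Tensor] = []
            for i, d in enumerate(d1):  # d1[i] involves levels i and i+1
                if level in (i, i + 1):
                    parts.append(_align(d, *sizes[level]))
            for d in d2:  # a round-2 map involves every level
                parts.append(_align(d, *sizes[level]))
            acc = parts[0]
            for p in parts[1:]:
                acc = acc + p
            outs.append(skips[level] + sign * self.level_weights[level] * acc)
        return outs

    def forward(self, raw_skips: Sequence[Tensor]) -> List[Tensor]:
        reduced = [self.reduce_channels(s, i) for i, s in enumerate(raw_skips)]
        return self.sfp_forward(reduced)
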