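"""Context feature enhancement: per-level ASPP attention with a residual.

Each backbone level C_i is first projected to the unified pyramid width by a
1×1 convolution φ_i.  An atrous spatial pyramid pooling (ASPP) block over the
projected feature produces per-element attention logits; after a sigmoid the
enhanced feature is

    M_i = (1 + A_i) ⊙ φ_i(C_i),      A_i = σ(f_aspp(φ_i(C_i)))

so attention can only amplify (by up to 2×), never erase, the projected
feature — the residual keeps small-scale responses from being swamped by
context.  Levels never mix: each has its own projection and ASPP.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import functional as F


class ASPP(nn.Module):
    """Four parallel context branches concatenated and projected back.

    Branches: 1×1 conv; 3×3 atrous conv at rate r; 3×3 atrous conv at rate
    2r; global-average pooling → 1×1 conv → broadcast.  The image-pool
    branch can be disabled.  The final 1×1 projection is zero-initialised so
    an untrained block emits zero logits (attention 0.5 everywhere — a mild,
    uniform boost).
    """

    def __init__(self, channels: int, rate: int, *, rng: np.random.Generator,
                 image_pool: bool = True):
        if rate < 1:
            raise ValueError(f"sampling rate must be >= 1, got {rate}")
        self.rate = int(rate)
        self.image_pool = image_pool
        c = channels
        self.b0 = nn.Conv2d(c, c, 1, rng=rng)
        self.b1 = nn.Conv2d(c, c, 3, padding=self.rate, dilation=self.rate, rng=rng)
        self.b2 = nn.Conv2d(c, c, 3, padding=2 * self.rate,
                            dilation=2 * self.rate, rng=rng)
        n_branches = 3
        if image_pool:
            self.b3 = nn.Conv2d(c, c, 1, rng=rng)
            n_branches = 4
        self.project = nn.Conv2d(n_branches * c, c, 1, rng=rng, init="zero")

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        hw = x.shape[2:]
        branches = [F.relu(self.b0(x)), F.relu(self.b1(x)), F.relu(self.b2(x))]
        if self.image_pool:
            pooled = F.relu(self.b3(F.global_avg_pool(x)))
            branches.append(F.broadcast_hw(pooled, hw))
        return self.project(F.concat(branches, axis=1))


class CFEMLevel(nn.Module):
    """Projection + attention enhancement for a single pyramid level."""

    def __init__(self, in_channels: int, channels: int, rate: int, *,
                 rng: np.random.Generator, enabled: bool = True,
                 image_pool: bool = True):
        self.project = nn.Conv2d(in_channels, channels, 1, rng=rng)
        self.enabled = enabled
        self.aspp = ASPP(channels, rate, rng=rng, image_pool=image_pool) \
            if enabled else None
        self.bypass_attention = False  # test hook: forces A ≡ 0

    def attention_logits(self, projected: nn.Tensor) -> nn.Tensor:
        if self.aspp is None:
            raise RuntimeError("attention requested on a disabled level")
        return self.aspp(projected)

    def __call__(self, c: nn.Tensor) -> nn.Tensor:
        if c.shape[2] == 0 or c.shape[3] == 0:
            raise ValueError("empty spatial extent")
        x = self.project(c)
        if not self.enabled or self.bypass_attention:
            return x
        a = F.sigmoid(self.attention_logits(x))
        return F.mul(F.add(1.0, a), x)


class CFEM(nn.Module):
    """One enhancement path per backbone level (levels 2..5)."""

    def __init__(self, in_channels: list[int], channels: int = 256,
                 rate: int = 2, *, rng: np.random.Generator,
                 enabled: bool = True, image_pool: bool = True):
        self.levels = [CFEMLevel(cin, channels, rate, rng=rng, enabled=enabled,
                                 image_pool=image_pool) for cin in in_channels]
        self.enabled = enabled

    def __call__(self, cs: list[nn.Tensor]) -> list[nn.Tensor]:
        if len(cs) != len(self.levels):
            raise ValueError("level count mismatch")
        return [lvl(c) for lvl, c in zip(self.levels, cs)]
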