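"""Adaptive RoI feature fusion across all pyramid levels.

Instead of assigning each proposal to a single pyramid level by its size,
every proposal is RoIAligned from *all* levels into 7×7 patches R_2..R_5.
The concatenated stack R_c is reduced by a 1×1 convolution, passed through a
ReLU and a 3×3 convolution, and a sigmoid yields one spatial weight map per
level:

    w = σ(ϕ₃(ψ(ϕ₁(R_c)))),      R = Σᵢ wᵢ ⊙ Rᵢ

Weights are independent sigmoids (not softmax-normalised across levels) and
spatial-only: each (7×7) map broadcasts over the channel axis of its level.
The ϕ₃ convolution is zero-initialised so an untrained module fuses with a
uniform weight of 0.5 per level.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import functional as F


def pool_roi(pyramids: list[nn.Tensor], strides: list[int],
             boxes: np.ndarray, out_size: int = 7,
             sampling: int = 2) -> list[nn.Tensor]:
    """RoIAlign one box set from every pyramid level.

    Returns one (n, C, out, out) tensor per level — the RoI stack.
    """
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    if np.any(boxes[:, 2] <= boxes[:, 0]) or np.any(boxes[:, 3] <= boxes[:, 1]):
        raise ValueError("degenerate box in pool_roi")
    return [F.roi_align(fm, boxes, spatial_scale=1.0 / s, out_size=out_size,
                        sampling=sampling)
            for fm, s in zip(pyramids, strides)]


class RFFM(nn.Module):
    def __init__(self, n_levels: int = 4, channels: int = 256,
                 out_size: int = 7, *, rng: np.random.Generator):
        self.n_levels = n_levels
        self.channels = channels
        self.out_size = out_size
        self.reduce = nn.Conv2d(n_levels * channels, channels, 1, rng=rng)
        self.weight_conv = nn.Conv2d(channels, n_levels, 3, padding=1,
                                     rng=rng, init="zero")

    def fusion_weights(self, r_c: nn.Tensor) -> nn.Tensor:
        """(n, N·C, 7, 7) → per-level spatial weights (n, N, 7, 7) in (0,1)."""
        if r_c.shape[1] != self.n_levels * self.channels:
            raise ValueError(
                f"expected {self.n_levels * self.channels} channels, "
                f"got {r_c.shape[1]}")
        return F.sigmoid(self.weight_conv(F.relu(self.reduce(r_c))))

    @staticmethod
    def fuse(stack: list[nn.Tensor], weights: nn.Tensor) -> nn.Tensor:
        """R = Σᵢ wᵢ ⊙ Rᵢ with each wᵢ broadcast across channels."""
        n_levels = weights.shape[1]
        if len(stack) != n_levels:
            raise ValueError("weight maps and RoI stack disagree in depth")
        out = None
        for i, r_i in enumerate(stack):
            if r_i.shape[0] != weights.shape[0] or \
                    r_i.shape[2:] != weights.shape[2:]:
                raise ValueError("shape mismatch between weights and stack")
            w_i = F.slice_channels(weights, i, i + 1)       # (n,1,7,7)
            term = F.mul(w_i, r_i)
            out = term if out is None else F.add(out, term)
        return out

    def __call__(self, stack: list[nn.Tensor]) -> nn.Tensor:
        r_c = F.concat(stack, axis=1)
        return self.fuse(stack, self.fusion_weights(r_c))
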