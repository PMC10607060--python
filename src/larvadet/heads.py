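"""Task-separated detection heads.

With task separation enabled, classification and localization run on
*different* fused RoI features from two independent fusion modules: the
classification branch reads the top-down pyramid (P2–P5, semantically
stronger), the localization branch reads the enhanced lateral pyramid
(M2–M5, richer in detail).  Both branches are two 1024-wide fully connected
layers; classification ends in K+1 logits (K classes + background),
localization in 4·K per-class box deltas.  Either branch can be re-pointed at
the other pyramid through configuration, which spans the full 2×2 grid of
(classification source, localization source) pairings.

With task separation disabled the head is the conventional one: a single
shared tower feeding separate final classification and regression layers.

Losses: mean cross-entropy over all sampled proposals for classification;
Smooth L1 over the positive proposals' four deltas (normalised by the number
of sampled proposals) for localization; the two are summed with unit weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F


class FCTower(nn.Module):
    """flatten → FC → ReLU → FC → ReLU."""

    def __init__(self, in_dim: int, width: int, *, rng: np.random.Generator):
        self.fc1 = nn.Linear(in_dim, width, rng=rng)
        self.fc2 = nn.Linear(width, width, rng=rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        flat = F.reshape(x, (x.shape[0], -1))
        return F.relu(self.fc2(F.relu(self.fc1(flat))))


@dataclass
class HeadOutput:
    cls_logits: nn.Tensor      # (n, K+1)
    box_deltas: nn.Tensor      # (n, 4K)


class SeparatedHead(nn.Module):
    """Independent classification and localization branches."""

    def __init__(self, n_classes: int, channels: int = 256, roi_size: int = 7,
                 width: int = 1024, *, rng: np.random.Generator):
        in_dim = channels * roi_size * roi_size
        self.n_classes = n_classes
        self.cls_tower = FCTower(in_dim, width, rng=rng)
        self.loc_tower = FCTower(in_dim, width, rng=rng)
        self.cls_out = nn.Linear(width, n_classes + 1, rng=rng,
                                 init="normal", init_std=0.01)
        self.loc_out = nn.Linear(width, 4 * n_classes, rng=rng,
                                 init="normal", init_std=0.001)

    def classify(self, p_roi: nn.Tensor) -> nn.Tensor:
        return self.cls_out(self.cls_tower(p_roi))

    def localize(self, m_roi: nn.Tensor) -> nn.Tensor:
        return self.loc_out(self.loc_tower(m_roi))

    def __call__(self, p_roi: nn.Tensor, m_roi: nn.Tensor) -> HeadOutput:
        return HeadOutput(self.classify(p_roi), self.localize(m_roi))


class SharedHead(nn.Module):
    """Conventional head: one shared tower, separate output layers."""

    def __init__(self, n_classes: int, channels: int = 256, roi_size: int = 7,
                 width: int = 1024, *, rng: np.random.Generator):
        in_dim = channels * roi_size * roi_size
        self.n_classes = n_classes
        self.tower = FCTower(in_dim, width, rng=rng)
        self.cls_out = nn.Linear(width, n_classes + 1, rng=rng,
                                 init="normal", init_std=0.01)
        self.loc_out = nn.Linear(width, 4 * n_classes, rng=rng,
                                 init="normal", init_std=0.001)

    def __call__(self, roi: nn.Tensor, _unused=None) -> HeadOutput:
        h = self.tower(roi)
        return HeadOutput(self.cls_out(h), self.loc_out(h))


def head_losses(output: HeadOutput, labels: np.ndarray,
                reg_targets: np.ndarray,
                pos_mask: np.ndarray) -> tuple[nn.Tensor, nn.Tensor, bool]:
    """Classification and localization losses for sampled proposals.

    ``labels`` are 0 for background and 1..K for classes; ``reg_targets``
    holds normalised deltas for positive rows (rows of negatives are
    ignored).  Returns (cls loss, loc loss, sampled flag); when no proposals
    were sampled both losses are zero and the flag is False.
    """
    labels = np.asarray(labels, dtype=np.intp)
    n = labels.shape[0]
    if n == 0:
        zero = nn.Tensor(0.0)
        return zero, zero, False
    cls_loss = F.softmax_cross_entropy(output.cls_logits, labels)
    pos = np.flatnonzero(pos_mask)
    if len(pos) == 0:
        return cls_loss, nn.Tensor(0.0), True
    pos_deltas = F.select_per_row(F.take_rows(output.box_deltas, pos),
                                  labels[pos] - 1, width=4)
    loc_loss = F.smooth_l1_loss(pos_deltas, reg_targets[pos], normalizer=float(n))
    return cls_loss, loc_loss, True
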