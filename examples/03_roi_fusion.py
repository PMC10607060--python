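"""Adaptive RoI fusion: pool one proposal from all four pyramid levels and
fuse with learned spatial weights instead of picking a single level.
"""

import numpy as np

from larvadet import nn
from larvadet.rffm import RFFM, pool_roi

rng = np.random.default_rng(0)
channels, strides = 16, [4, 8, 16, 32]
# a synthetic pyramid where each level carries a distinct constant, so the
# fused result reveals the weighting directly
pyramid = [nn.Tensor(np.full((1, channels, 256 // s, 256 // s), float(i + 1)))
           for i, s in enumerate(strides)]

box = np.array([[40.0, 40.0, 140.0, 120.0]])
stack = pool_roi(pyramid, strides, box, out_size=7)
print("RoI stack: " + ", ".join(f"R{i + 2}={r.data.mean():.1f}"
                                for i, r in enumerate(stack)))

fusion = RFFM(n_levels=4, channels=channels, rng=rng)
fused = fusion(stack)
print(f"untrained fusion (all weights 0.5): fused mean = "
      f"{fused.data.mean():.3f}  (= 0.5 * (1+2+3+4) = 5.0)")

# push the weight convolution away from zero: weights differentiate by level
fusion.weight_conv.weight.data = rng.normal(
    0, 0.4, size=fusion.weight_conv.weight.shape)
w = fusion.fusion_weights(nn.functional.concat(stack, axis=1))
print("per-level mean weights after perturbing the weight head: " +
      ", ".join(f"w{i + 2}={w.data[0, i].mean():.3f}" for i in range(4)))
print("(weights are independent sigmoids per level, learned end to end; "
      "no level is hard-selected)")
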