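"""Position/channel attention on a toy feature map.

Builds a small feature map, shows that the attention affinities are
row-stochastic, that the zero-initialized gates make both modules start
as the identity, and that the dual-attention block preserves shape.
"""

import numpy as np

from datransunet import (ChannelAttention, DABlockConfig, DualAttentionBlock,
                         PositionAttention, channel_affinity, spatial_affinity)

rng = np.random.default_rng(0)
feature = rng.normal(size=(4, 6, 6)).astype(np.float32)   # C=4, H=W=6

S = spatial_affinity(feature, feature)
X = channel_affinity(feature)
print(f"spatial affinity: {S.shape}, row sums {S.sum(axis=1).min():.6f}"
      f"..{S.sum(axis=1).max():.6f}")
print(f"channel affinity: {X.shape}, row sums {X.sum(axis=1).min():.6f}"
      f"..{X.sum(axis=1).max():.6f}")
# Each row is a probability distribution: position j (channel j) decides
# how much to listen to every other position (channel).

pam = PositionAttention(4, np.random.default_rng(1))
cam = ChannelAttention()
print("PAM output equals input at init (alpha=0):",
      bool(np.allclose(pam(feature), feature)))
print("CAM output equals input at init (beta=0):",
      bool(np.allclose(cam(feature), feature)))

pam.alpha.data[:] = 0.5
delta = np.abs(pam(feature) - feature).mean()
print(f"after opening the gate to 0.5, mean |change| = {delta:.4f}")

block = DualAttentionBlock(DABlockConfig(in_channels=32, reduction=16),
                           np.random.default_rng(2))
x = rng.normal(size=(2, 32, 8, 8)).astype(np.float32)
y = block(x)
print(f"DA-block: {x.shape} -> {y.shape} "
      f"(intermediate width {block.cfg.mid_channels} = 32/16)")
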