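"""Train the desk-scale model on phantoms and score it.

Runs a short CPU training of the tiny configuration on 8 binary
phantoms, then evaluates Dice/IoU/Hausdorff on the training images --
a capacity check: exact ground truth means a sufficiently expressive
model should approach Dice 1.
"""

import numpy as np

from datransunet import (PhantomSpec, TrainConfig, evaluate, make_binary_phantoms,
                         tiny_config, train)

data = make_binary_phantoms(PhantomSpec(n_images=8, img_size=64, seed=7))
cfg = TrainConfig(network=tiny_config(n_classes=1), epochs=200, val_fraction=0.0,
                  stop_at_dice=0.96, seed=3)
model, history = train(cfg, data)

last = history.iloc[-1]
print(f"stopped after {len(history)} epochs "
      f"(loss {last.train_loss:.4f}, train dice {last.val_dice:.4f})")

frame, summary = evaluate(model, data)
print(f"mean dice {summary['mean_dice']:.4f}  mean iou {summary['mean_iou']:.4f}  "
      f"mean hd {summary['mean_hd']:.2f} px  mean hd95 {summary['mean_hd95']:.2f} px")
# Dice/IoU near 1 and Hausdorff of a few pixels mean the network
# reproduces the generating geometry almost exactly.
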