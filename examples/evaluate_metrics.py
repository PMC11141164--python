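"""The evaluation metrics on small constructed masks.

Shows the exact hand-checkable values: partial overlap, the
dice = 2*iou/(1+iou) identity, a single-pair Hausdorff distance, and how
the robust 95th-percentile variant discounts an outlier.
"""

import numpy as np

from datransunet import dice_coefficient, evaluate_masks, hausdorff, hd95, iou

truth = np.zeros((4, 4), bool)
truth[1, 1] = truth[1, 2] = True          # two foreground pixels
pred = np.zeros((4, 4), bool)
pred[1, 1] = True                         # hits one of them
d, j = dice_coefficient(pred, truth), iou(pred, truth)
print(f"one-of-two overlap: dice = {d:.4f} (2/3), iou = {j:.4f} (1/2)")
print(f"identity 2*iou/(1+iou) = {2 * j / (1 + j):.4f} = dice")

a = np.zeros((6, 6), bool); a[0, 0] = True
b = np.zeros((6, 6), bool); b[3, 4] = True
print(f"single-pixel masks at (0,0) and (3,4): hausdorff = {hausdorff(a, b):.1f} px")

t = np.zeros((40, 110), bool); t[0, 1:101] = True
p = np.zeros((40, 110), bool); p[3, 2:101] = True; p[30, 1] = True  # one outlier
print(f"100-point boundary with one outlier: hd = {hausdorff(p, t):.1f} px, "
      f"hd95 = {hd95(p, t):.1f} px (robust to the outlier)")

report = evaluate_masks(pred.astype(int), truth.astype(int), n_classes=2)
print("per-class report:", report.summary())
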