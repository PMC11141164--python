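"""Ablation harness: where the dual-attention blocks sit and how wide.

Three axes mirror the published study design:

* ``placement`` -- encoder DA and skip DA toggled independently (4 rows);
* ``skip_layers`` -- with encoder DA on, DA in no / one / all skip layers
  (5 rows);
* ``reduction`` -- the intermediate-channel divisor swept over
  {1, 2, 4, 8, 16, 32} with all DA on (6 rows).

Every variant in one run shares the data split and the initialization
seed so the comparison is architectural only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .network import NetworkConfig, build_model, count_parameters
from .phantoms import read_dataset, split_dataset
from .training import TrainConfig, evaluate, train

REDUCTION_SWEEP = (1, 2, 4, 8, 16, 32)


@dataclass
class AblationSpec:
    axis: str  # placement | skip_layers | reduction
    variants: Optional[Sequence] = None

    def resolved_variants(self) -> list[dict]:
        if self.axis == "placement":
            combos = [(False, False), (False, True), (True, False), (True, True)]
            return [{"name": f"enc={'on' if e else 'off'},skips={'on' if s else 'off'}",
                     "da_encoder": e, "da_skips": (s, s, s)}
                    for e, s in combos]
        if self.axis == "skip_layers":
            layouts = [("none", (False, False, False)),
                       ("layer1", (True, False, False)),
                       ("layer2", (False, True, False)),
                       ("layer3", (False, False, True)),
                       ("all", (True, True, True))]
            return [{"name": name, "da_encoder": True, "da_skips": flags}
                    for name, flags in layouts]
        if self.axis == "reduction":
            sweep = tuple(self.variants) if self.variants else REDUCTION_SWEEP
            return [{"name": f"reduction={r}", "da_encoder": True,
                     "da_skips": (True, True, True), "reduction": r}
                    for r in sweep]
        raise ValueError(f"unknown ablation axis {self.axis!r}")


def ablation_run(spec: AblationSpec, base_cfg: TrainConfig, dataset,
                 output_dir=None) -> pd.DataFrame:
    """Train and score every variant on a shared split; one row each."""
    if not isinstance(dataset, (list, tuple)):
        dataset = read_dataset(dataset)
    train_items, test_items = split_dataset(dataset, 0.75, base_cfg.seed)

    rows = []
    for variant in spec.resolved_variants():
        overrides = {k: v for k, v in variant.items() if k != "name"}
        net = NetworkConfig.from_dict({**base_cfg.network.to_dict(), **overrides})
        cfg = dataclasses.replace(base_cfg, network=net, val_fraction=0.0,
                                  output_dir=None)
        model, history = train(cfg, train_items)
        _, summary = evaluate(model, test_items)
        rows.append({
            "variant": variant["name"],
            "da_encoder": net.da_encoder,
            "da_skips": "".join("1" if f else "0" for f in net.da_skips),
            "reduction": net.reduction,
            "n_parameters": count_parameters(model),
            "mean_dice": summary["mean_dice"],
            "mean_iou": summary["mean_iou"],
            "mean_hd": summary["mean_hd"],
            "mean_hd95": summary["mean_hd95"],
            "final_train_loss": float(history["train_loss"].iloc[-1]),
        })
    frame = pd.DataFrame(rows)
    if output_dir:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / f"ablation_{spec.axis}.csv", index=False)
    return frame
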