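"""Parameter accounting for the full-scale hybrid network.

Builds the DA-free baseline and the full dual-attention model and prints
their trainable-parameter counts and the relative increase the four
DA-blocks cost.  Takes a few seconds (the models hold ~10^8 weights).
"""

from datransunet import build_model, count_parameters, r50_config

baseline = build_model(r50_config(da_encoder=False, da_skips=(False,) * 3), seed=0)
full = build_model(r50_config(), seed=0)

n_base = count_parameters(baseline)
n_full = count_parameters(full)
print(f"baseline (no dual attention): {n_base:,} parameters")
print(f"dual-attention model:         {n_full:,} parameters")
print(f"DA overhead: {n_full - n_base:,} parameters "
      f"(+{100 * (n_full - n_base) / n_base:.2f} %)")
# The overhead is small because every DA-block works at 1/16 of its
# input channel count before restoring it.
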