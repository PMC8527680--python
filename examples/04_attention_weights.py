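"""Inspect which residues the self-attention mechanism weighs most.

Trains on compositionally tilted synthetic data (positives enriched in
C,F,G,H,I,N,S,Y), then averages each residue's *received* attention mass —
column sums of the weight matrices — over the positive peptides.  Residues
from the enriched set should attract more than the uniform 1/L baseline once
the model has learned the signal; the per-peptide weight matrices are the
same quantity the `acpnet attention` command exports as TSV for heat-map
style visualization.
"""

import numpy as np

from acpnet import (
    ModelConfig, SyntheticSpec, batch_encode, build_model, generate_dataset,
    multi_head_self_attention, one_hot_encode, train,
)
from acpnet.synthetic import POS_ENRICHED

ds = generate_dataset(SyntheticSpec(n_pos=60, n_neg=60, effect=2.0, seed=2,
                                    length_range=(10, 30)))
batch = batch_encode(ds)
config = ModelConfig(
    seq_conv={"n_kernels": 8, "kernel": 5},
    struct_conv={"n_kernels": 4, "kernel": 3},
    seq_lstm_units=8, struct_lstm_units=4, dense_hidden=16,
    learning_rate=3e-3, max_epochs=12, batch_size=32, seed=2,
)
fitted = train(build_model(config, batch.max_len), batch, config)
params = fitted.rebuild().attention_params()

enriched_ratio, other_ratio = [], []
for rec in ds.records:
    if rec.label != 1:
        continue
    L = len(rec.sequence)
    onehot, mask = one_hot_encode(rec.sequence, L)
    weights = multi_head_self_attention(onehot, params, mask).weights
    share = weights.mean(axis=0).sum(axis=0) / L  # received mass share per residue
    flag = np.array([aa in POS_ENRICHED for aa in rec.sequence])
    if flag.any():
        enriched_ratio.append(share[flag].mean() * L)
    if (~flag).any():
        other_ratio.append(share[~flag].mean() * L)

print(f"received attention mass relative to uniform baseline (1.0 = uniform):")
print(f"  ACP-enriched residues (C,F,G,H,I,N,S,Y): {np.mean(enriched_ratio):.4f}")
print(f"  other residues:                          {np.mean(other_ratio):.4f}")
print("a ratio above 1 for the enriched set means attention concentrates on the "
      "residue class that carries the anticancer signal; the effect is small for "
      "a single seed but directionally consistent")
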