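"""Generate a synthetic labeled peptide dataset and inspect its class signal.

Positives are compositionally enriched in C,F,G,H,I,N,S,Y and carry
helix-tilted secondary-structure profiles; negatives are enriched in
E,L,M,Q,R,W.  The printed total-variation distance between the empirical
class residue distributions grows with `effect`.
"""

import numpy as np

from acpnet import AMINO_ACIDS, SyntheticSpec, generate_dataset

for effect in (0.0, 1.0, 2.0):
    spec = SyntheticSpec(n_pos=500, n_neg=500, effect=effect, helix_bias=1.0, seed=42)
    ds = generate_dataset(spec)

    def freqs(label):
        counts = np.zeros(20)
        for r in ds.records:
            if r.label == label:
                for aa in r.sequence:
                    counts[AMINO_ACIDS.index(aa)] += 1
        return counts / counts.sum()

    tv = 0.5 * np.abs(freqs(1) - freqs(0)).sum()
    helix = {
        lab: np.mean([ds.profiles[r.id].probs[:, 0].mean() for r in ds.records if r.label == lab])
        for lab in (0, 1)
    }
    print(f"effect={effect:3.1f}  residue TV distance {tv:.3f}  "
          f"mean helix prob pos/neg {helix[1]:.3f}/{helix[0]:.3f}")

# TV distance ~0 at effect=0 (no learnable composition signal) and ~0.2 at
# effect=2; the helix gap is the structural signal the structure branches use.
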