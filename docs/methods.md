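# Methods

## Problem and model

`acpnet` classifies short peptides (5–50 residues over the 20 canonical
amino acids) as anticancer (ACP) or not, from two channels: the sequence
itself and a per-residue 3-state secondary-structure probability profile
produced by an external predictor. The two channels are deliberately kept in
separate feature branches until the final dense layer, so sequence and
structure information do not cross-talk during feature extraction.

The architecture is described in the README. Points that are conventions of
this implementation rather than forced by the problem:

* **One-hot alphabet order** is fixed alphabetical (`ACDEFGHIKLMNPQRSTVWY`).
  Any fixed order is equivalent up to a column permutation, but it must be
  frozen for checkpoint compatibility.
* **Structure state order** is fixed internally as (helix, strand, coil).
  Upstream predictors label these states inconsistently; the TSV header
  (`p_helix, p_strand, p_coil`) makes the convention explicit, and profiles
  are clipped to [0, 1] and renormalized per residue on load (row sums must
  already be within 1e-3 of 1).
* **Padding** is post-padding with an explicit validity mask. The mask
  drives additive −1e9 key masking (and query-row zeroing) in attention and
  frozen state updates in the LSTM. Convolutions intentionally carry **no
  bias term**, so all-zero padding rows contribute exactly nothing; together
  these make predictions invariant to appended padding, which the tests
  assert to 1e-6 and which holds exactly in practice.
* **Attention scaling** divides scores by √d_w with d_w the full model width
  (20), not the per-head width. The output matrix W^M left-multiplies each
  position's concatenated head vector (`enhanced = concat @ W_m.T`),
  preserving the n×d_w shape. No positional encoding is used; the map is
  permutation-equivariant over valid positions, and a property test asserts
  this.
* **Masked-query rows** of an attention weight matrix are defined as uniform
  over valid keys in the functional API (they are zeroed in the model and in
  exported weights, so padding emits no mass).
* **LSTM gates** use the peephole form (cell state visible to all three
  gates, as full matrices; the output gate sees the freshly updated cell).
  A `peephole=False` compatibility mode matches common framework cells.
* **Dense head**: one hidden ReLU layer (default 64 units), dropout 0.45
  after it (training only), then a single sigmoid unit. Classification
  threshold 0.5, with a score exactly at the threshold called positive.
* **Inter-head disagreement regularization** is the mean pairwise cosine
  similarity of flattened head outputs, scaled by `head_reg_weight`
  (default 0 = off; with the default h = 2 the heads stay diverse without
  it). All-zero heads contribute 0 by convention.

## Training

Adam (lr 1e-3 default, betas 0.9/0.999) on mean binary cross-entropy with
probabilities clipped to [1e-7, 1−1e-7]. A stratified 10% validation split
(per class, seeded) drives early stopping on validation loss with patience
10 and best-weight restoration; `val_fraction=0` disables it. Non-finite
loss aborts with diagnostics. All randomness (initialization, shuffling,
dropout, splits) flows from one integer seed through `numpy` generators, so
training is bit-reproducible; the test suite asserts identical weights and
history for two same-seed runs.

The network runs on a compact in-repo reverse-mode autodiff engine
(`acpnet.autodiff`, float64 throughout) — a deliberate dependency-light
design for a model this small. Its gradients are asserted against central
differences, and every layer's forward pass is asserted against an
independent plain-loop reference implementation.

## Evaluation

Confusion-based Acc/Sens/Spec/Prec/Mcc with zero-denominator cases returning
0.0 plus a recorded `undefined` flag (the convention matters mostly for tiny
or single-class folds). ROC is an in-repo threshold sweep over unique scores
with trapezoidal area; tests pin it to the tie-corrected Mann–Whitney rank
statistic to 1e-9 and to scikit-learn's implementation. Cross-validation is
stratified (scikit-learn `StratifiedKFold` behind the module surface),
seeded, with per-fold metrics, their unweighted mean, and a headline AUC
pooled over concatenated held-out scores. Each fold's model trains from
scratch with a fold-specific seed offset.

## Synthetic data: what it emulates and what it does not

`generate_dataset` draws lengths uniformly in [5, 50] and residues i.i.d.
from a uniform 1/20 background tilted multiplicatively by (1 + `effect`) on
the class-enriched sets (positives: C,F,G,H,I,N,S,Y; negatives: E,L,M,Q,R,W
— the compositional preferences reported for curated ACP benchmarks).
Structure profiles are per-residue Dirichlet draws with base concentration
(2, 2, 2), the helix component scaled by (1 + `helix_bias`) for positives.
Defaults `effect = 1`, `helix_bias = 1` are free parameters chosen to give a
clearly learnable but not saturated signal; `effect = 0` **and**
`helix_bias = 0` is the null regime with identical class-conditional
distributions (the two signal channels are independent dials, so a genuine
null requires both at zero). A uniform background rather than natural
amino-acid abundances isolates the planted signal.

This emulates class-conditional composition and coarse structure bias only.
Real peptides have positional motifs, autocorrelated structure along the
chain, length–class dependence and curation/homology artifacts, none of
which are modelled. Passing the synthetic benchmarks therefore shows the
pipeline can detect the kinds of signal it was built for — it does not
certify benchmark-level accuracy on real ACP datasets.

`separable_fixture` plants the motif FGHC in every positive (rejection
sampling keeps it out of negatives) for overfit and smoke tests.

## Problem sizes in tests and the acceptance script

Training-based checks run the full five-branch architecture at reduced
widths — 8/4 convolution kernels (sizes 5×5/3×3 as in the default), 8/4
LSTM units, 16 dense units, ≤30 epochs — which keeps the whole suite at a
few CPU-minutes while exercising every code path of the full-size model
(the full-scale widths 300/150/45/20 remain the `ModelConfig` defaults and
are used by the CLI unless overridden). Signal recovery uses n = 400 with
`effect = 2` (5-fold CV, mean held-out AUC ≈ 1) and the null uses
`effect = helix_bias = 0` (pooled AUC ≈ 0.5); the structure-ablation check
uses n = 150, `effect = 0.25`, `helix_bias = 2`, k = 3 over 3 seeds, a
regime where structure carries most of the class signal so the
structure-enabled model's advantage is directional and large. The
attention-localization check aggregates 3 seeded runs; the localization
effect is consistently positive but small per seed, so single-run ratios
should not be over-read.

## Known limitations

* The convolution treats the L×20 one-hot plane as a single-channel image
  with square kernels spanning the feature axis partially; this follows the
  stated kernel geometry, but it makes some kernel columns align with
  arbitrary alphabet positions — a per-residue 1-D convolution would be the
  more conventional alternative.
* CPU-only and float64; full-scale widths train in minutes–hours on one
  core for benchmark-sized datasets, not seconds.
* No transfer learning, pretrained embeddings, or comparison baselines; no
  secondary-structure prediction (profiles are consumed, never computed).
* Sequences longer than 50 residues are rejected, not truncated.
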