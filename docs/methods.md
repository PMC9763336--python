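# Methods

## Problem and scope

`acpkit` classifies short peptides (3–50 residues, standard 20-letter
alphabet) as anticancer peptides (ACPs) or non-ACPs from sequence alone.
The package covers the full experimental loop — encoding, model fitting,
cross-validated selection, independent testing with redundancy control,
and post-hoc explanation — and ships a synthetic data generator so every
stage runs and is tested without external downloads.

## Sequence encodings

A peptide of length *l* becomes an `Lmax × d` matrix with `Lmax = 50`;
rows beyond *l* are padded with 0.0. Zero is the least-informative pad
after z-scoring, and pad rows are exactly all-zero, which inference also
exploits to recover true lengths when masking is enabled.

* **bpf** (d = 20): one-hot at the residue's alphabetical index
  (A, C, D, …, Y). This ordering is the single source of truth for
  column order; the property CSV's storage row order never leaks into
  encodings.
* **quanc** (d = 26): bpf plus six quantitative properties — molecular
  mass (Da), isoelectric point (pH), pk1 (α-carboxyl), pk2 (α-amino),
  side-chain pKa, van der Waals volume (Å³). Residues without a
  side-chain pKa carry the literal padding value 0, which enters the
  z-score as printed in the source table. Standardization is per column
  over the 20 amino-acid rows with population standard deviation
  (divide by 20), so the encoding is dataset-independent; the μ/σ
  snapshot is still serialized with every model for provenance.
  Proline's isoelectric point is flagged provisional in the shipped CSV
  (set to the standard reference value 6.30; the other proline fields
  follow column-count analogy with the zero-pKa rows).
* **qualc** (d = 30): bpf plus one-hot blocks for four categorical
  properties: hydrophobicity {Y, N}, polarity {Y, N}, charge
  {negative, positive, N}, aromatic/aliphatic {aromatic, aliphatic, N}.
  Both levels of the binary properties are encoded (2 + 2 + 3 + 3 = 10,
  which is what the 30 − 20 dimension arithmetic forces); each block
  sums to exactly 1 for every residue.
* **mix** (d = 36): bpf ∥ quanc block ∥ qualc block.
* **embedding** (d = 36): no fixed encoder; a trainable 20 × 36 lookup
  inside the network maps the one-hot input and is learned jointly.
  It serves as the prior-free baseline against the knowledge-based
  schemes.

The scheme name `quanl` is accepted as an alias for `qualc` (both
abbreviations circulate for the bpf+qualc combination).

## Architectures

Both models end in dense(`dense_units`, ReLU) → dense(2, softmax).

* **basic**: Bi-LSTM with `n_units` per direction; the classifier sees
  the concatenated final hidden states (2n).
* **selfatt**: the Bi-LSTM returns per-position outputs `x_t` (2n wide).
  Additive self-attention scores every ordered pair,
  `h_{t,t'} = tanh(x_t W_t + x_{t'} W_x + b_t)`,
  `e_{t,t'} = σ(W_a h_{t,t'} + b_a)` with σ the logistic sigmoid (the
  conventional choice for this additive self-attention family), rows
  normalized by softmax and re-combined, `l_t = Σ_{t'} a_{t,t'} x_{t'}`.
  Attention pooling then collapses positions:
  `e = hW + b`, `α = softmax(e)`, output `Σ_j α_j h_j`, with
  `W ∈ ℝ^{2n}`, `b ∈ ℝ^{Lmax}`. Pooling consumes the self-attention
  output, matching the layer order basic → self-attention → attention.

Design choices where the architecture family leaves freedom: the
self-attention score path width defaults to 32 (configurable); the first
dense layer uses ReLU; no dropout; padded positions are *not* masked by
default (pad rows are all-zero, and the default mirrors the simplest
formulation), but `mask_padding=True` freezes LSTM state past the true
length for both training and inference.

## Numerical core

No deep-learning framework is a dependency: layers run on an in-package
reverse-mode autodiff engine over float64 numpy arrays (broadcast
arithmetic, batched matmul, elementwise nonlinearities, reductions,
slicing, concatenation). Every primitive and both full architectures are
verified against central finite differences in the test suite. LSTM
gates follow the standard i/f/g/o parameterization with Glorot-uniform
weights and forget-gate bias 1; training is Adam (β₁ = 0.9, β₂ = 0.999)
on categorical cross-entropy. Determinism: all initialization and
shuffling derive from the config seed; inference is pure numpy, so a
serialized-and-reloaded model (single `.npz` with weights + JSON
metadata) reproduces predictions bit-for-bit.

Defaults that are community convention rather than derived: learning
rate 1e-3, batch size 32, threshold 0.5 on P(ACP) with the boundary
counted as a positive call.

## Evaluation and selection

ACC, Sen, Spc are confusion-matrix percentages; MCC is computed directly
with the convention that a zero denominator factor yields MCC = 0
(avoids NaNs poisoning grid search on degenerate folds); AUC is the
Mann–Whitney concordance probability (delegated to scikit-learn,
cross-checked against exhaustive pair counting in tests).

Stratified K-fold splitting deals each class round-robin after a seeded
shuffle, so per-fold class counts differ by at most one; holdout
splitting takes `round(fraction × class size)` per class. Five-fold CV
retrains each fold from scratch with fold-derived seeds (seed + fold
index) and averages per-fold metrics arithmetically — AUC included
(per-fold averaging, not pooling, to keep all metrics on the same
footing; pooled AUC can be computed from the exported predictions if
wanted). Grid search maximizes mean CV MCC, breaking ties by higher
mean ACC, then fewer epochs, then grid order.

## Redundancy filtering

To measure generalization, test peptides similar to the training set can
be removed at identity thresholds such as 40/80/90%. Identity here is
the number of identical aligned positions in a Needleman–Wunsch global
alignment (match = 1, mismatch = 0, gap = −1, traceback ties broken
diagonal-first, then up, then left) divided by the shorter sequence
length. This mirrors the shorter-sequence denominator convention of
CD-HIT-style tools but is a documented stand-in, not bit-compatible
with CD-HIT's greedy word-filtered clustering.

## Explanation

Shapley attributions treat each (position, channel) cell of the encoded
matrix as a player; an absent feature is replaced by the mean of a
background set (by default drawn from training encodings). The estimator
is permutation sampling: each random feature ordering walks from the
all-background baseline to the sample, crediting marginal changes, so
`φ₀ + Σ φᵢ = P(ACP)` holds *by construction* for any permutation count
(observed reconstruction error ~1e-16), and averaging permutations
converges to exact Shapley values. An exhaustive 2^M enumeration is
provided for M ≤ 20 and anchors the estimator tests (efficiency,
symmetry, null-player axioms; permutation estimate within 0.02 of exact
on a 3-feature toy at 2000 permutations). Attributions target the
ACP-class probability. Channel importance is mean |φ| over samples and
positions per channel, ranked descending with ties broken by channel
index. Penultimate-layer activations (the first dense layer) can be
projected by PCA for 2-D class-separation plots; degenerate
(zero-variance) feature sets are rejected explicitly.

Because encoding channels are correlated (e.g. a lysine lights up
`bpf_K`, `charge_positive`, a high isoelectric point and pKa at once),
Shapley credit for one biological signal spreads across its correlated
channels; rankings should be read at the level of channel groups, not
single channels.

## Synthetic benchmark

The generator plants the compositional contrast that distinguishes ACPs
from random peptides: positives draw residues i.i.d. with weight 4 on
{K, R, H, F, W, Y} and 0.25 on {D, E} (1 otherwise, normalized), giving
an expected enriched-residue fraction ≈ 0.66 versus 0.30 for uniform
negatives; lengths are uniform on [3, 50]. Defaults are 200 + 200
peptides at seed 7 — large enough that a small basic/mix model (32
units, 50 dense, 15 epochs) exceeds 90% mean CV accuracy and 0.8 MCC,
small enough that full CV plus a Shapley report runs in about a minute
on one CPU. The signal is deliberately compositional rather than
motif-based so the explanation stage can rediscover it at channel grain.

What passing on this benchmark does **not** show: real ACP-vs-AMP
discrimination is far harder (ACPs are a subset of antimicrobial
peptides, and real data carry motif structure, length–composition
coupling and label noise the generator omits). Synthetic results
validate the machinery, not clinical performance; benchmark datasets in
FASTA + label-TSV form drop into the same pipeline unchanged.

## Limitations

* Non-standard amino acids are rejected rather than remapped.
* The identity filter is quadratic in sequence count and unoptimized;
  it targets test-set curation, not large-scale clustering.
* The numpy training loop is single-threaded; it is sized for the
  benchmark scales above (hundreds of peptides), not for corpus-scale
  training.
* Exact Shapley is exponential; the permutation estimator's per-channel
  rankings at few permutations are stable for strong signals only.
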