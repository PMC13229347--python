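# Methods

## Problem setting

Given fixed-length embeddings of two proteins, decide whether the pair
interacts. Embeddings are produced upstream by a pretrained protein
language model and consumed here as an identifier-indexed N×D matrix;
the package never computes embeddings itself (the `SequenceEmbedder`
protocol defines the adapter boundary for an external embedder).

## Preprocessing

Language-model embeddings are heavy-tailed and carry outliers, so the
matrix is normalised per dimension by median and interquartile range,
X_scaled = (X − median) / (Q3 − Q1), rather than by mean and standard
deviation. Quantiles use the linear-interpolation ("type 7")
convention; the convention is recorded in the persisted scaler JSON so
a fitted scaler is reproducible elsewhere. Dimensions whose IQR falls
below 1e-8 are centred but left unscaled (divisor 1). The scaler is
fitted on training-set proteins only; fitting on all data would leak
held-out statistics into the transform.

Each pair yields four model inputs: the two scaled embeddings, their
element-wise product and their absolute difference. During training,
independent Gaussian noise N(0, σ²I) with σ = 0.02 is added to both
scaled embeddings — resampled every epoch — *before* the product and
difference are formed, so the derived features see the perturbed
inputs. Augmentation is disabled at evaluation time.

## Architecture

Four parallel attention blocks (one per input view), bidirectional
cross-attention between the protein streams and between the
product/difference streams, concatenation, a two-layer GELU fusion
network, and four task heads. Defaults: hidden 256, 8 heads, FFN
expansion 4, dropout 0.1, 4 type classes, uncertainty cap 10.

Two choices deserve explanation:

* **Token factoring.** Multi-head attention is defined over a token
  sequence, but each stream state is a single flat vector; a length-1
  sequence degenerates attention into a linear map. By default each
  hidden vector is reshaped into `n_tokens = 8` tokens of
  `hidden_dim/8` channels, so self- and cross-attention mix channel
  groups. `n_tokens = 1` is supported for the literal flat-vector
  reading; both modes are tested, and neither is claimed to be the
  uniquely correct interpretation.
* **Gated residual.** The self-attention branch enters through a
  learnable scalar α initialised at 0, so every block starts as an
  identity-plus-FFN map and learns how much attention to admit. This
  gives stable early training; the gradient to α is nonzero from the
  first step, so the gate opens as soon as attention helps.

Stream parameters are not shared: each view gets its own block, which
lets streams specialise. Symmetry properties (swapping the pair swaps
the protein streams) hold exactly only under explicitly tied weights,
and are tested that way.

## Objective

L = λ₁·BCE(p, y) + λ₂·mean(±u) + λ₃·MSE(s, 2|p−0.5|·y) + λ₄·KL(t ‖ uniform),
with λ = (1.0, 0.1, 0.1, 0.1) by default: the interaction task
dominates and the auxiliaries act as regularisers. Specifics:

* probabilities are clipped to [1e-7, 1−1e-7] before logs;
* the hard label ŷ is 1 iff p > 0.5 (strictly), so p = 0.5 counts as
  negative;
* the uncertainty term is +u on correct and −u on incorrect pairs. As
  written it is unbounded below on a persistently wrong pair, so the
  softplus head caps u at u_max = 10; the cap preserves the ordering
  incentive (low u when right, high u when wrong) while keeping the
  objective bounded. A test demonstrates the divergence without the
  cap;
* the binding target 2|p−0.5|·y is a constant with respect to the
  graph (stop-gradient): a regression target that moved with the
  prediction would let the MSE collapse trivially;
* with no type labels, the type head is regularised toward the uniform
  distribution by KL divergence (the cross-entropy branch activates
  when labels are supplied).

## Data curation and splitting

Pairs are unordered: canonicalisation puts the lexicographically
smaller identifier first and deduplication keeps the first occurrence
of each pair. A pair recorded with both labels has no principled
winner, so the conflict is reported and the call refuses. Self-pairs
are retained. Class balancing is by majority undersampling or minority
oversampling-with-replacement (all originals retained).

Splitting is two-stage stratified: the test partition is carved out
first and never revisited, then validation is separated from training,
each stage allocating per-class quotas by largest fractional part —
deterministic and row-order-independent. Partition counts follow
test = ⌈0.12·N⌉ and validation = round-half-up(0.20·N); a nested
variant (validation as a fraction of the post-test remainder) is
available as `compute_split_sizes_nested`. Because oversampling before
splitting can place copies of one record on both sides of a boundary,
`audit_leakage` counts cross-split duplicate pairs; the split manifest
always includes the audit. Splits are by pair, not by protein: a
protein may appear in several partitions, so these splits measure
generalisation to unseen *pairs*, not unseen proteins.

## Training

Mini-batch optimisation with Adam, AdamW or RMSprop (weight decay
L2-coupled for Adam/RMSprop, decoupled for AdamW), schedulers
ReduceLROnPlateau (factor 0.5, patience 5, monitoring validation
accuracy), StepLR (halve every 10 epochs) or cosine annealing to
max_epochs. Defaults: 100 epochs maximum, early stop after 10 stagnant
epochs of validation accuracy, model selection by best validation
accuracy. The hyperparameter grid spans 4 learning rates × 3 weight
decays × 3 optimizers × 3 schedulers × 4 batch sizes = 432
configurations; a seeded random subset supports budgeted searches.
Every source of randomness (init, shuffling, dropout, augmentation)
derives from the configured seeds, so a run is bit-reproducible.

## Synthetic benchmark

The generator emulates the two properties of real embedding data the
pipeline is built around, and nothing else:

* **Heavy tails** — per-coordinate Student-t draws with tail_df = 3
  degrees of freedom, rescaled to unit variance, giving the positive
  excess kurtosis and outliers that motivate robust scaling.
* **A learnable pairwise rule** — a symmetric bilinear score
  s(a, b) = aᵀSb with S of rank `rule_rank` (default 4), thresholded
  at the empirical quantile that produces the requested positive
  fraction. The rank-r factors are coordinate spikes with a small
  dense admixture (weight 0.05), which concentrates most of the score
  variance on the diagonal of S. This keeps the planted signal
  expressible through the element-wise product feature (a linear probe
  on [x_int; x_diff] separates the classes well above chance) while
  the off-diagonal part still requires genuinely bilinear modeling —
  so all four streams carry signal and the rule is recoverable by the
  network. Label noise flips each label independently with a
  configurable probability.

Identifiers are "P000001"-style; the store, the rule and the pair
sample each derive their RNG from the base seed at fixed offsets so any
stage can be regenerated independently. The benchmark does not attempt
biological realism beyond these properties: there are no sequences, no
protein families, no homology structure, and no realistic
interaction-network topology. Passing the recovery benchmark shows the
architecture, objective and training loop can extract a planted
pairwise signal end to end; it says nothing about accuracy on real
proteome-scale corpora.

Benchmark scales used by the test suite: the recovery experiment uses
500 proteins, 32 dimensions, 20,000 pairs and a hidden size of 64,
which trains in a few minutes on one CPU and reaches ≥ 95% held-out
accuracy; the capacity (memorization) check uses 512 random pairs.

## Validation statistics

* **Chi-square** of independence on the 2×2 predicted-vs-actual table:
  χ² = Σ(O−E)²/E with margin-derived expected counts, df = 1. For a
  2×2 table Cramér's V, the φ coefficient and Cohen's w coincide at
  √(χ²/n) and are all reported. Yates continuity correction is off by
  default (flag available); a zero margin is an error.
* **Wilcoxon signed-rank**, exact: zero differences dropped, average
  ranks for ties, and the null distribution of W⁺ computed by exact
  convolution of per-rank two-point distributions on a half-rank
  integer grid (no normal approximation at any n; the doubled grid
  makes tied average ranks exact too). One-sided p is the upper tail
  P(W⁺ ≥ W). For n = 44 with all differences positive this gives
  W = 990 and p = 2⁻⁴⁴ ≈ 5.68×10⁻¹⁴.

## Numerical and implementation notes

* The network runs on a small reverse-mode autodiff tape over float64
  numpy arrays; gradients are verified against central finite
  differences in the test suite (the only deliberate exception is the
  binding-target stop-gradient).
* GELU is the exact erf form, softmax is max-shifted, sigmoid uses the
  tanh identity; attention scores scale by 1/√d_k.
* Linear layers use Glorot-uniform init; LayerNorm ε = 1e-5; the
  uncertainty cap is a clip whose gradient vanishes beyond u_max.
* Checkpoints are an `.npz` parameter archive plus a JSON config
  manifest; histories are CSV.

## Limitations

* Reported benchmark accuracies are for synthetic planted rules; they
  do not transfer to real PPI corpora, which require the external
  embedding model and large-scale training.
* Pair-level splitting shares proteins across partitions (see above).
* The uncertainty head is a ranking signal, not a calibrated
  probability; no post-hoc calibration is included.
* Task weights λ are not learned; only fixed values are supported.
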