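# Methods

## Problem and model

`milbind` models in-vivo protein–DNA binding as weakly supervised binary
classification of fixed-length DNA sequences. A ChIP-seq peak sequence
is *bound* (label 1) if the assayed transcription factor binds somewhere
inside it; the binding site itself — possibly several sites — is not
annotated. This is the classical multiple-instance learning (MIL)
setting: the sequence is a *bag*, its overlapping windows are
*instances*, the bag label is observed and the instance labels are
latent.

The pipeline has three stages.

**Data processing.** A sequence of length *l* is cut by a sliding
window of length *c* and stride *s* into
*n* = ⌈(*l* − *c*)/*s*⌉ + 1 instances; when (*l* − *c*) is not a
multiple of *s* the sequence is first padded at its 3′ end with the
character `0`. Each instance is encoded with *k*-mer one-hot channels:
position *i* of the instance activates the channel of the *k*-mer
starting at *i*, with channels ordered lexicographically (A<C<G<T), so
an instance becomes a binary 4ᵏ × (*c* − *k* + 1) matrix and a bag the
tensor 4ᵏ × *n* × (*c* − *k* + 1). Ordinary one-hot encoding is the
*k* = 1 special case; *k* = 2, 3 capture di-/trinucleotide dependencies
(at a 4ᵏ⁻¹-fold cost in first-layer parameters, hence the warning for
*k* > 3). A window that touches an ambiguous base (N) or the `0` pad
is encoded as an all-zero column — the natural extension of the
zero-padding semantics that keeps the channel count at 4ᵏ. No
reverse-complement augmentation is applied; only the forward strand is
encoded.

**Instance scoring.** Every instance of a bag is scored by one shared
network (convolution and pooling act along the width axis only, so no
information crosses instances before fusion):

    conv(16 kernels, 1×24) → ReLU → max-pool(1×8) → dropout
    → bidirectional LSTM (32 units/direction) → dropout → softmax(2)

The BiLSTM consumes the pooled width axis as its time axis and is read
out as the concatenation of the two directions' final hidden states
(64 features) — the standard bidirectional read-out; no fully connected
layer sits between the recurrent layer and the softmax. Weights use
Glorot-uniform initialisation; LSTM forget-gate biases start at 1
(standard practice to keep the cell memory open early). Three baseline
architectures are provided for comparison: a DeepBind-like model
(single instance, global max-pool → FC(32) → dropout → softmax), a
DanQ-like model (single instance, same conv-BiLSTM stack) and a
WSCNN-like model (MIL bag, global max-pool → FC(32) → dropout →
softmax per instance, then fusion).

**Fusion.** The per-instance probability matrix (*n* × 2) collapses to
one bag distribution. The default is Noisy-and with slope *a* = 7.5:

    P_i = [σ(a(p̄_i − b_i)) − σ(−a b_i)] / [σ(a(1 − b_i)) − σ(−a b_i)]

where p̄ᵢ is the mean instance probability of class *i* and *b*ᵢ a
learned soft threshold. The subtraction and denominator normalise
*P*ᵢ to [0, 1] for *b*ᵢ ∈ [0, 1], *a* > 0, and the function is strictly
increasing in p̄ with fixed points at 0 and 1: the bag activates once
the *fraction* of positive-looking instances passes the threshold,
rather than on a single maximal window. `max` and `average` fusion are
available as alternatives. Numerical choices: *b* is stored as an
unconstrained parameter squashed through a logistic sigmoid (so the
[0, 1] constraint can never be violated during optimisation),
initialised at the uninformative midpoint 0.5 and excluded from weight
decay; an ε = 1e-8 guards the denominator at degenerate endpoints; the
two per-class fused values are renormalised to a simplex before the
cross-entropy loss, since the Noisy-and transform is applied per class.

## Training protocol

Bag-level two-class cross-entropy, optimised with AdaDelta (learning
rate 1, running-average momentum ρ, conditioning constant δ),
mini-batches of 300 bags, 60 epochs, L2 weight decay 5e-4 on all
weights except biases and the fusion thresholds. After every epoch the
bag-level accuracy on a held-out validation set (a stratified 1/8 of
the training data) is recorded and the parameters of the best epoch are
kept (earliest epoch wins ties — determinism). The sensitive
hyper-parameters are grid-searched by validation accuracy over
dropout ∈ {0.75, 0.5, 0.1} × ρ ∈ {0.999, 0.99, 0.9} ×
δ ∈ {1e-4, 1e-6, 1e-8} (27 fits; earliest tuple wins ties). Evaluation
uses stratified three-fold cross-validation (stratification is our
choice — with 1–3× class imbalance, unstratified small folds are
unstable) reporting ROC AUC, PR AUC (average precision) and F1 at the
argmax decision rule.

**Desk profile.** `TrainConfig.desk()` is the laptop/CI-scale preset:
20 epochs, mini-batches of 10 bags, and the hyper-parameter grid
collapsed to a single point — dropout 0.5, ρ = 0.999, δ = 1e-6. That
point was fixed once by running the full protocol's 27-point grid
search (selection by validation accuracy) on a reference synthetic
dataset generated with a seed disjoint from any evaluation seed; the
search also shows why a collapsed point must be chosen with care, as a
few grid corners (e.g. ρ = 0.999 with δ = 1e-4, or ρ = 0.9 with
δ = 1e-8) stall at the majority-class solution within 20 epochs. The
batch-size reduction preserves the *update count* of the full protocol
rather than its batch size: the 300-bag batch was sized for datasets of
tens of thousands of sequences (~150 updates/epoch); on desk-scale
datasets of ~10³ bags it would yield ~3 updates per epoch, far too few
for AdaDelta to adapt. Batch 10 restores roughly a hundred updates per
epoch.

All randomness flows from a single integer seed, fanned out to data
generation, splitting, initialisation, shuffling and dropout streams.

## The neural-network engine

The scorer and fusion layers run on `milbind.nn`, a compact
reverse-mode automatic-differentiation engine over single-precision
NumPy arrays. It provides exactly the primitives the architectures
need — broadcasting arithmetic, matmul, valid cross-correlation
(einsum over a strided window view), non-overlapping max-pooling
(right-edge remainder dropped, as only the pool *size* is part of the
design), stable log-softmax, inverted dropout, Glorot initialisation
and AdaDelta. Gradients of every primitive are verified against central
differences in the test suite, and the composed model against a
numeric gradient check. Pooling/ReLU tie-breaking: max-pool routes the
gradient to the (first) argmax; the max reduction used by max-fusion
splits ties evenly.

## Synthetic data

`milbind.synthdata` generates datasets with the statistical structure
the method assumes, so the whole pipeline is testable without any
download. Positives carry 1–3 (configurable) motif occurrences drawn
column-wise from a PWM and implanted at uniformly sampled
non-overlapping positions in an i.i.d. background with
P(G) = P(C) = gc/2; negatives are background-only draws from the same
law, so length and GC content are matched *by construction* (a
dinucleotide-shuffle mode is available when a more conservative
negative set is wanted). Defaults: *l* = 200 bp, GC 0.5, negatives 2×
positives (the typical 1–3× imbalance of ChIP-seq negative sets), and
a bundled 12-column synthetic PWM whose columns put probability 0.85 on
the consensus base — a high-information motif comparable to a good
JASPAR entry. A truth table records every implant position, enabling
instance-level oracles (e.g. verifying that some window fully contains
an occurrence).

What the generator does *not* emulate: genomic repeat structure,
read-level ChIP-seq noise, positional bias of sites within peaks, and
co-occurring cofactor motifs. Passing the synthetic parameter-recovery
test therefore shows that the estimator recovers planted signal under
the model's own assumptions — not that it matches published performance
on ENCODE data, which is out of scope here.

## Problem sizes and reproducibility

The bundled experiments run at desk scale: parameter recovery uses
n_pos = 500 (1500 bags), a stratified 2/3–1/3 train/test split and the
desk profile, averaged over three seeds; the fusion/architecture
ablations use n_pos = 300 with occurrence counts in {2, 3}
(multi-occurrence positives are where Noisy-and's assumption — a bag is
positive once *enough* instances are positive — should pay off). At
this scale the ablation differences are stochastic: the orderings
(Noisy-and ≥ Max/Average, WSCNNLSTM ≥ WSCNN-like) are checked as
warning-level properties, not hard assertions.
`scripts/acceptance.py` re-runs both experiments end-to-end from a
single seed and writes the measured metrics as JSON.

## Known limitations

* Single-CPU NumPy training: practical up to ~10³–10⁴ bags; the full
  published protocol (60 epochs, 27-point grid, ~5×10⁴ sequences) is
  supported in configuration but not desk-practical.
* Forward strand only; no reverse-complement pooling.
* Fixed-length bags within a batch (the protocol uses fixed *l*,
  *c*, *s*).
* The BiLSTM read-out (final states of both directions) is one of
  several defensible conventions; it is isolated behind the model
  specification so alternatives can be tested.
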