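# milbind

Weakly supervised multiple-instance learning for in-vivo protein–DNA
binding prediction.

ChIP-seq tells you *that* a transcription factor binds somewhere in a
~200 bp peak sequence, not *where* — and a bound sequence may contain
several binding sites. `milbind` treats each sequence as a bag of
overlapping windows (instances), scores every window with one shared
CNN→BiLSTM network, and fuses the window probabilities into a bag-level
binding probability with the Noisy-and function. It is aimed at
computational biologists who want a transparent, dependency-light
NumPy implementation of this weakly supervised architecture (called
`WSCNNLSTM` here), together with its classical baselines, an evaluation
protocol, and a synthetic-data generator for controlled experiments.

## The model

A sequence of length *l* is segmented by a window of length *c* and
stride *s* into *n* = ⌈(*l* − *c*)/*s*⌉ + 1 instances (`0`-padded at
the 3′ end if needed). Each instance is *k*-mer one-hot encoded — the
window of *k* adjacent bases at position *i* activates one of 4ᵏ
channels, lexicographically ordered (AA → channel 0, …, TT →
channel 15 for *k* = 2) — giving a bag tensor of shape
4ᵏ × *n* × (*c* − *k* + 1). One-hot encoding is the *k* = 1 case.

Each instance is scored by a shared network — convolution (16 kernels,
1×24) → ReLU → max-pool (1×8) → dropout → BiLSTM (32 units per
direction, 64 output features) → dropout → 2-class softmax — and the
*n* instance probabilities are fused per class *i* by Noisy-and,

$$P_i = \frac{\sigma(a(\bar p_i - b_i)) - \sigma(-a b_i)}
             {\sigma(a(1 - b_i)) - \sigma(-a b_i)},\qquad
  \bar p_i = \tfrac1n \sum_j p_{i,j},$$

with fixed slope *a* = 7.5 and a learned soft threshold
*b*ᵢ ∈ [0, 1]: the bag activates once the *mean* instance probability
passes the threshold. `max` and `average` fusion, and three baseline
architectures (DeepBind-like, DanQ-like, WSCNN-like) are included.
Training follows the published protocol: AdaDelta (lr 1), weight decay
5e-4, best-validation-accuracy checkpointing, grid search over dropout
× AdaDelta momentum × delta, three-fold stratified cross-validation,
ROC AUC / PR AUC / F1 metrics. The networks run on a small
reverse-mode autodiff engine over NumPy (`milbind.nn`) — no
deep-learning framework required.

## Worked example

Generate a synthetic dataset (positives with 1–3 implanted occurrences
of the bundled 12-bp motif, GC-matched negatives at 2× imbalance),
train the weakly supervised model under the desk profile, and evaluate:

```python
import numpy as np
from sklearn.model_selection import train_test_split
from milbind import (BagLayout, BagClassifier, FusionParams, ModelSpec,
                     SyntheticSpec, generate_dataset, evaluate)
from milbind.train_eval import TrainConfig, encode_for, train

seqs, truth = generate_dataset(SyntheticSpec(n_pos=500, neg_ratio=2.0, seed=0))
layout = BagLayout(l=200, c=120, s=10, k=1)   # 9 windows per bag
config = TrainConfig.desk(seed=0)             # 20 epochs, batch 10
spec = ModelSpec.for_variant("WSCNNLSTM", dropout_ratio=config.dropout_grid[0])

bags, labels, _ = encode_for(spec, layout, seqs)   # (1500, 4, 9, 120)
idx = np.arange(len(labels))
tr, te = train_test_split(idx, test_size=1/3, stratify=labels, random_state=0)
fit, val = train_test_split(tr, test_size=1/8, stratify=labels[tr], random_state=0)

model = BagClassifier(spec, layout, FusionParams(method="noisy_and"),
                      rng=np.random.default_rng(0))
result = train(model, bags[fit], labels[fit], bags[val], labels[val], config)
print(evaluate(model, bags[te], labels[te]))
```

```
{'roc_auc': 0.9788531046016076, 'pr_auc': 0.9673141930538013, 'f1': 0.9226190476190477}
```

ROC AUC 0.98 means the fused bag probability ranks a random bound
sequence above a random unbound one 98% of the time — the model has
recovered the implanted motif from bag labels alone. The same pipeline
is available from the shell:

```bash
milbind generate --out data/ --n-pos 500 --neg-ratio 2 --seed 0
milbind cv --fasta data/dataset.fasta --out runs/cv \
           --variant WSCNNLSTM --fusion noisy_and --profile desk --seed 0
milbind compare --fasta data/dataset.fasta --out runs/cmp \
                --variants WSCNNLSTM,WSCNN_LIKE --profile desk --seed 0
```

`cv` writes per-fold ROC AUC / PR AUC / F1 plus a mean row as TSV, and
every command snapshots its fully resolved configuration to YAML so a
run can be reproduced exactly.

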