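import numpy as np
import pytest

from milbind import BagLayout, ModelSpec, Sequence, SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def paper_layout():
    """The published segmentation geometry: 200 bp sequences, 120 bp
    windows, stride 10."""
    return BagLayout(l=200, c=120, s=10, k=1)


@pytest.fixture
def small_layout():
    """A miniature geometry for fast network tests."""
    return BagLayout(l=40, c=20, s=10, k=1)


@pytest.fixture
def small_spec():
    """A scaled-down WSCNNLSTM that fits the miniature geometry."""
    return ModelSpec(variant="WSCNNLSTM", conv_width=6, pool_width=2,
                     dropout_ratio=0.25)


@pytest.fixture
def tiny_dataset():
    """60 short labelled sequences with implanted motifs (40 bp)."""
    spec = SyntheticSpec(l=40, n_pos=20, neg_ratio=2.0, seed=7,
                         occurrences=(1, 2))
    return generate_dataset(spec)


@pytest.fixture
def random_sequences(rng):
    """Clean random ACGT sequences of mixed lengths."""
    def make(n=20, length=30):
        return [
            Sequence(f"s{i}", "".join(rng.choice(list("ACGT"), size=length)),
                     label=int(rng.integers(0, 2)))
            for i in range(n)
        ]
    return make
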