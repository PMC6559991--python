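"""Segmentation of DNA sequences into overlapping instances and k-mer
one-hot encoding of the resulting multiple-instance bags.

A labelled sequence of length *l* is cut by a sliding window of length
*c* and stride *s* into n = ceil((l-c)/s) + 1 instances; if (l-c) is not
a multiple of *s* the sequence is first padded at its 3' end with the
character '0'.  Each instance is encoded as a binary matrix with 4**k
channels — one per k-mer in lexicographic A<C<G<T order — and width
c-k+1; stacking the n instance matrices gives the bag tensor of shape
(4**k, n, c-k+1).  Ordinary one-hot encoding is the k=1 special case.

Windows containing any character outside {A, C, G, T} (ambiguous bases
such as N, or the pad character '0') are encoded as an all-zero column.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

ALPHABET = "ACGT"
PAD_CHAR = "0"
#: Sentinel returned by :func:`kmer_index` for windows containing a
#: character outside the ACGT alphabet ("no channel").
NO_CHANNEL = -1

_BASE_RANK = {b: i for i, b in enumerate(ALPHABET)}


class LayoutError(ValueError):
    """Raised for inconsistent segmentation/encoding geometry."""


@dataclass(frozen=True)
class Sequence:
    """A DNA sequence with an optional binary bound/non-bound label."""

    seq_id: str
    bases: str
    label: int | None = None

    def __post_init__(self):
        if len(self.bases) == 0:
            raise ValueError(f"sequence {self.seq_id!r} is empty")
        object.__setattr__(self, "bases", self.bases.upper())
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class BagLayout:
    """Geometry of one bag: window length ``c``, stride ``s``, k-mer
    order ``k`` and the sequence length ``l`` the layout applies to."""

    l: int
    c: int
    s: int
    k: int = 1

    def __post_init__(self):
        if not 1 <= self.c <= self.padded_length:
            raise LayoutError(f"window c={self.c} invalid for l={self.l}")
        if self.c > self.l:
            raise LayoutError(f"window c={self.c} exceeds sequence l={self.l}")
        if self.s < 1:
            raise LayoutError(f"stride must be >= 1, got {self.s}")
        if self.k < 1:
            raise LayoutError(f"k must be >= 1, got {self.k}")
        if self.k > self.c:
            raise LayoutError(f"k={self.k} exceeds window length c={self.c}")
        if self.k > 3:
            warnings.warn(
                f"k={self.k}: channel count 4**k = {4 ** self.k}; learnable "
                "parameters in the first convolutional layer grow "
                "exponentially with k",
                stacklevel=2,
            )

    @property
    def n_instances(self) -> int:
        """n = ceil((l-c)/s) + 1."""
        return math.ceil((self.l - self.c) / self.s) + 1

    @property
    def padded_length(self) -> int:
        """Smallest l' >= l with (l'-c) a multiple of s."""
        remainder = (self.l - self.c) % self.s
        return self.l if remainder == 0 else self.l + self.s - remainder

    @property
    def n_channels(self) -> int:
        return 4 ** self.k

    @property
    def instance_width(self) -> int:
        """Width of the encoded instance matrix, c-k+1."""
        return self.c - self.k + 1

    @property
    def tensor_shape(self) -> tuple[int, int, int]:
        return (self.n_channels, self.n_instances, self.instance_width)

    def single_instance(self) -> "BagLayout":
        """The degenerate layout treating the whole sequence as one
        instance (single-instance learning)."""
        return replace(self, c=self.l, s=self.l)


@dataclass
class EncodedBag:
    """A bag as a dense (4**k, n, c-k+1) binary tensor plus its label."""

    tensor: np.ndarray
    label: int | None = None
    seq_id: str = ""

    def __post_init__(self):
        if self.tensor.ndim != 3:
            raise ValueError("bag tensor must be 3-dimensional")


def pad_sequence(seq: Sequence, c: int, s: int) -> Sequence:
    """Pad '0' at the 3' end until (l'-c) is a multiple of s."""
    if c > len(seq):
        raise LayoutError(
            f"window c={c} exceeds sequence length {len(seq)}"
        )
    layout = BagLayout(l=len(seq), c=c, s=s)
    extra = layout.padded_length - len(seq)
    if extra == 0:
        return seq
    return Sequence(seq.seq_id, seq.bases + PAD_CHAR * extra, seq.label)


def segment(seq: Sequence, layout: BagLayout) -> list[str]:
    """Cut a (padded) sequence into its n overlapping instances.

    Instance j spans [j*s, j*s + c); consecutive instances overlap by
    c - s bases.
    """
    if len(seq) != layout.padded_length:
        raise LayoutError(
            f"sequence length {len(seq)} does not match padded layout "
            f"length {layout.padded_length}; call pad_sequence first"
        )
    n = layout.n_instances
    return [seq.bases[j * layout.s: j * layout.s + layout.c]
            for j in range(n)]


def kmer_index(word: str) -> int:
    """Lexicographic index of a k-mer with A<C<G<T (AA -> 0, TT -> 15
    for k=2); ``NO_CHANNEL`` for words containing N, pad or any other
    non-ACGT character."""
    idx = 0
    for ch in word.upper():
        rank = _BASE_RANK.get(ch)
        if rank is None:
            return NO_CHANNEL
        idx = idx * 4 + rank
    return idx


def encode_instance(instance: str, k: int) -> np.ndarray:
    """Encode one window as a binary (4**k, c-k+1) matrix.

    Column i carries a single 1 in the row of the k-mer starting at
    position i, or is all-zero when that window touches an ambiguous or
    pad character.
    """
    c = len(instance)
    if c < k:
        raise LayoutError(f"instance length {c} shorter than k={k}")
    width = c - k + 1
    mat = np.zeros((4 ** k, width), dtype=np.float32)
    instance = instance.upper()
    for i in range(width):
        idx = kmer_index(instance[i: i + k])
        if idx != NO_CHANNEL:
            mat[idx, i] = 1.0
    return mat


def encode_bag(seq: Sequence, layout: BagLayout) -> EncodedBag:
    """Segment and encode one sequence into its bag tensor."""
    padded = pad_sequence(seq, layout.c, layout.s)
    instances = segment(padded, layout)
    tensor = np.stack(
        [encode_instance(inst, layout.k) for inst in instances], axis=1
    )
    return EncodedBag(tensor=tensor, label=seq.label, seq_id=seq.seq_id)


def encode_dataset(seqs: list[Sequence], layout: BagLayout
                   ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Encode equal-length sequences into a stacked (B, 4**k, n, w)
    array plus the label vector and sequence ids."""
    bags = [encode_bag(s, layout) for s in seqs]
    tensors = np.stack([b.tensor for b in bags])
    labels = np.array(
        [-1 if b.label is None else b.label for b in bags], dtype=np.int64
    )
    ids = [b.seq_id for b in bags]
    return tensors, labels, ids


def decode_instance(matrix: np.ndarray, k: int) -> str:
    """Reconstruct the window string from a clean one-hot k-mer matrix
    (inverse of :func:`encode_instance` on N/pad-free input)."""
    kmers = ["".join(p) for p in _product_acgt(k)]
    chars: list[str] = []
    width = matrix.shape[1]
    for i in range(width):
        col = matrix[:, i]
        (rows,) = np.nonzero(col)
        if len(rows) != 1:
            raise ValueError(f"column {i} is not one-hot")
        word = kmers[rows[0]]
        chars.append(word[0] if i < width - 1 else word)
    return "".join(chars)


def _product_acgt(k: int):
    if k == 1:
        yield from ((b,) for b in ALPHABET)
    else:
        for head in _product_acgt(k - 1):
            for b in ALPHABET:
                yield head + (b,)
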