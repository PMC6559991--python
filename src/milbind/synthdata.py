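"""Synthetic ChIP-seq-like datasets for end-to-end testing.

Positive sequences carry one or more motif occurrences drawn from a
position weight matrix and implanted at non-overlapping positions in an
i.i.d. background; negatives are background-only sequences drawn from
the same length and GC composition, so the classes are matched by
construction.  The negative:positive ratio defaults to 2 (the typical
1-3x imbalance of ChIP-seq negative sets).  A truth table records every
implant position so instance-level oracles can be built downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .bagcode import ALPHABET, Sequence

DEFAULT_OCCURRENCES = (1, 2, 3)
_MAX_PLACEMENT_TRIES = 1000


@dataclass
class SyntheticSpec:
    """Generator settings: sequence length, motif PWM, per-positive
    occurrence counts, background GC fraction and class balance."""

    l: int = 200
    pwm: np.ndarray | None = None          # (4, w), columns on the simplex
    occurrences: tuple[int, ...] = DEFAULT_OCCURRENCES
    gc: float = 0.5
    n_pos: int = 100
    neg_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.pwm is None:
            self.pwm = example_pwm()
        self.pwm = np.asarray(self.pwm, dtype=np.float64)
        if self.pwm.shape[0] != 4:
            raise ValueError("PWM must have 4 rows (A, C, G, T)")
        if not np.allclose(self.pwm.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must each sum to 1")
        if not 0.0 < self.gc < 1.0:
            raise ValueError(f"gc must lie in (0, 1), got {self.gc}")
        if min(self.occurrences) < 1:
            raise ValueError("every positive needs at least one occurrence")
        if not 1.0 <= self.neg_ratio <= 3.0:
            raise ValueError(
                f"neg_ratio should lie in [1, 3], got {self.neg_ratio}"
            )
        if max(self.occurrences) * self.pwm.shape[1] > self.l:
            raise ValueError("occurrences x motif width exceed sequence length")

    @property
    def motif_width(self) -> int:
        return self.pwm.shape[1]

    @property
    def n_neg(self) -> int:
        return int(round(self.n_pos * self.neg_ratio))


def example_pwm() -> np.ndarray:
    """The bundled 12-column example PWM (high-information,
    consensus-like; a synthetic motif, not a database entry)."""
    path = resources.files("milbind").joinpath("data/example_pwm.meme")
    with resources.as_file(path) as p:
        return read_meme_pwm(p)


def read_meme_pwm(path) -> np.ndarray:
    """Read the first motif of a MEME minimal-format file as a (4, w)
    matrix (MEME rows are positions, ours are bases)."""
    rows = []
    in_matrix = False
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line.startswith("letter-probability matrix"):
                in_matrix = True
                continue
            if in_matrix:
                parts = line.split()
                if len(parts) != 4:
                    break
                rows.append([float(x) for x in parts])
    if not rows:
        raise ValueError(f"no letter-probability matrix found in {path}")
    return np.array(rows).T


def read_pwm_tsv(path) -> np.ndarray:
    """Read a plain-matrix PWM: 4 rows (A, C, G, T) x w columns."""
    mat = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    if mat.shape[0] != 4:
        raise ValueError("PWM TSV must have exactly 4 rows")
    return mat


def sample_background(l: int, gc: float, rng: np.random.Generator) -> str:
    """An i.i.d. background sequence with P(G)=P(C)=gc/2 and
    P(A)=P(T)=(1-gc)/2."""
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must lie in the open interval (0, 1), got {gc}")
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]  # A, C, G, T
    idx = rng.choice(4, size=l, p=probs)
    return "".join(ALPHABET[i] for i in idx)


def sample_motif(pwm: np.ndarray, rng: np.random.Generator) -> str:
    """One motif realisation, drawing each position from its PWM column."""
    bases = [rng.choice(list(ALPHABET), p=pwm[:, j])
             for j in range(pwm.shape[1])]
    return "".join(bases)


def implant(seq: str, pwm: np.ndarray, count: int,
            rng: np.random.Generator) -> tuple[str, list[int]]:
    """Implant ``count`` non-overlapping motif occurrences at uniformly
    sampled positions; returns the new sequence and the sorted start
    positions (0-based)."""
    w = pwm.shape[1]
    l = len(seq)
    if count * w > l:
        raise ValueError(f"cannot place {count} motifs of width {w} in {l} bp")
    if count == 0:
        return seq, []
    positions: list[int] = []
    for _ in range(_MAX_PLACEMENT_TRIES):
        pos = int(rng.integers(0, l - w + 1))
        if all(abs(pos - p) >= w for p in positions):
            positions.append(pos)
            if len(positions) == count:
                break
    else:
        raise RuntimeError(
            f"failed to place {count} non-overlapping motifs of width {w} "
            f"in {l} bp after {_MAX_PLACEMENT_TRIES} tries"
        )
    chars = list(seq)
    for pos in positions:
        chars[pos: pos + w] = sample_motif(pwm, rng)
    return "".join(chars), sorted(positions)


def generate_dataset(spec: SyntheticSpec
                     ) -> tuple[list[Sequence], pd.DataFrame]:
    """Labelled sequences plus a truth table of implant positions.

    Positives are named pos_0000..., negatives neg_0000...; the truth
    table has one row per sequence with comma-separated implant starts
    (empty for negatives).
    """
    rng = np.random.default_rng(spec.seed)
    seqs: list[Sequence] = []
    rows = []
    for i in range(spec.n_pos):
        count = int(rng.choice(spec.occurrences))
        bases, positions = implant(
            sample_background(spec.l, spec.gc, rng), spec.pwm, count, rng)
        sid = f"pos_{i:04d}"
        seqs.append(Sequence(sid, bases, label=1))
        rows.append({"seq_id": sid, "label": 1,
                     "implant_positions": ",".join(map(str, positions))})
    for i in range(spec.n_neg):
        sid = f"neg_{i:04d}"
        seqs.append(Sequence(sid, sample_background(spec.l, spec.gc, rng),
                             label=0))
        rows.append({"seq_id": sid, "label": 0, "implant_positions": ""})
    return seqs, pd.DataFrame(rows)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide composition
    (Altschul-Erickson style edge shuffling on the transition multigraph);
    an optional, more conservative negative-construction mode."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # shuffle each adjacency list, keeping one edge into the terminal
    # vertex reachable (retry until an Eulerian walk completes)
    for _ in range(100):
        trial = {a: list(bs) for a, bs in edges.items()}
        for bs in trial.values():
            rng.shuffle(bs)
        out = [seq[0]]
        cur = seq[0]
        ok = True
        for _ in range(len(seq) - 1):
            if not trial.get(cur):
                ok = False
                break
            cur = trial[cur].pop(0)
            out.append(cur)
        if ok and out[-1] == last:
            return "".join(out)
    return seq  # fall back to the original on repeated failure
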