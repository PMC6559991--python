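"""Dataset and report I/O: labelled FASTA, truth tables, encoded-bag
caches and YAML run configuration."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bagcode import Sequence


def write_fasta(seqs: list[Sequence], path: str | Path) -> None:
    """Write sequences with the binary label carried in the description
    line as ``label=0|1``."""
    records = []
    for s in seqs:
        desc = "" if s.label is None else f"label={s.label}"
        records.append(SeqRecord(Seq(s.bases), id=s.seq_id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read sequences, recovering labels from ``label=`` description
    tags when present."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = None
        for token in rec.description.split():
            if token.startswith("label="):
                label = int(token.split("=", 1)[1])
        out.append(Sequence(rec.id, str(rec.seq), label=label))
    return out


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       dtype={"implant_positions": str})


def save_encoded(path: str | Path, tensors: np.ndarray, labels: np.ndarray,
                 seq_ids: list[str]) -> None:
    """Cache encoded bags in an HDF5 container with datasets ``tensor``,
    ``label`` and ``seq_id``."""
    with h5py.File(path, "w") as f:
        f.create_dataset("tensor", data=tensors, compression="gzip")
        f.create_dataset("label", data=labels)
        f.create_dataset(
            "seq_id", data=np.array(seq_ids, dtype=h5py.string_dtype()))


def load_encoded(path: str | Path
                 ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    with h5py.File(path, "r") as f:
        tensors = f["tensor"][:]
        labels = f["label"][:]
        seq_ids = [s.decode() for s in f["seq_id"][:]]
    return tensors, labels, seq_ids


def write_config(config: dict, path: str | Path) -> None:
    """Snapshot a fully resolved run configuration for reproducibility."""
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}
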