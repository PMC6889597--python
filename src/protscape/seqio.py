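"""FASTA input/output (thin wrappers over Biopython, gzip-aware)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta"]


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly gzipped) multi-record FASTA into ``{name: sequence}``."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")
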