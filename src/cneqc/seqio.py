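"""FASTA-backed sequence records.

Sequences preserve case: lowercase bases mark soft-masked (repeat-annotated)
positions and count as real nucleotides everywhere except
:func:`cneqc.assembly.masked_fraction`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = ["SeqRecord", "parse_fasta", "write_fasta", "reverse_complement"]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence over {A,C,G,T,N}, case preserved."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def parse_fasta(path: str | Path) -> list[SeqRecord]:
    """Read FASTA into records in file order, case preserved.

    Raises ``ValueError`` on duplicate ids (naming the id) and on files
    containing no records.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    bio = [_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)
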