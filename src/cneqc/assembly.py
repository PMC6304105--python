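"""Assembly summary statistics: gap runs, contigs, N(x) values, masked fraction.

An *assembly gap* is a maximal run of >= ``min_run`` ambiguous bases (N/n)
inside a scaffold (default 25, the convention used throughout); *contigs*
are the gap-free pieces obtained by splitting scaffolds at those runs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .intervals import Interval, IntervalSet
from .seqio import SeqRecord

__all__ = [
    "find_gaps",
    "split_into_contigs",
    "nx_value",
    "nx_curve",
    "masked_fraction",
    "AssemblyReport",
    "summarize_assembly",
]


def find_gaps(assembly: Iterable[SeqRecord], min_run: int = 25) -> IntervalSet:
    """Maximal runs of N/n of length >= ``min_run``, as intervals.

    Runs shorter than ``min_run`` are not reported.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    pattern = re.compile(f"[Nn]{{{min_run},}}")
    gaps = [
        Interval(rec.id, m.start(), m.end())
        for rec in assembly
        for m in pattern.finditer(rec.sequence)
    ]
    return IntervalSet(gaps)


def split_into_contigs(assembly: Iterable[SeqRecord], min_run: int = 25) -> list[int]:
    """Contig lengths after splitting each scaffold at its gap runs.

    Zero-length pieces (leading/trailing/adjacent gaps) are discarded, so
    ``sum(contigs) == total_bases - gap_bases``.
    """
    pattern = re.compile(f"[Nn]{{{min_run},}}")
    lengths: list[int] = []
    for rec in assembly:
        for piece in pattern.split(rec.sequence):
            if piece:
                lengths.append(len(piece))
    return lengths


def nx_value(lengths: Sequence[int], x: int) -> int:
    """N(x): the largest length L such that sequences >= L together cover at
    least x% of the total.

    Computed by descending sort and cumulative sum with exact integer
    arithmetic (``100 * cumsum >= x * total``) so percentage ties at the
    boundary are reproducible.
    """
    if not lengths:
        raise ValueError("nx_value requires a non-empty set of lengths")
    if not (1 <= x <= 99):
        raise ValueError("x must be in 1..99")
    total = sum(lengths)
    cum = 0
    for length in sorted(lengths, reverse=True):
        cum += length
        if 100 * cum >= x * total:
            return length
    return min(lengths)  # unreachable: cum == total satisfies any x <= 99


def nx_curve(lengths: Sequence[int]) -> list[tuple[int, int]]:
    """The full N(x) series for x = 1..99; non-increasing in x."""
    if not lengths:
        raise ValueError("nx_curve requires a non-empty set of lengths")
    desc = sorted(lengths, reverse=True)
    total = sum(desc)
    curve: list[tuple[int, int]] = []
    cum = 0
    i = 0
    for x in range(1, 100):
        while 100 * cum < x * total:
            cum += desc[i]
            i += 1
        curve.append((x, desc[i - 1]))
    return curve


def masked_fraction(assembly: Iterable[SeqRecord]) -> float:
    """Fraction of soft-masked (lowercase) bases; N bases count in the
    denominator only."""
    lower = total = 0
    for rec in assembly:
        total += len(rec.sequence)
        lower += sum(c.islower() for c in rec.sequence)
    if total == 0:
        raise ValueError("empty assembly")
    return lower / total


@dataclass
class AssemblyReport:
    total_bases: int
    gap_bases: int
    n_scaffolds: int
    n_contigs: int
    scaffold_nx: dict[int, int] = field(repr=False)
    contig_nx: dict[int, int] = field(repr=False)
    masked_fraction: float = 0.0

    @property
    def scaffold_n50(self) -> int:
        return self.scaffold_nx[50]

    @property
    def contig_n50(self) -> int:
        return self.contig_nx[50]


def summarize_assembly(assembly: Sequence[SeqRecord], min_run: int = 25) -> AssemblyReport:
    scaffold_lengths = [len(r) for r in assembly]
    gaps = find_gaps(assembly, min_run)
    contigs = split_into_contigs(assembly, min_run)
    return AssemblyReport(
        total_bases=sum(scaffold_lengths),
        gap_bases=sum(len(g) for g in gaps),
        n_scaffolds=len(assembly),
        n_contigs=len(contigs),
        scaffold_nx=dict(nx_curve(scaffold_lengths)),
        contig_nx=dict(nx_curve(contigs)) if contigs else {x: 0 for x in range(1, 100)},
        masked_fraction=masked_fraction(assembly),
    )
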