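"""Alignment I/O and quality measures.

Covers three alignment currencies:

* **PAF** element-to-assembly hits (``cg`` cigar tag) — the unit of the
  completeness and synteny statistics;
* **MAF** reference-anchored multiple-alignment blocks — the source of
  per-species identity windows;
* plain **aligned column pairs** ``(query_char, target_char)`` — used by the
  entropy quality filter and the pairwise difference summary.

A built-in exact-seed, ungapped-extension mapper (:func:`map_elements`)
produces hits for desk-scale fixtures without an external aligner.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .intervals import Interval
from .seqio import SeqRecord, reverse_complement

__all__ = [
    "AlignmentHit",
    "hit_identity",
    "hit_coverage",
    "parse_paf",
    "write_paf",
    "MafRow",
    "MafBlock",
    "parse_maf",
    "write_maf",
    "column_pairs",
    "shannon_entropy",
    "passes_entropy_quality",
    "ColumnPairStats",
    "summarize_differences",
    "map_elements",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = frozenset("M=XI")
_TARGET_OPS = frozenset("M=XD")


# ---------------------------------------------------------------------------
# Pairwise hits (PAF)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentHit:
    """One element-to-assembly alignment.

    Gap fields follow the row the gap character sits in: ``query_gap_bases``
    counts target bases absent from the query (cigar ``D``, a gap in the
    query row) and ``target_gap_bases`` counts query bases absent from the
    target (cigar ``I``).
    """

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    target: Interval
    target_len: int
    matches: int
    mismatches: int
    query_gap_bases: int = 0
    target_gap_bases: int = 0
    cigar: str | None = None

    def __post_init__(self) -> None:
        if self.query_len <= 0:
            raise ValueError(f"hit {self.query_id}: zero-length query")
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError(f"hit {self.query_id}: bad query span")
        aligned = self.query_end - self.query_start
        if self.matches + self.mismatches + self.target_gap_bases != aligned:
            raise ValueError(
                f"hit {self.query_id}: matches+mismatches+target_gaps "
                f"({self.matches}+{self.mismatches}+{self.target_gap_bases}) "
                f"!= aligned query bases ({aligned})"
            )
        if self.matches + self.mismatches + self.query_gap_bases != len(self.target):
            raise ValueError(
                f"hit {self.query_id}: counts inconsistent with target span"
            )

    @property
    def aligned_query_bases(self) -> int:
        return self.query_end - self.query_start


def hit_identity(hit: AlignmentHit, mode: str = "gap-inclusive") -> float:
    """Alignment identity of a hit.

    ``gap-inclusive`` (default): matches / (matches + mismatches + gap
    bases); ``gap-exclusive``: matches / (matches + mismatches).
    """
    if mode == "gap-inclusive":
        denom = (
            hit.matches + hit.mismatches + hit.query_gap_bases + hit.target_gap_bases
        )
    elif mode == "gap-exclusive":
        denom = hit.matches + hit.mismatches
    else:
        raise ValueError(f"unknown identity mode {mode!r}")
    if denom == 0:
        raise ValueError(f"hit {hit.query_id}: no aligned columns")
    return hit.matches / denom


def hit_coverage(hit: AlignmentHit) -> float:
    """Query-side coverage: fraction of the element length that aligned."""
    return hit.aligned_query_bases / hit.query_len


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed cigar {cigar!r}")
    bad = {op for _, op in ops} - set("MIDX=")
    if bad:
        raise ValueError(f"unsupported cigar ops {sorted(bad)} in {cigar!r}")
    return ops


def parse_paf(path: str | Path) -> list[AlignmentHit]:
    """Read PAF (columns 1-12 plus tags; cigar required in a ``cg:Z:`` tag).

    The residue-match column supplies ``matches``; the cigar supplies gap
    accounting and, with ``=``/``X`` ops, exact mismatch counts.  Spans
    implied by the cigar are checked against the stated spans.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected >= 12 PAF columns")
            qname, qlen, qstart, qend, strand = f[0], int(f[1]), int(f[2]), int(f[3]), f[4]
            tname, tlen, tstart, tend, nmatch = f[5], int(f[6]), int(f[7]), int(f[8]), int(f[9])
            cigar = None
            for tag in f[12:]:
                if tag.startswith("cg:Z:"):
                    cigar = tag[5:]
            if cigar is None:
                raise ValueError(
                    f"{path}:{lineno}: missing cg cigar tag (required to "
                    "recompute identity)"
                )
            ops = _parse_cigar(cigar)
            q_span = sum(n for n, op in ops if op in _QUERY_OPS)
            t_span = sum(n for n, op in ops if op in _TARGET_OPS)
            if q_span != qend - qstart or t_span != tend - tstart:
                raise ValueError(
                    f"{path}:{lineno}: cigar-implied spans ({q_span},{t_span}) "
                    f"!= stated spans ({qend - qstart},{tend - tstart})"
                )
            ins = sum(n for n, op in ops if op == "I")
            dele = sum(n for n, op in ops if op == "D")
            n_eq = sum(n for n, op in ops if op == "=")
            n_x = sum(n for n, op in ops if op == "X")
            n_m = sum(n for n, op in ops if op == "M")
            if n_eq or n_x:
                if n_m:
                    raise ValueError(f"{path}:{lineno}: cigar mixes M with =/X")
                if n_eq != nmatch:
                    raise ValueError(
                        f"{path}:{lineno}: cigar '=' total {n_eq} != residue "
                        f"matches {nmatch}"
                    )
                mismatches = n_x
            else:
                if nmatch > n_m:
                    raise ValueError(
                        f"{path}:{lineno}: residue matches {nmatch} exceed "
                        f"M columns {n_m}"
                    )
                mismatches = n_m - nmatch
            hits.append(
                AlignmentHit(
                    query_id=qname,
                    query_len=qlen,
                    query_start=qstart,
                    query_end=qend,
                    target=Interval(tname, tstart, tend, strand),
                    target_len=tlen,
                    matches=nmatch,
                    mismatches=mismatches,
                    query_gap_bases=dele,
                    target_gap_bases=ins,
                    cigar=cigar,
                )
            )
    return hits


def write_paf(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits as PAF with a ``cg`` tag.

    Hits lacking a stored cigar must be ungapped; they are written with a
    single-run ``M`` cigar (counts are recoverable from the residue-match
    column).
    """
    with open(path, "w") as fh:
        for h in hits:
            cigar = h.cigar
            if cigar is None:
                if h.query_gap_bases or h.target_gap_bases:
                    raise ValueError(
                        f"hit {h.query_id}: gapped hit without stored cigar"
                    )
                cigar = f"{h.matches + h.mismatches}M"
            block = h.matches + h.mismatches + h.query_gap_bases + h.target_gap_bases
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.query_len, h.query_start, h.query_end,
                        h.target.strand if h.target.strand in "+-" else "+",
                        h.target.seq_id, h.target_len, h.target.start, h.target.end,
                        h.matches, block, 255, f"cg:Z:{cigar}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# MAF blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MafRow:
    """One species row of a MAF block.

    ``src`` is ``species.chrom``; ``start`` is 0-based on the source strand
    and ``size`` is the ungapped length, per MAF semantics.
    """

    src: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def chrom(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) > 1 else parts[0]

    def ungapped(self) -> str:
        return self.text.replace("-", "")

    def forward_interval(self) -> Interval:
        """Span on the forward strand of the source sequence (negative-strand
        rows are projected: MAF start counts from the reverse strand)."""
        if self.strand == "+":
            return Interval(self.chrom, self.start, self.start + self.size, "+")
        start = self.src_size - self.start - self.size
        return Interval(self.chrom, start, start + self.size, "-")


@dataclass(frozen=True)
class MafBlock:
    rows: tuple[MafRow, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MAF block with no rows")
        ncol = len(self.rows[0].text)
        for row in self.rows:
            if len(row.text) != ncol:
                raise ValueError(
                    f"MAF block rows of unequal aligned length ({row.src})"
                )
            if len(row.ungapped()) != row.size:
                raise ValueError(
                    f"MAF row {row.src}: ungapped length != declared size"
                )

    @property
    def ncols(self) -> int:
        return len(self.rows[0].text)

    def species(self) -> list[str]:
        return [r.species for r in self.rows]

    def row_for_species(self, species: str) -> MafRow | None:
        for r in self.rows:
            if r.species == species:
                return r
        return None


def parse_maf(path: str | Path) -> list[MafBlock]:
    """Read MAF blocks in file order (``##maf`` header tolerated)."""
    blocks: list[MafBlock] = []
    for aln in AlignIO.parse(str(path), "maf"):
        rows = tuple(
            MafRow(
                src=rec.id,
                start=int(rec.annotations["start"]),
                size=int(rec.annotations["size"]),
                strand="+" if int(rec.annotations["strand"]) >= 0 else "-",
                src_size=int(rec.annotations["srcSize"]),
                text=str(rec.seq),
            )
            for rec in aln
        )
        blocks.append(MafBlock(rows))
    return blocks


def write_maf(blocks: Iterable[MafBlock], path: str | Path) -> None:
    alns = []
    for block in blocks:
        recs = [
            _BioRecord(
                Seq(row.text),
                id=row.src,
                annotations={
                    "start": row.start,
                    "size": row.size,
                    "strand": 1 if row.strand == "+" else -1,
                    "srcSize": row.src_size,
                },
            )
            for row in block.rows
        ]
        alns.append(MultipleSeqAlignment(recs))
    with open(path, "w") as fh:
        AlignIO.write(alns, fh, "maf")


def column_pairs(block: MafBlock, ref_species: str, other_species: str) -> list[tuple[str, str]]:
    """Aligned column pairs (ref_char, other_char) for two species of a block."""
    ref = block.row_for_species(ref_species)
    other = block.row_for_species(other_species)
    if ref is None or other is None:
        raise ValueError(
            f"block lacks a row for {ref_species if ref is None else other_species}"
        )
    return list(zip(ref.text, other.text))


# ---------------------------------------------------------------------------
# Column-pair quality measures
# ---------------------------------------------------------------------------

def _is_base(c: str) -> bool:
    return c != "-" and c.upper() in "ACGT"


def _pair_matches(q: str, t: str) -> bool:
    return _is_base(q) and _is_base(t) and q.upper() == t.upper()


def shannon_entropy(counts: Sequence[int]) -> float:
    """Shannon entropy H = -sum p log2 p in bits of a composition."""
    total = sum(counts)
    if total == 0:
        return 0.0
    return -sum(
        (c / total) * math.log2(c / total) for c in counts if c > 0
    ) + 0.0  # normalise -0.0 for pure compositions


def passes_entropy_quality(
    pairs: Sequence[tuple[str, str]],
    min_len: int = 30,
    min_id: float = 0.60,
    min_entropy_bits: float = 1.8,
) -> bool:
    """Per-alignment quality filter: true iff some contiguous run of
    >= ``min_len`` columns has identity >= ``min_id`` AND Shannon entropy of
    its query-base composition >= ``min_entropy_bits``.

    Identity is gap-inclusive over the run's columns; the composition counts
    query bases only (gaps excluded).  All run lengths are examined via
    prefix sums, so cost is quadratic in the number of columns — intended
    for per-alignment QC at the few-kilobase scale.
    """
    if not pairs:
        raise ValueError("empty alignment")
    n = len(pairs)
    if n < min_len:
        return False
    # prefix sums: matches and per-base query composition
    pm = [0] * (n + 1)
    pb = {b: [0] * (n + 1) for b in "ACGT"}
    for i, (q, t) in enumerate(pairs):
        pm[i + 1] = pm[i] + (1 if _pair_matches(q, t) else 0)
        for b in "ACGT":
            pb[b][i + 1] = pb[b][i] + (1 if q.upper() == b else 0)
    for start in range(n - min_len + 1):
        for end in range(start + min_len, n + 1):
            run = end - start
            if pm[end] - pm[start] < min_id * run:
                continue
            comp = [pb[b][end] - pb[b][start] for b in "ACGT"]
            if shannon_entropy(comp) >= min_entropy_bits:
                return True
    return False


@dataclass(frozen=True)
class ColumnPairStats:
    columns: int
    match: int
    mismatch: int
    ins: int
    dele: int

    def __post_init__(self) -> None:
        if self.match + self.mismatch + self.ins + self.dele != self.columns:
            raise ValueError("column classes do not sum to column count")

    @property
    def reference_bases(self) -> int:
        """Columns in which the reference (first genome) has a base."""
        return self.match + self.mismatch + self.dele


def summarize_differences(
    pairs: Sequence[tuple[str, str]]
) -> tuple[ColumnPairStats, dict[str, float]]:
    """Classify aligned columns of a pairwise (reference, other) alignment
    and report percentage rates over reference bases.

    Each column is exactly one of: match, mismatch (substitution), ins
    (reference gap: base present only in the other genome), del (other-side
    gap: reference base deleted).  Percentages use the number of reference
    bases as denominator, matching how per-genome difference rates are
    quoted.
    """
    if not pairs:
        raise ValueError("empty alignment")
    match = mismatch = ins = dele = 0
    for i, (q, t) in enumerate(pairs):
        q_gap, t_gap = q == "-", t == "-"
        if q_gap and t_gap:
            raise ValueError(f"column {i}: gap on both sides (malformed)")
        if q_gap:
            ins += 1
        elif t_gap:
            dele += 1
        elif q.upper() == t.upper():
            match += 1
        else:
            mismatch += 1
    stats = ColumnPairStats(len(pairs), match, mismatch, ins, dele)
    ref = stats.reference_bases
    pct = {
        "match_pct": 100 * match / ref,
        "substitution_pct": 100 * mismatch / ref,
        "insertion_pct": 100 * ins / ref,
        "deletion_pct": 100 * dele / ref,
    }
    return stats, pct


# ---------------------------------------------------------------------------
# Built-in element mapper
# ---------------------------------------------------------------------------

def _seed_index(assembly: Sequence[SeqRecord], k: int) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for si, rec in enumerate(assembly):
        seq = rec.sequence.upper()
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((si, pos))
    return index


def map_elements(
    elements: Sequence[SeqRecord],
    assembly: Sequence[SeqRecord],
    seed_len: int = 12,
) -> list[AlignmentHit]:
    """Exact-seed (k-mer) anchored, ungapped-extension mapping of elements
    onto an assembly, on both strands.

    Each distinct (scaffold, diagonal, strand) anchor yields at most one
    ungapped hit covering the overlap of the element with the scaffold.  An
    element planted verbatim yields a hit with identity and coverage 1.0;
    elements with no exact ``seed_len``-mer in common with the assembly
    produce no hit.  Substitution-level divergence is tolerated as long as
    one seed survives intact.
    """
    index = _seed_index(assembly, seed_len)
    hits: list[AlignmentHit] = []
    for elem in elements:
        if len(elem) < seed_len:
            continue
        seen: set[tuple[int, int, str]] = set()
        for strand in ("+", "-"):
            qseq = elem.sequence if strand == "+" else reverse_complement(elem.sequence)
            qupper = qseq.upper()
            qlen = len(qseq)
            for off in range(0, qlen - seed_len + 1, seed_len):
                for si, pos in index.get(qupper[off : off + seed_len], ()):
                    tstart = pos - off
                    key = (si, tstart, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    tseq = assembly[si].sequence.upper()
                    qs = max(0, -tstart)
                    ts = max(0, tstart)
                    span = min(qlen - qs, len(tseq) - ts)
                    if span < seed_len:
                        continue
                    eq = [
                        qupper[qs + i] == tseq[ts + i]
                        and qupper[qs + i] != "N"
                        for i in range(span)
                    ]
                    matches = sum(eq)
                    # run-length =/X cigar from the equality vector
                    cig_parts: list[str] = []
                    run_op, run_len = None, 0
                    for e in eq:
                        op = "=" if e else "X"
                        if op == run_op:
                            run_len += 1
                        else:
                            if run_op is not None:
                                cig_parts.append(f"{run_len}{run_op}")
                            run_op, run_len = op, 1
                    cig_parts.append(f"{run_len}{run_op}")
                    if strand == "+":
                        q0, q1 = qs, qs + span
                    else:  # report query span on the forward query
                        q0, q1 = qlen - (qs + span), qlen - qs
                    hits.append(
                        AlignmentHit(
                            query_id=elem.id,
                            query_len=qlen,
                            query_start=q0,
                            query_end=q1,
                            target=Interval(
                                assembly[si].id, ts, ts + span, strand
                            ),
                            target_len=len(tseq),
                            matches=matches,
                            mismatches=span - matches,
                            cigar="".join(cig_parts),
                        )
                    )
    return hits
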