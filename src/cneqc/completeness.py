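"""Assembly completeness scored with conserved-element reference sets.

A set of deeply conserved elements (UCEs or CNEs) is mapped to the assembly
under test; an element counts as *found* when its best alignment passes the
identity/coverage filter (defaults >= 60% identity, >= 80% query coverage,
thresholds inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .alignments import AlignmentHit, hit_coverage, hit_identity
from .seqio import SeqRecord

__all__ = [
    "prepare_cne_reference",
    "filter_hits",
    "CompletenessReport",
    "score_completeness",
]


def prepare_cne_reference(
    elements: Iterable[SeqRecord], min_len: int = 301, trim: int = 30
) -> list[SeqRecord]:
    """Prepare a CNE reference set: drop elements shorter than ``min_len``
    (default keeps only elements longer than 300 bp — the bound is strict)
    and trim ``trim`` bp from both ends of the survivors, retaining the
    conserved core.  Ids are preserved.
    """
    if trim < 0:
        raise ValueError("trim must be >= 0")
    if min_len <= 2 * trim:
        raise ValueError("min_len must exceed 2*trim")
    out: list[SeqRecord] = []
    for elem in elements:
        if len(elem) < min_len:
            continue
        seq = elem.sequence[trim : len(elem.sequence) - trim] if trim else elem.sequence
        out.append(SeqRecord(elem.id, seq))
    return out


def _rank_key(hit: AlignmentHit, identity_mode: str):
    # higher is better for the first two components; ties broken toward the
    # lexicographically smallest target location for order-independence
    return (
        -(hit_identity(hit, identity_mode) * hit_coverage(hit)),
        -hit.matches,
        hit.target.seq_id,
        hit.target.start,
    )


def filter_hits(
    hits: Iterable[AlignmentHit],
    min_identity: float = 0.60,
    min_coverage: float = 0.80,
    identity_mode: str = "gap-inclusive",
) -> dict[str, AlignmentHit]:
    """Apply the identity/coverage filter (inclusive thresholds) and retain
    the single best surviving hit per element.

    Ranking: identity x coverage, then match count, then smallest
    (target seq_id, start) — deterministic and input-order independent.
    Elements with no surviving hit are absent from the result.
    """
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        if hit_identity(hit, identity_mode) < min_identity:
            continue
        if hit_coverage(hit) < min_coverage:
            continue
        cur = best.get(hit.query_id)
        if cur is None or _rank_key(hit, identity_mode) < _rank_key(cur, identity_mode):
            best[hit.query_id] = hit
    return best


@dataclass
class CompletenessReport:
    n_total: int
    n_found: int
    found_ids: list[str]
    missing_ids: list[str]
    best_hits: dict[str, AlignmentHit] = field(repr=False)
    identity_mode: str = "gap-inclusive"

    def __post_init__(self) -> None:
        assert self.n_found + len(self.missing_ids) == self.n_total

    @property
    def fraction_found(self) -> float:
        return self.n_found / self.n_total if self.n_total else 0.0

    def detail_rows(self) -> list[dict]:
        rows = []
        for eid in self.found_ids:
            h = self.best_hits[eid]
            rows.append(
                {
                    "element": eid,
                    "status": "found",
                    "identity": hit_identity(h, self.identity_mode),
                    "coverage": hit_coverage(h),
                    "target": h.target.seq_id,
                    "target_start": h.target.start,
                    "target_end": h.target.end,
                    "strand": h.target.strand,
                }
            )
        for eid in self.missing_ids:
            rows.append(
                {
                    "element": eid,
                    "status": "missing",
                    "identity": None,
                    "coverage": None,
                    "target": None,
                    "target_start": None,
                    "target_end": None,
                    "strand": None,
                }
            )
        return rows


def score_completeness(
    elements: Sequence[SeqRecord],
    filtered_hits: Mapping[str, AlignmentHit],
    identity_mode: str = "gap-inclusive",
) -> CompletenessReport:
    """Count elements recovered by their filtered best hits.

    ``filtered_hits`` is the output of :func:`filter_hits`; a hit keyed by
    an id not in ``elements`` is an error.
    """
    ids = [e.id for e in elements]
    unknown = set(filtered_hits) - set(ids)
    if unknown:
        raise ValueError(f"hits for unknown element ids: {sorted(unknown)}")
    found = [eid for eid in ids if eid in filtered_hits]
    missing = [eid for eid in ids if eid not in filtered_hits]
    return CompletenessReport(
        n_total=len(ids),
        n_found=len(found),
        found_ids=found,
        missing_ids=missing,
        best_hits=dict(filtered_hits),
        identity_mode=identity_mode,
    )
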