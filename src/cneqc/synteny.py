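"""Contiguity statistic from conserved pairs of neighboring elements.

Two elements form an *evolutionarily conserved pair* when they are
consecutive neighbours on the same chromosome, at most 1 Mb apart, in every
provided outgroup genome.  The statistic is the fraction of those pairs
recovered on a single scaffold, again at most 1 Mb apart, in the assembly
under test — a completeness-independent probe of intergenic contiguity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .alignments import AlignmentHit
from .intervals import Interval, IntervalSet

__all__ = ["PairRecord", "ContiguityReport", "build_reference_pairs", "evaluate_pairs"]

logger = logging.getLogger(__name__)

RECOVERED = "recovered"
SPLIT = "split"
UNMAPPED = "unmapped"


@dataclass
class PairRecord:
    """Two neighboring elements with per-outgroup co-location evidence."""

    element_a: str
    element_b: str
    evidence: dict[str, tuple[str, int]]  # outgroup -> (chrom, inner_distance)
    status: str | None = None

    def __post_init__(self) -> None:
        if self.element_a == self.element_b:
            raise ValueError("pair of an element with itself")

    @property
    def key(self) -> frozenset:
        return frozenset((self.element_a, self.element_b))


def _inner_distance(a: Interval, b: Interval) -> int:
    """End-of-upstream to start-of-downstream distance; overlapping spans
    count as distance 0."""
    first, second = (a, b) if (a.start, a.end) <= (b.start, b.end) else (b, a)
    return max(0, second.start - first.end)


def build_reference_pairs(
    locations: Mapping[str, IntervalSet],
    max_dist: int = 1_000_000,
    pairing: str = "adjacent",
) -> list[PairRecord]:
    """Derive conserved neighbour pairs from element locations in outgroup
    genomes (named BED sets; interval ``name`` = element id).

    Within each outgroup, elements are sorted by position; a candidate pair
    is two elements consecutive in that ordering (``pairing="adjacent"``, the
    default) or any two within ``max_dist`` (``pairing="all-within-window"``),
    on the same chromosome with inner distance <= ``max_dist``.  A pair is
    emitted only when it is a candidate in EVERY provided outgroup; elements
    absent from any outgroup are excluded from pairing (logged).
    """
    if not locations:
        raise ValueError("at least one outgroup location set required")
    if pairing not in ("adjacent", "all-within-window"):
        raise ValueError(f"unknown pairing mode {pairing!r}")
    per_og: dict[str, dict[str, Interval]] = {}
    for og, ivset in locations.items():
        d: dict[str, Interval] = {}
        for iv in ivset:
            if iv.name is None:
                raise ValueError(f"outgroup {og}: BED interval without element name")
            if iv.name in d:
                raise ValueError(f"outgroup {og}: element {iv.name} appears twice")
            d[iv.name] = iv
        per_og[og] = d
    common = set.intersection(*(set(d) for d in per_og.values()))
    dropped = set.union(*(set(d) for d in per_og.values())) - common
    if dropped:
        logger.info(
            "excluded %d element(s) absent from some outgroup: %s",
            len(dropped), ", ".join(sorted(dropped)),
        )

    candidates_per_og: list[dict[frozenset, tuple[str, int]]] = []
    for og, d in per_og.items():
        ordered = sorted(
            (iv for name, iv in d.items() if name in common),
            key=Interval.sort_key,
        )
        cands: dict[frozenset, tuple[str, int]] = {}
        for i, a in enumerate(ordered):
            js = (
                range(i + 1, i + 2)
                if pairing == "adjacent"
                else range(i + 1, len(ordered))
            )
            for j in js:
                if j >= len(ordered):
                    break
                b = ordered[j]
                if b.seq_id != a.seq_id:
                    break
                dist = _inner_distance(a, b)
                if dist > max_dist:
                    if pairing == "all-within-window":
                        break
                    continue
                cands[frozenset((a.name, b.name))] = (a.seq_id, dist)
        candidates_per_og.append(cands)

    shared = set.intersection(*(set(c) for c in candidates_per_og))
    pairs: list[PairRecord] = []
    for key in shared:
        a, b = sorted(key)
        evidence = {
            og: candidates_per_og[k][key] for k, og in enumerate(per_og)
        }
        pairs.append(PairRecord(a, b, evidence))
    pairs.sort(key=lambda p: (p.element_a, p.element_b))
    return pairs


@dataclass
class ContiguityReport:
    n_pairs: int
    n_recovered: int
    pairs: list[PairRecord] = field(repr=False)

    @property
    def fraction(self) -> float:
        return self.n_recovered / self.n_pairs if self.n_pairs else 0.0

    def counts(self) -> dict[str, int]:
        out = {RECOVERED: 0, SPLIT: 0, UNMAPPED: 0}
        for p in self.pairs:
            out[p.status] += 1
        return out


def evaluate_pairs(
    pairs: Iterable[PairRecord],
    best_hits: Mapping[str, AlignmentHit],
    max_dist: int = 1_000_000,
) -> ContiguityReport:
    """Score pair recovery in the assembly under test.

    A pair is ``recovered`` iff both elements have retained hits on the same
    scaffold with inner distance (end of the upstream hit to start of the
    downstream hit; overlapping hits count 0) <= ``max_dist``; ``unmapped``
    if either element lacks a hit; ``split`` otherwise.  Input order does
    not affect the result.
    """
    evaluated: list[PairRecord] = []
    n_recovered = 0
    for pair in sorted(pairs, key=lambda p: (p.element_a, p.element_b)):
        ha = best_hits.get(pair.element_a)
        hb = best_hits.get(pair.element_b)
        if ha is None or hb is None:
            status = UNMAPPED
        elif ha.target.seq_id != hb.target.seq_id:
            status = SPLIT
        elif _inner_distance(ha.target, hb.target) <= max_dist:
            status = RECOVERED
            n_recovered += 1
        else:
            status = SPLIT
        evaluated.append(
            PairRecord(pair.element_a, pair.element_b, dict(pair.evidence), status)
        )
    return ContiguityReport(len(evaluated), n_recovered, evaluated)
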