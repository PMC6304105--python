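"""Conserved non-exonic element (CNE) derivation and classification.

The pipeline consumes interval calls from two constraint callers (e.g. a
PhastCons-style and a GERP-style set), a reference-anchored multiple
alignment (MAF) and an exon annotation, and produces CNEs with
species-support and lineage-class labels, plus transposon-overlap
accounting against a repeat annotation.

Stages: merge the two conserved-region sets (join gap <= 10 bp, length >=
30 bp) -> require alignment support in >= 4 ingroup species -> subtract
exonic bases, keep fragments >= 30 bp -> classify lineage specificity
(ingroup-specific: support in >= 6 ingroup species and zero outgroups;
shared: >= 6 ingroup and >= 1 outgroup) -> intersect with SINE/LINE/LTR/DNA
transposons (>= 30 bp overlap with a single feature).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .alignments import MafBlock, _pair_matches
from .intervals import Interval, IntervalSet, merge_intervals, subtract_intervals

__all__ = [
    "ConservedRegion",
    "Cne",
    "RepeatFeature",
    "merge_conserved_sets",
    "compute_support_windows",
    "species_support_filter",
    "derive_cnes",
    "classify_lineage",
    "parse_repeatmasker_out",
    "write_repeatmasker_out",
    "normalize_repeat_class",
    "transposon_overlap",
    "TransposonOverlapReport",
]

INGROUP_SPECIFIC = "ingroup_specific"
SHARED = "shared"
UNCLASSIFIED = "unclassified"

TRANSPOSON_CLASSES = ("SINE", "LINE", "LTR", "DNA")


@dataclass
class ConservedRegion:
    id: str
    interval: Interval
    sources: frozenset[str]
    supporting_species: frozenset[str] = frozenset()


@dataclass
class Cne:
    id: str
    interval: Interval
    parent_region: str
    lineage_class: str = UNCLASSIFIED
    supporting_species: frozenset[str] = frozenset()
    transposon_overlap: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class RepeatFeature:
    interval: Interval
    repeat_class: str
    family: str


def merge_conserved_sets(
    set_a: IntervalSet,
    set_b: IntervalSet,
    join_gap: int = 10,
    min_len: int = 30,
    names: tuple[str, str] = ("setA", "setB"),
) -> list[ConservedRegion]:
    """Union two conserved-region call sets, join regions separated by
    <= ``join_gap`` bp, and drop merged regions shorter than ``min_len``.

    Each surviving region records which input set(s) contributed bases.
    """
    merged = merge_intervals(list(set_a) + list(set_b), join_gap)
    inputs = {names[0]: list(set_a), names[1]: list(set_b)}
    trees: dict[str, dict[str, IntervalTree]] = {}
    for label, ivs in inputs.items():
        per_seq: dict[str, IntervalTree] = {}
        for iv in ivs:
            per_seq.setdefault(iv.seq_id, IntervalTree()).addi(iv.start, iv.end)
        trees[label] = per_seq
    regions: list[ConservedRegion] = []
    idx = 0
    for iv in merged:
        if len(iv) < min_len:
            continue
        sources = frozenset(
            label
            for label, per_seq in trees.items()
            if iv.seq_id in per_seq and per_seq[iv.seq_id].overlap(iv.start, iv.end)
        )
        idx += 1
        regions.append(ConservedRegion(f"region_{idx}", iv, sources))
    return regions


def compute_support_windows(
    blocks: Iterable[MafBlock],
    ref_species: str,
    win: int = 30,
    min_id: float = 0.60,
) -> dict[str, IntervalSet]:
    """Per-species alignment-support windows on the reference genome.

    For each non-reference species and each MAF block, every run of exactly
    ``win`` alignment columns whose pairwise identity with the reference is
    >= ``min_id`` marks the reference-base positions it spans (identity is
    gap-inclusive: a gap column counts as a non-match).  Marked positions
    are merged into maximal intervals and only intervals >= ``win`` bp are
    reported.  The reference row must be present (forward strand) in every
    block.
    """
    marked: dict[str, list[Interval]] = {}
    for bi, block in enumerate(blocks):
        ref = block.row_for_species(ref_species)
        if ref is None:
            raise ValueError(f"MAF block {bi} lacks reference species {ref_species}")
        if ref.strand != "+":
            raise ValueError(
                f"MAF block {bi}: reference row must be on the forward strand"
            )
        n = block.ncols
        # reference coordinate of each column (position of the ref base)
        ref_pos = []
        pos = ref.start
        for c in ref.text:
            ref_pos.append(pos if c != "-" else None)
            if c != "-":
                pos += 1
        for row in block.rows:
            if row.species == ref_species:
                continue
            eq = [1 if _pair_matches(a, b) else 0 for a, b in zip(ref.text, row.text)]
            if n < win:
                continue
            # sliding window of length win; mark covered columns of passing windows
            covered = [False] * n
            s = sum(eq[:win])
            need = min_id * win
            for start in range(n - win + 1):
                if start > 0:
                    s += eq[start + win - 1] - eq[start - 1]
                if s >= need:
                    for k in range(start, start + win):
                        covered[k] = True
            ivs = marked.setdefault(row.species, [])
            for k in range(n):
                if covered[k] and ref_pos[k] is not None:
                    ivs.append(
                        Interval(ref.chrom, ref_pos[k], ref_pos[k] + 1)
                    )
    out: dict[str, IntervalSet] = {}
    for species, ivs in marked.items():
        merged = merge_intervals(ivs, 0)
        out[species] = IntervalSet(iv for iv in merged if len(iv) >= win)
    return out


def _window_trees(windows: Mapping[str, IntervalSet]) -> dict[str, dict[str, IntervalTree]]:
    trees: dict[str, dict[str, IntervalTree]] = {}
    for species, ivset in windows.items():
        per_seq: dict[str, IntervalTree] = {}
        for iv in ivset:
            per_seq.setdefault(iv.seq_id, IntervalTree()).addi(iv.start, iv.end)
        trees[species] = per_seq
    return trees


def _species_overlapping(
    interval: Interval,
    trees: Mapping[str, dict[str, IntervalTree]],
    min_overlap: int,
) -> frozenset[str]:
    hit = set()
    for species, per_seq in trees.items():
        tree = per_seq.get(interval.seq_id)
        if tree is None:
            continue
        for ov in tree.overlap(interval.start, interval.end):
            if min(ov.end, interval.end) - max(ov.begin, interval.start) >= min_overlap:
                hit.add(species)
                break
    return frozenset(hit)


def species_support_filter(
    regions: Sequence[ConservedRegion],
    windows: Mapping[str, IntervalSet],
    min_species: int = 4,
    min_overlap: int = 1,
) -> list[ConservedRegion]:
    """Keep regions that overlap (>= ``min_overlap`` bp) a support window in
    at least ``min_species`` distinct species; record the supporting set."""
    trees = _window_trees(windows)
    kept: list[ConservedRegion] = []
    for region in regions:
        support = _species_overlapping(region.interval, trees, min_overlap)
        if len(support) >= min_species:
            kept.append(replace(region, supporting_species=support))
    return kept


def derive_cnes(
    regions: Sequence[ConservedRegion],
    exons: IntervalSet,
    min_len: int = 30,
) -> list[Cne]:
    """Subtract exonic bases from conserved regions; fragments >= ``min_len``
    become CNEs, each recording its parent region."""
    cnes: list[Cne] = []
    idx = 0
    for region in regions:
        fragments = subtract_intervals([region.interval], exons)
        for frag in fragments:
            if len(frag) < min_len:
                continue
            idx += 1
            cnes.append(
                Cne(
                    id=f"cne_{idx}",
                    interval=frag,
                    parent_region=region.id,
                    supporting_species=region.supporting_species,
                )
            )
    return cnes


def classify_lineage(
    cnes: Sequence[Cne],
    windows: Mapping[str, IntervalSet],
    ingroup: Sequence[str],
    outgroup: Sequence[str],
    min_ingroup: int = 6,
    min_overlap: int = 1,
) -> list[Cne]:
    """Assign lineage classes from per-species window overlap.

    ``ingroup_specific``: >= ``min_ingroup`` ingroup species overlap and not
    a single outgroup species; ``shared``: >= ``min_ingroup`` ingroup and
    >= 1 outgroup; everything else ``unclassified``.  The classes are
    mutually exclusive and exhaustive.
    """
    in_set, out_set = set(ingroup), set(outgroup)
    if in_set & out_set:
        raise ValueError("ingroup and outgroup species sets overlap")
    undeclared = set(windows) - in_set - out_set
    if undeclared:
        raise ValueError(
            f"species in windows not declared ingroup/outgroup: {sorted(undeclared)}"
        )
    trees = _window_trees(windows)
    classified: list[Cne] = []
    for cne in cnes:
        support = _species_overlapping(cne.interval, trees, min_overlap)
        n_in = len(support & in_set)
        n_out = len(support & out_set)
        if n_in >= min_ingroup and n_out == 0:
            cls = INGROUP_SPECIFIC
        elif n_in >= min_ingroup:
            cls = SHARED
        else:
            cls = UNCLASSIFIED
        classified.append(replace(cne, lineage_class=cls, supporting_species=support))
    return classified


def normalize_repeat_class(class_family: str) -> tuple[str, str]:
    """Map a RepeatMasker class/family string to (class, family).

    The class is the token before '/', with uncertainty markers ('?')
    stripped; anything outside {SINE, LINE, LTR, DNA} becomes ``other``.
    """
    cls, _, family = class_family.partition("/")
    cls = cls.strip("?")
    family = family.strip("?")
    if cls.upper() in TRANSPOSON_CLASSES:
        cls = cls.upper()
    else:
        cls = "other"
    return cls, family or class_family


def parse_repeatmasker_out(path: str | Path) -> list[RepeatFeature]:
    """Read a RepeatMasker ``.out`` annotation.

    Skips the three header lines; query coordinates are 1-based inclusive
    and converted to 0-based half-open.
    """
    feats: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if not fields[0].isdigit():
                # banner/header lines (SW-score columns legend) and asterisked
                # footers all start with a non-numeric token
                continue
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: truncated RepeatMasker line")
            try:
                begin, end = int(fields[5]), int(fields[6])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed coordinates {fields[5]!r}/{fields[6]!r}"
                ) from None
            if begin < 1 or end < begin:
                raise ValueError(f"{path}:{lineno}: malformed coordinate range")
            query = fields[4]
            strand = "+" if fields[8] == "+" else "-"
            repeat_name = fields[9]
            cls, family = normalize_repeat_class(fields[10])
            feats.append(
                RepeatFeature(
                    Interval(query, begin - 1, end, strand, repeat_name),
                    cls,
                    family,
                )
            )
    return feats


def write_repeatmasker_out(features: Iterable[RepeatFeature], path: str | Path) -> None:
    """Write a RepeatMasker-style ``.out`` file (1-based inclusive coords)."""
    header = (
        "   SW   perc perc perc  query     position in query    matching"
        "  repeat        position in repeat\n"
        "score   div. del. ins.  sequence  begin end   (left)   repeat"
        "        class/family  begin  end  (left)  ID\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, f in enumerate(sorted(features, key=lambda f: f.interval.sort_key()), 1):
            iv = f.interval
            cls_fam = f"{f.repeat_class}/{f.family}" if f.family else f.repeat_class
            name = iv.name or f"rep{i}"
            strand = "+" if iv.strand != "-" else "C"
            fh.write(
                f"  {1000 + i}    1.0  0.0  0.0  {iv.seq_id}  {iv.start + 1} "
                f"{iv.end}  (0)  {strand}  {name}  {cls_fam}  1  {len(iv)}  (0)  {i}\n"
            )


@dataclass
class TransposonOverlapReport:
    n_cnes_total: int
    n_cnes_overlapping: int
    overlapping_ids: list[str]
    overlapped_bp: int
    bp_by_class: dict[str, int]
    total_cne_bases: int

    @property
    def fraction_cnes(self) -> float:
        return self.n_cnes_overlapping / self.n_cnes_total if self.n_cnes_total else 0.0

    @property
    def fraction_cne_bases(self) -> float:
        return self.overlapped_bp / self.total_cne_bases if self.total_cne_bases else 0.0


def transposon_overlap(
    cnes: Sequence[Cne],
    repeats: Sequence[RepeatFeature],
    min_overlap: int = 30,
    sum_overlaps: bool = False,
) -> TransposonOverlapReport:
    """Quantify CNE-transposon overlap.

    Only SINE/LINE/LTR/DNA features are considered.  A CNE counts as
    transposon-overlapping when some single feature overlaps it by
    >= ``min_overlap`` bp (or, with ``sum_overlaps``, when the summed
    overlap across features reaches the threshold).  The overlapped-bp
    accounting covers counted CNEs only, split by repeat class.
    """
    tes = [r for r in repeats if r.repeat_class in TRANSPOSON_CLASSES]
    trees: dict[str, IntervalTree] = {}
    for r in tes:
        trees.setdefault(r.interval.seq_id, IntervalTree()).addi(
            r.interval.start, r.interval.end, r
        )
    overlapping: list[str] = []
    overlapped_bp = 0
    bp_by_class: dict[str, int] = {c: 0 for c in TRANSPOSON_CLASSES}
    for cne in cnes:
        tree = trees.get(cne.interval.seq_id)
        if tree is None:
            continue
        per_feature: list[tuple[int, str]] = []
        for ov in tree.overlap(cne.interval.start, cne.interval.end):
            bp = min(ov.end, cne.interval.end) - max(ov.begin, cne.interval.start)
            if bp > 0:
                per_feature.append((bp, ov.data.repeat_class))
        if not per_feature:
            continue
        qualifies = (
            sum(bp for bp, _ in per_feature) >= min_overlap
            if sum_overlaps
            else max(bp for bp, _ in per_feature) >= min_overlap
        )
        if not qualifies:
            continue
        overlapping.append(cne.id)
        cne.transposon_overlap = {}
        for bp, cls in per_feature:
            overlapped_bp += bp
            bp_by_class[cls] += bp
            cne.transposon_overlap[cls] = cne.transposon_overlap.get(cls, 0) + bp
    return TransposonOverlapReport(
        n_cnes_total=len(cnes),
        n_cnes_overlapping=len(overlapping),
        overlapping_ids=overlapping,
        overlapped_bp=overlapped_bp,
        bp_by_class=bp_by_class,
        total_cne_bases=sum(len(c.interval) for c in cnes),
    )
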