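"""Deterministic synthetic clade generator with known ground truth.

Builds a toy study system end to end: a reference genome with planted
conserved elements, per-species copies diverged by independent per-branch
substitutions on a fixed ingroup/outgroup topology, a reference-anchored
MAF over the element loci, two conserved-region call sets, an exon
annotation, a RepeatMasker-style transposon annotation, element locations
in outgroup genomes, and a truth table of element classes and expected
neighbour pairs.

Evolution is substitution-only (uniform choice among the three alternative
bases, independent per branch), so MAF blocks follow from positional
correspondence and no aligner is needed.  Every output derives from its own
random stream seeded by ``(seed, output name)``, so adding outputs never
perturbs existing ones and a fixed seed reproduces every file byte for
byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alignments import MafBlock, MafRow, write_maf
from .cne import RepeatFeature, write_repeatmasker_out
from .intervals import Interval, IntervalSet, write_bed
from .seqio import SeqRecord, write_fasta

__all__ = [
    "SimulationConfig",
    "ElementTruth",
    "TruthTable",
    "SimulatedClade",
    "simulate_clade",
    "fragment_assembly",
    "join_with_gaps",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_INGROUP = (
    "anole", "gecko", "skink", "dragon", "glasslizard",
    "monitor", "iguana", "boa", "python",
)
DEFAULT_OUTGROUP = ("chicken", "human", "mouse")


def _stream(seed: int, name: str) -> np.random.Generator:
    """One reproducible random stream per (seed, logical output)."""
    h = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big") % (2**31)
    return np.random.default_rng([int(seed) % (2**31), h])


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, codes: np.ndarray, p: float) -> np.ndarray:
    """Substitute each base with probability ``p`` to a uniformly chosen
    different base (Jukes-Cantor-style)."""
    out = codes.copy()
    if p <= 0:
        return out
    mask = rng.random(codes.size) < p
    n_mut = int(mask.sum())
    if n_mut:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n_mut, dtype=np.uint8)) % 4
    return out


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic clade.

    Defaults model the real setting at desk scale: a 200 kb reference with
    50 planted conserved elements, nine ingroup species at 0.05
    substitutions per site on their branches, three outgroups at 0.10, and
    a 40/40/20 split of ingroup-specific / shared / decoy elements.
    """

    seed: int = 0
    genome_len: int = 200_000
    n_elements: int = 50
    element_len: tuple[int, int] = (310, 400)
    ref_species: str = "tegu"
    ingroup: dict[str, float] = field(
        default_factory=lambda: {sp: 0.05 for sp in DEFAULT_INGROUP}
    )
    outgroup: tuple[str, ...] = DEFAULT_OUTGROUP
    outgroup_sub: float = 0.10
    frac_ingroup_specific: float = 0.40
    frac_shared: float = 0.40
    # (class, count, length) of annotated transposon insertions
    transposons: tuple[tuple[str, int, int], ...] = (
        ("LINE", 8, 400), ("SINE", 8, 150), ("LTR", 4, 300), ("DNA", 4, 250)
    )
    n_te_in_elements: int = 3  # transposons planted to overlap an element >= 30 bp
    n_exons: int = 20
    exon_len: tuple[int, int] = (100, 300)
    n_breaks: int = 0
    gap_len: int = 100
    region_jitter: int = 5  # setB call boundaries move by up to this many bp

    def __post_init__(self) -> None:
        if not (0 <= self.frac_ingroup_specific + self.frac_shared <= 1):
            raise ValueError("element class fractions must sum to <= 1")
        for p in list(self.ingroup.values()) + [self.outgroup_sub]:
            if not 0 <= p <= 1:
                raise ValueError("substitution probabilities must be in [0,1]")
        if self.gap_len < 25:
            raise ValueError("gap_len must be >= 25 so fragments register as gaps")
        names = [self.ref_species, *self.ingroup, *self.outgroup]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        slot = self.genome_len // self.n_elements
        if slot < self.element_len[1] + 200:
            raise ValueError(
                "genome too small for the requested number/length of elements"
            )


@dataclass
class ElementTruth:
    id: str
    interval: Interval
    lineage_class: str  # ingroup_specific | shared | decoy
    present_in: dict[str, bool]


@dataclass
class TruthTable:
    elements: list[ElementTruth]
    pairs: list[tuple[str, str]]
    transposons: list[RepeatFeature]
    te_overlapping_elements: list[str]

    def element_by_id(self, eid: str) -> ElementTruth:
        for e in self.elements:
            if e.id == eid:
                return e
        raise KeyError(eid)


@dataclass
class SimulatedClade:
    config: SimulationConfig
    reference: SeqRecord
    scaffolds: list[SeqRecord]
    species_genomes: dict[str, SeqRecord]
    elements: list[SeqRecord]
    maf_blocks: list[MafBlock]
    conserved_set_a: IntervalSet
    conserved_set_b: IntervalSet
    exons: IntervalSet
    repeats: list[RepeatFeature]
    outgroup_locations: dict[str, IntervalSet]
    truth: TruthTable

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every artifact as plain-text files; deterministic content
        and ordering for a given config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def _p(name: str) -> Path:
            paths[name] = outdir / name
            return paths[name]

        write_fasta([self.reference], _p("reference.fa"))
        write_fasta(self.scaffolds, _p("assembly.fa"))
        write_fasta(self.elements, _p("elements.fa"))
        sp_dir = outdir / "species"
        sp_dir.mkdir(exist_ok=True)
        for sp, rec in sorted(self.species_genomes.items()):
            write_fasta([rec], sp_dir / f"{sp}.fa")
            paths[f"species/{sp}.fa"] = sp_dir / f"{sp}.fa"
        write_maf(self.maf_blocks, _p("alignment.maf"))
        write_bed(self.conserved_set_a, _p("conserved_setA.bed"))
        write_bed(self.conserved_set_b, _p("conserved_setB.bed"))
        write_bed(self.exons, _p("exons.bed"))
        write_repeatmasker_out(self.repeats, _p("repeats.out"))
        og_dir = outdir / "outgroups"
        og_dir.mkdir(exist_ok=True)
        for og, ivset in sorted(self.outgroup_locations.items()):
            write_bed(ivset, og_dir / f"{og}.bed")
            paths[f"outgroups/{og}.bed"] = og_dir / f"{og}.bed"
        with open(_p("truth_elements.tsv"), "w") as fh:
            fh.write("element\tstart\tend\tclass\t" +
                     "\t".join(sorted(self.truth.elements[0].present_in)) + "\n")
            for e in self.truth.elements:
                cols = [e.id, str(e.interval.start), str(e.interval.end), e.lineage_class]
                cols += ["1" if e.present_in[sp] else "0"
                         for sp in sorted(e.present_in)]
                fh.write("\t".join(cols) + "\n")
        with open(_p("truth_pairs.tsv"), "w") as fh:
            fh.write("element_a\telement_b\n")
            for a, b in self.truth.pairs:
                fh.write(f"{a}\t{b}\n")
        return paths


def simulate_clade(config: SimulationConfig) -> SimulatedClade:
    """Generate the full synthetic study system for ``config``.

    Identical configs (in particular identical seeds) produce identical
    objects and, through :meth:`SimulatedClade.write`, byte-identical files.
    """
    cfg = config
    seed = cfg.seed
    ref_chrom = "chr1"
    ref_src = f"{cfg.ref_species}.{ref_chrom}"

    ref_codes = _random_codes(_stream(seed, "reference"), cfg.genome_len)

    # --- element placement: one element per equal slot, jittered ----------
    place_rng = _stream(seed, "placement")
    slot = cfg.genome_len // cfg.n_elements
    intervals: list[Interval] = []
    for i in range(cfg.n_elements):
        length = int(place_rng.integers(cfg.element_len[0], cfg.element_len[1] + 1))
        lo = i * slot + 100
        hi = (i + 1) * slot - 100 - length
        start = int(place_rng.integers(lo, hi + 1))
        intervals.append(Interval(ref_chrom, start, start + length, name=f"elem_{i + 1:03d}"))

    # --- class assignment --------------------------------------------------
    n_is = round(cfg.frac_ingroup_specific * cfg.n_elements)
    n_sh = round(cfg.frac_shared * cfg.n_elements)
    labels = (
        ["ingroup_specific"] * n_is
        + ["shared"] * n_sh
        + ["decoy"] * (cfg.n_elements - n_is - n_sh)
    )
    _stream(seed, "classes").shuffle(labels)

    # --- species genomes ----------------------------------------------------
    species_codes: dict[str, np.ndarray] = {}
    for sp, p in sorted(cfg.ingroup.items()):
        species_codes[sp] = _mutate(_stream(seed, f"branch:{sp}"), ref_codes, p)
    for sp in cfg.outgroup:
        species_codes[sp] = _mutate(
            _stream(seed, f"branch:{sp}"), ref_codes, cfg.outgroup_sub
        )
    # ingroup-specific loci: outgroups carry unrelated sequence;
    # decoy loci: every non-reference species carries unrelated sequence
    presence: dict[str, dict[str, bool]] = {}
    for iv, label in zip(intervals, labels):
        pres = {sp: True for sp in species_codes}
        if label == "ingroup_specific":
            for sp in cfg.outgroup:
                rng = _stream(seed, f"erase:{sp}:{iv.name}")
                species_codes[sp][iv.start : iv.end] = _random_codes(rng, len(iv))
                pres[sp] = False
        elif label == "decoy":
            for sp in species_codes:
                rng = _stream(seed, f"erase:{sp}:{iv.name}")
                species_codes[sp][iv.start : iv.end] = _random_codes(rng, len(iv))
                pres[sp] = False
        presence[iv.name] = pres

    reference = SeqRecord(ref_chrom, _codes_to_str(ref_codes))
    species_genomes = {
        sp: SeqRecord(ref_chrom, _codes_to_str(codes))
        for sp, codes in species_codes.items()
    }
    elements = [
        SeqRecord(iv.name, reference.sequence[iv.start : iv.end]) for iv in intervals
    ]

    # --- MAF: one substitution-only block per element locus ----------------
    blocks: list[MafBlock] = []
    all_species = sorted(species_codes)
    for iv in intervals:
        rows = [
            MafRow(
                src=ref_src,
                start=iv.start,
                size=len(iv),
                strand="+",
                src_size=cfg.genome_len,
                text=reference.sequence[iv.start : iv.end],
            )
        ]
        for sp in all_species:
            rows.append(
                MafRow(
                    src=f"{sp}.{ref_chrom}",
                    start=iv.start,
                    size=len(iv),
                    strand="+",
                    src_size=cfg.genome_len,
                    text=species_genomes[sp].sequence[iv.start : iv.end],
                )
            )
        blocks.append(MafBlock(tuple(rows)))

    # --- conserved-region call sets -----------------------------------------
    # setA calls element spans exactly; setB re-calls them with jittered
    # boundaries, emulating two constraint callers with imperfect agreement
    set_a = IntervalSet(Interval(ref_chrom, iv.start, iv.end) for iv in intervals)
    jit_rng = _stream(seed, "setB")
    set_b_ivs = []
    for iv in intervals:
        j1 = int(jit_rng.integers(-cfg.region_jitter, cfg.region_jitter + 1))
        j2 = int(jit_rng.integers(-cfg.region_jitter, cfg.region_jitter + 1))
        start = max(0, iv.start + j1)
        end = min(cfg.genome_len, iv.end + j2)
        if end - start >= 30:
            set_b_ivs.append(Interval(ref_chrom, start, end))
    set_b = IntervalSet(set_b_ivs)

    # --- exons: placed in inter-element background --------------------------
    exon_rng = _stream(seed, "exons")
    occupied = sorted((iv.start, iv.end) for iv in intervals)
    exons: list[Interval] = []
    attempts = 0
    while len(exons) < cfg.n_exons and attempts < 50 * cfg.n_exons:
        attempts += 1
        length = int(exon_rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
        start = int(exon_rng.integers(0, cfg.genome_len - length))
        if any(start < e + 50 and s - 50 < start + length for s, e in occupied):
            continue
        if any(start < x.end + 10 and x.start - 10 < start + length for x in exons):
            continue
        exons.append(Interval(ref_chrom, start, start + length, name=f"exon_{len(exons) + 1}"))
    exon_set = IntervalSet(exons)

    # --- transposon annotation ----------------------------------------------
    te_rng = _stream(seed, "transposons")
    repeats: list[RepeatFeature] = []
    te_overlapping: list[str] = []
    non_decoy = [iv for iv, lab in zip(intervals, labels) if lab != "decoy"]
    # a few features planted to overlap an element by >= 30 bp
    for i in range(cfg.n_te_in_elements):
        host = non_decoy[int(te_rng.integers(0, len(non_decoy)))]
        length = 120
        overlap = int(te_rng.integers(30, 80))
        start = max(0, host.start - (length - overlap))
        repeats.append(
            RepeatFeature(
                Interval(ref_chrom, start, start + length, "+", f"planted_te_{i + 1}"),
                "LINE",
                "RTE-BovB",
            )
        )
        if host.name not in te_overlapping:
            te_overlapping.append(host.name)
    # background features, clear of all elements
    blocked = sorted((iv.start - 30, iv.end + 30) for iv in intervals)
    counter = 0
    for cls, count, length in cfg.transposons:
        fam = {"LINE": "L2", "SINE": "MIR", "LTR": "ERVL", "DNA": "hAT-Charlie"}[cls]
        placed = 0
        attempts = 0
        while placed < count and attempts < 50 * count:
            attempts += 1
            start = int(te_rng.integers(0, cfg.genome_len - length))
            if any(start < e and s < start + length for s, e in blocked):
                continue
            counter += 1
            repeats.append(
                RepeatFeature(
                    Interval(ref_chrom, start, start + length, "+", f"te_{counter}"),
                    cls,
                    fam,
                )
            )
            placed += 1

    # --- element locations in outgroup genomes ------------------------------
    # order and spacing mirror the reference (scaled per outgroup), so
    # every consecutive element pair within 1 Mb is a conserved neighbour
    outgroup_locations: dict[str, IntervalSet] = {}
    for og in cfg.outgroup:
        og_rng = _stream(seed, f"og_coords:{og}")
        scale = float(og_rng.uniform(0.8, 1.2))
        offset = int(og_rng.integers(10_000, 50_000))
        ivs = []
        for iv in intervals:
            start = offset + int(iv.start * scale)
            ivs.append(Interval("chr1", start, start + len(iv), name=iv.name))
        outgroup_locations[og] = IntervalSet(ivs)

    # --- truth ---------------------------------------------------------------
    truth_elements = [
        ElementTruth(iv.name, iv, label, presence[iv.name])
        for iv, label in zip(intervals, labels)
    ]
    pairs = [
        (intervals[i].name, intervals[i + 1].name)
        for i in range(len(intervals) - 1)
    ]
    truth = TruthTable(truth_elements, pairs, list(repeats), te_overlapping)

    # --- assembly under test -------------------------------------------------
    if cfg.n_breaks > 0:
        scaffolds = fragment_assembly(
            reference,
            cfg.n_breaks,
            gap_len=cfg.gap_len,
            seed=seed,
            avoid=IntervalSet(intervals),
        )
    else:
        scaffolds = [SeqRecord("scaffold_1", reference.sequence)]

    return SimulatedClade(
        config=cfg,
        reference=reference,
        scaffolds=scaffolds,
        species_genomes=species_genomes,
        elements=elements,
        maf_blocks=blocks,
        conserved_set_a=set_a,
        conserved_set_b=set_b,
        exons=exon_set,
        repeats=repeats,
        outgroup_locations=outgroup_locations,
        truth=truth,
    )


def fragment_assembly(
    reference: SeqRecord,
    n_breaks: int,
    gap_len: int = 100,
    seed: int = 0,
    avoid: IntervalSet | None = None,
    as_gapped_scaffold: bool = False,
) -> list[SeqRecord]:
    """Cut a sequence at ``n_breaks`` uniformly random positions.

    Break positions inside ``avoid`` intervals are resampled, so planted
    elements survive fragmentation intact.  Returns the fragments as
    separate scaffolds, or — with ``as_gapped_scaffold`` — a single scaffold
    with runs of ``gap_len`` Ns at the cut points, so that contig splitting
    at gap runs recovers exactly the fragment lengths.  ``n_breaks == 0``
    returns the input sequence unchanged (under the same naming).
    """
    if n_breaks < 0:
        raise ValueError("n_breaks must be >= 0")
    rng = _stream(seed, f"fragment:{reference.id}:{n_breaks}")
    n = len(reference.sequence)
    forbidden = []
    if avoid is not None:
        forbidden = [(iv.start, iv.end) for iv in avoid if iv.seq_id == reference.id]
    cuts: set[int] = set()
    attempts = 0
    while len(cuts) < n_breaks and attempts < 1000 * max(1, n_breaks):
        attempts += 1
        pos = int(rng.integers(1, n))
        if any(s < pos < e for s, e in forbidden):
            continue
        cuts.add(pos)
    bounds = [0, *sorted(cuts), n]
    pieces = [
        reference.sequence[bounds[i] : bounds[i + 1]]
        for i in range(len(bounds) - 1)
        if bounds[i + 1] > bounds[i]
    ]
    if as_gapped_scaffold:
        return [SeqRecord(reference.id, ("N" * gap_len).join(pieces))]
    return [
        SeqRecord(f"scaffold_{i + 1}", piece) for i, piece in enumerate(pieces)
    ]


def join_with_gaps(scaffolds: Sequence[SeqRecord], gap_len: int = 100, name: str = "joined") -> SeqRecord:
    """Concatenate scaffolds with ``gap_len`` Ns between them."""
    return SeqRecord(name, ("N" * gap_len).join(r.sequence for r in scaffolds))
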