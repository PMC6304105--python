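"""CNE derivation, support windows, lineage classification, repeat overlap."""

import numpy as np
import pytest

from conftest import bitmap_close_gaps, bitmap_of, bitmap_to_intervals, random_interval_set
from cneqc.alignments import MafBlock, MafRow
from cneqc.cne import (
    INGROUP_SPECIFIC,
    SHARED,
    UNCLASSIFIED,
    Cne,
    RepeatFeature,
    classify_lineage,
    compute_support_windows,
    derive_cnes,
    merge_conserved_sets,
    normalize_repeat_class,
    parse_repeatmasker_out,
    species_support_filter,
    transposon_overlap,
    write_repeatmasker_out,
)
from cneqc.intervals import Interval, IntervalSet


def _region(start, end, rid="r1", seq="chr"):
    from cneqc.cne import ConservedRegion

    return ConservedRegion(rid, Interval(seq, start, end), frozenset({"setA"}))


def _cne(start, end, cid="c1", seq="chr"):
    return Cne(cid, Interval(seq, start, end), "r1")


class TestMergeConservedSets:
    def test_cross_set_join_within_gap(self):
        out = merge_conserved_sets(
            IntervalSet([Interval("chr", 0, 20)]),
            IntervalSet([Interval("chr", 25, 60)]),
        )
        assert [(r.interval.start, r.interval.end) for r in out] == [(0, 60)]
        assert out[0].sources == frozenset({"setA", "setB"})

    def test_short_isolated_region_dropped(self):
        out = merge_conserved_sets(
            IntervalSet([Interval("chr", 0, 29)]), IntervalSet([])
        )
        assert out == []

    def test_source_labels_single_set(self):
        out = merge_conserved_sets(
            IntervalSet([Interval("chr", 0, 40)]),
            IntervalSet([Interval("chr", 500, 540)]),
        )
        assert [r.sources for r in out] == [frozenset({"setA"}), frozenset({"setB"})]

    def test_matches_bitmap_union_oracle(self):
        rng = np.random.default_rng(73)
        universe = 5000
        for _ in range(100):
            a = random_interval_set(rng, universe, int(rng.integers(1, 20)))
            b = random_interval_set(rng, universe, int(rng.integers(1, 20)))
            got = [(r.interval.start, r.interval.end)
                   for r in merge_conserved_sets(a, b)]
            bits = bitmap_close_gaps(
                bitmap_of(a, universe) | bitmap_of(b, universe), 10
            )
            expected = [(iv.start, iv.end)
                        for iv in bitmap_to_intervals(bits) if len(iv) >= 30]
            assert got == expected


def _block(ref_text, others, start=0, chrom="chr"):
    rows = [MafRow(f"tegu.{chrom}", start, len(ref_text.replace("-", "")),
                   "+", 100_000, ref_text)]
    for sp, text in others.items():
        rows.append(MafRow(f"{sp}.{chrom}", start, len(text.replace("-", "")),
                           "+", 100_000, text))
    return MafBlock(tuple(rows))


class TestSupportWindows:
    def test_perfect_block_yields_one_window(self):
        text = "ACGT" * 13  # 52 columns
        block = _block(text, {"anole": text}, start=100)
        windows = compute_support_windows([block], "tegu")
        assert [(iv.start, iv.end) for iv in windows["anole"]] == [(100, 152)]

    def test_identity_threshold_boundary(self):
        base = "ACGTA" * 6  # 30 columns

        def flip(text, k):  # substitute the first k columns
            shifted = {"A": "C", "C": "G", "G": "T", "T": "A"}
            return "".join(shifted[c] for c in text[:k]) + text[k:]

        # 13 mismatches -> 17/30 = 56.7% < 60%: no window
        windows = compute_support_windows([_block(base, {"sp": flip(base, 13)})], "tegu")
        assert "sp" not in windows or len(windows["sp"]) == 0
        # 12 mismatches -> 18/30 = 60%: window appears
        windows = compute_support_windows([_block(base, {"sp": flip(base, 12)})], "tegu")
        assert [(iv.start, iv.end) for iv in windows["sp"]] == [(0, 30)]

    def test_missing_reference_row_errors(self):
        block = MafBlock((MafRow("sp.chr", 0, 4, "+", 100, "ACGT"),))
        with pytest.raises(ValueError, match="reference"):
            compute_support_windows([block], "tegu")

    def test_gap_columns_count_as_mismatch_and_skip_ref_positions(self):
        ref = "AAAA" * 10
        other = ref[:35] + "-" * 5
        windows = compute_support_windows([_block(ref, {"sp": other})], "tegu")
        # windows cover reference bases only; the trailing gap run still
        # sits inside >=60% windows so marked columns extend across it
        assert windows["sp"].covered_bases() == 40

    def test_matches_run_enumeration_oracle(self):
        rng = np.random.default_rng(79)
        win = 30
        for _ in range(30):
            n = int(rng.integers(win, 200))
            ref = "".join(rng.choice(list("ACGT"), size=n))
            sp_text = "".join(
                c if rng.random() < 0.7 else str(rng.choice(list("ACGT-")))
                for c in ref
            )
            block = _block(ref, {"sp": sp_text}, start=50)
            got = windows = compute_support_windows([block], "tegu")
            got = [(iv.start, iv.end) for iv in windows.get("sp", IntervalSet())]
            # oracle: enumerate every length-30 column run, mark ref bases
            marked = set()
            eq = [a == b for a, b in zip(ref, sp_text)]
            ref_pos = list(range(50, 50 + n))
            for s in range(n - win + 1):
                if sum(eq[s : s + win]) >= 0.6 * win:
                    marked.update(ref_pos[s : s + win])
            expected = []
            for p in sorted(marked):
                if expected and expected[-1][1] == p:
                    expected[-1] = (expected[-1][0], p + 1)
                else:
                    expected.append((p, p + 1))
            expected = [e for e in expected if e[1] - e[0] >= win]
            assert got == expected


class TestSpeciesSupport:
    def _windows(self, n_species, start=0, end=100):
        return {
            f"sp{i}": IntervalSet([Interval("chr", start, end)])
            for i in range(n_species)
        }

    def test_four_species_boundary_kept(self):
        out = species_support_filter([_region(10, 90)], self._windows(4))
        assert len(out) == 1
        assert out[0].supporting_species == frozenset({"sp0", "sp1", "sp2", "sp3"})

    def test_three_species_dropped(self):
        assert species_support_filter([_region(10, 90)], self._windows(3)) == []

    def test_single_base_overlap_counts_by_default(self):
        windows = {f"sp{i}": IntervalSet([Interval("chr", 0, 11)]) for i in range(4)}
        assert len(species_support_filter([_region(10, 90)], windows)) == 1
        # but not with a stricter overlap requirement
        assert species_support_filter([_region(10, 90)], windows, min_overlap=5) == []


class TestDeriveCnes:
    def test_exon_splits_region(self):
        out = derive_cnes([_region(100, 200)], IntervalSet([Interval("chr", 150, 160)]))
        assert [(c.interval.start, c.interval.end) for c in out] == [(100, 150), (160, 200)]
        assert all(c.parent_region == "r1" for c in out)

    def test_short_fragment_discarded(self):
        out = derive_cnes([_region(100, 200)], IntervalSet([Interval("chr", 100, 175)]))
        assert out == []  # the 25 bp remainder is below the length floor

    def test_no_cne_base_is_exonic(self):
        rng = np.random.default_rng(83)
        universe = 5000
        for _ in range(30):
            regions = [
                _region(iv.start, iv.end, rid=f"r{k}")
                for k, iv in enumerate(random_interval_set(rng, universe, 10).merge(0))
                if len(iv) >= 30
            ]
            exons = random_interval_set(rng, universe, 10)
            cnes = derive_cnes(regions, exons)
            cne_bits = bitmap_of((c.interval for c in cnes), universe)
            exon_bits = bitmap_of(exons, universe)
            region_bits = bitmap_of((r.interval for r in regions), universe)
            assert not (cne_bits & exon_bits).any()
            assert (cne_bits <= region_bits).all()


class TestClassify:
    def _windows(self, n_in, n_out):
        w = {}
        for i in range(n_in):
            w[f"in{i}"] = IntervalSet([Interval("chr", 0, 100)])
        for i in range(n_out):
            w[f"out{i}"] = IntervalSet([Interval("chr", 0, 100)])
        return w

    INGROUP = [f"in{i}" for i in range(9)]
    OUTGROUP = [f"out{i}" for i in range(3)]

    @pytest.mark.parametrize(
        "n_in,n_out,expected",
        [
            (7, 0, INGROUP_SPECIFIC),
            (7, 1, SHARED),
            (5, 0, UNCLASSIFIED),
            (6, 0, INGROUP_SPECIFIC),  # boundary: exactly six ingroup species
            (9, 3, SHARED),
        ],
    )
    def test_rules(self, n_in, n_out, expected):
        (c,) = classify_lineage(
            [_cne(10, 90)], self._windows(n_in, n_out), self.INGROUP, self.OUTGROUP
        )
        assert c.lineage_class == expected

    def test_undeclared_species_errors(self):
        with pytest.raises(ValueError, match="not declared"):
            classify_lineage(
                [_cne(10, 90)], {"mystery": IntervalSet([Interval("chr", 0, 100)])},
                self.INGROUP, self.OUTGROUP,
            )

    def test_overlapping_ingroup_outgroup_errors(self):
        with pytest.raises(ValueError, match="overlap"):
            classify_lineage([], {}, ["a", "b"], ["b"])

    def test_partition_is_exhaustive(self, default_sim):
        sim = default_sim
        regions = merge_conserved_sets(sim.conserved_set_a, sim.conserved_set_b)
        windows = compute_support_windows(sim.maf_blocks, "tegu")
        cnes = derive_cnes(species_support_filter(regions, windows), sim.exons)
        classified = classify_lineage(
            cnes, windows, list(sim.config.ingroup), list(sim.config.outgroup)
        )
        counts = {INGROUP_SPECIFIC: 0, SHARED: 0, UNCLASSIFIED: 0}
        for c in classified:
            counts[c.lineage_class] += 1
        assert sum(counts.values()) == len(classified) == len(cnes)


class TestRepeatMaskerIO:
    def test_coordinate_convention_and_class(self, tmp_path):
        p = tmp_path / "r.out"
        p.write_text(
            "   SW   perc perc perc  query  position in query  matching repeat\n"
            "score   div. del. ins.  sequence begin end (left) repeat class/family begin end (left) ID\n"
            "\n"
            "  239    1.0  0.0  0.0  chr1  101  200  (0)  +  BovB  LINE/RTE-BovB  1  100  (0)  1\n"
        )
        (feat,) = parse_repeatmasker_out(p)
        assert (feat.interval.start, feat.interval.end) == (100, 200)
        assert feat.repeat_class == "LINE" and feat.family == "RTE-BovB"

    def test_simple_repeat_normalized_to_other(self, tmp_path):
        p = tmp_path / "r.out"
        p.write_text(
            "  100  1.0 0.0 0.0  chr1  11  50  (0)  +  (TA)n  Simple_repeat  1  40  (0)  1\n"
        )
        (feat,) = parse_repeatmasker_out(p)
        assert feat.repeat_class == "other"

    def test_uncertainty_marker_stripped(self):
        assert normalize_repeat_class("LINE?/CR1")[0] == "LINE"
        assert normalize_repeat_class("Unknown")[0] == "other"

    def test_malformed_coordinates_error_with_line(self, tmp_path):
        p = tmp_path / "r.out"
        p.write_text("  100  1.0 0.0 0.0  chr1  50  11  (0)  +  x  LINE/L1  1  40  (0)  1\n")
        with pytest.raises(ValueError, match=":1"):
            parse_repeatmasker_out(p)

    def test_round_trip_with_writer(self, tmp_path):
        feats = [
            RepeatFeature(Interval("chr1", 10, 130, "+", "BovB"), "LINE", "RTE-BovB"),
            RepeatFeature(Interval("chr1", 500, 650, "-", "MIR"), "SINE", "MIR"),
            RepeatFeature(Interval("chr2", 0, 99, "+", "hAT1"), "DNA", "hAT-Charlie"),
        ]
        p = tmp_path / "rt.out"
        write_repeatmasker_out(feats, p)
        got = parse_repeatmasker_out(p)
        assert [(f.interval.seq_id, f.interval.start, f.interval.end,
                 f.repeat_class, f.family) for f in got] == \
               [(f.interval.seq_id, f.interval.start, f.interval.end,
                 f.repeat_class, f.family) for f in feats]


class TestTransposonOverlap:
    def _repeat(self, start, end, cls="LINE", seq="chr"):
        return RepeatFeature(Interval(seq, start, end), cls, "fam")

    def test_below_threshold_not_counted(self):
        rep = transposon_overlap([_cne(0, 100)], [self._repeat(80, 140)])
        assert rep.n_cnes_overlapping == 0

    def test_boundary_counted(self):
        rep = transposon_overlap([_cne(0, 100)], [self._repeat(70, 140)])
        assert rep.n_cnes_overlapping == 1 and rep.overlapped_bp == 30
        assert rep.bp_by_class["LINE"] == 30

    def test_non_transposon_classes_ignored(self):
        rep = transposon_overlap([_cne(0, 100)], [self._repeat(0, 100, cls="other")])
        assert rep.n_cnes_overlapping == 0

    def test_per_feature_vs_summed_threshold(self):
        # two features overlapping 20 bp each: per-feature fails, summed passes
        cne = _cne(0, 100)
        reps = [self._repeat(0, 20), self._repeat(80, 140)]
        assert transposon_overlap([cne], reps).n_cnes_overlapping == 0
        assert transposon_overlap([cne], reps, sum_overlaps=True).n_cnes_overlapping == 1

    def test_monotone_in_min_overlap(self):
        rng = np.random.default_rng(89)
        cnes = [_cne(int(s), int(s) + int(l), cid=f"c{i}")
                for i, (s, l) in enumerate(zip(rng.integers(0, 5000, 50),
                                               rng.integers(30, 200, 50)))]
        reps = [self._repeat(int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 5000, 30), rng.integers(20, 300, 30))]
        prev = None
        for thr in (1, 10, 30, 60, 100):
            n = transposon_overlap(cnes, reps, min_overlap=thr).n_cnes_overlapping
            if prev is not None:
                assert n <= prev
            prev = n

    def test_planted_fixture_recovers_expected_hosts(self, default_sim):
        sim = default_sim
        cnes = [
            Cne(e.id, e.interval, "r") for e in sim.truth.elements
            if e.lineage_class != "decoy"
        ]
        rep = transposon_overlap(cnes, sim.repeats)
        assert sorted(rep.overlapping_ids) == sorted(sim.truth.te_overlapping_elements)
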