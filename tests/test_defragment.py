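"""Defragmentation: merging, extraction, consolidation, BED round trip."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyfaidx import Fasta

from evescreen.defragment import (
    bed_to_intervals,
    consolidate,
    extract_locus_sequence,
    loci_to_bed,
    merge_hits,
)
from evescreen.model import Locus, RawHit

from oracles import chain_by_gap, interval_clusters


def _hit(start, end, contig="c", strand="+", probe="p", bits=70.0):
    return RawHit(probe, "t", contig, start, end, strand, bits, 0.0, 90.0, 1, 10)


def _locus(start, end, locus_id=None, contig="c", strand="+", gene=None, n=1):
    return Locus(
        locus_id=locus_id,
        target_file_id="t",
        contig_id=contig,
        start=start,
        end=end,
        strand=strand,
        assigned_gene=gene,
        assigned_taxon="Fam" if gene else None,
        n_merged_hits=n,
    )


class TestMergeHits:
    def test_overlap_union(self):
        loci, changed = merge_hits([], [_hit(100, 200), _hit(150, 250)], 100)
        assert [(l.start, l.end) for l in loci] == [(100, 250)]
        assert loci[0].n_merged_hits == 2
        assert changed == loci

    def test_gap_rule_boundary(self):
        loci, _ = merge_hits([], [_hit(100, 200), _hit(290, 400)], 100)  # gap 89
        assert [(l.start, l.end) for l in loci] == [(100, 400)]
        loci, _ = merge_hits([], [_hit(100, 200), _hit(290, 400)], 50)
        assert [(l.start, l.end) for l in loci] == [(100, 200), (290, 400)]

    def test_strands_never_merge(self):
        loci, _ = merge_hits([], [_hit(100, 200, strand="+"), _hit(150, 250, strand="-")], 100)
        assert len(loci) == 2

    def test_bridging_hit_merges_existing_loci_keeping_lowest_id(self):
        existing = [
            _locus(100, 200, locus_id=5, n=2),
            _locus(400, 500, locus_id=9, n=3),
        ]
        loci, changed = merge_hits(existing, [_hit(190, 410)], 50)
        assert len(loci) == 1
        merged = loci[0]
        assert (merged.start, merged.end, merged.locus_id) == (100, 500, 5)
        assert merged.n_merged_hits == 2 + 3 + 1
        assert changed == [merged]

    def test_idempotence_on_absorbed_hits(self):
        loci1, _ = merge_hits([], [_hit(100, 200), _hit(150, 250)], 100)
        loci1[0].locus_id = 1
        loci2, changed = merge_hits(loci1, [_hit(120, 180)], 100)
        assert changed == []
        assert [(l.start, l.end, l.n_merged_hits) for l in loci2] == [(100, 250, 2)]

    def test_matches_union_find_oracle_on_random_instances(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(1, 60))
            starts = rng.integers(1, 5000, size=n)
            lengths = rng.integers(1, 400, size=n)
            hits = [_hit(int(s), int(s + l)) for s, l in zip(starts, lengths)]
            loci, _ = merge_hits([], hits, 100)
            expected = interval_clusters([h.interval for h in hits], 100)
            assert sorted((l.start, l.end) for l in loci) == expected

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(1, 2000), st.integers(1, 300)),
            min_size=1,
            max_size=30,
        ),
        st.integers(0, 150),
        st.randoms(use_true_random=False),
    )
    def test_order_independence_and_conservation(self, raw, range_nt, pyrandom):
        hits = [_hit(s, s + l) for s, l in raw]
        shuffled = hits[:]
        pyrandom.shuffle(shuffled)
        loci_a, _ = merge_hits([], hits, range_nt)
        loci_b, _ = merge_hits([], shuffled, range_nt)
        assert [(l.start, l.end) for l in loci_a] == [(l.start, l.end) for l in loci_b]
        # conservation: every distinct hit is accounted for exactly once
        assert sum(l.n_merged_hits for l in loci_a) == len(hits)
        # non-redundancy: survivors pairwise separated by more than range_nt
        for a, b in zip(loci_a, loci_a[1:]):
            assert b.start - a.end - 1 > range_nt

    def test_empty_hits_is_identity(self):
        existing = [_locus(10, 50, locus_id=1), _locus(500, 700, locus_id=2)]
        loci, changed = merge_hits(existing, [], 100)
        assert loci == existing and changed == []


class TestExtraction:
    @pytest.fixture()
    def fasta(self, tmp_path):
        path = tmp_path / "g.fasta"
        path.write_text(">c\nATGCATGCAT\n")
        return Fasta(str(path))

    def test_whole_contig_identity(self, fasta):
        assert extract_locus_sequence(_locus(1, 10), fasta) == "ATGCATGCAT"

    def test_minus_strand_reverse_complement(self, fasta):
        assert extract_locus_sequence(_locus(1, 4, strand="-"), fasta) == "GCAT"

    def test_out_of_bounds_names_contig(self, fasta):
        with pytest.raises(IndexError, match="'c'"):
            extract_locus_sequence(_locus(5, 11), fasta)


class TestConsolidate:
    def test_adjacent_genes_form_structure(self):
        loci = [
            _locus(100, 600, locus_id=1, gene="NP"),
            _locus(700, 1500, locus_id=2, gene="L"),
        ]
        entries = consolidate(loci, 200)  # gap 99 <= 200
        assert len(entries) == 1
        e = entries[0]
        assert e.structure == "NP(+)-L(+)"
        assert (e.span_start, e.span_end) == (100, 1500)
        assert e.member_locus_ids == (1, 2)

    def test_distance_too_small_keeps_singletons(self):
        loci = [
            _locus(100, 600, locus_id=1, gene="NP"),
            _locus(700, 1500, locus_id=2, gene="L"),
        ]
        entries = consolidate(loci, 50)
        assert [e.structure for e in entries] == ["NP(+)", "L(+)"]

    def test_unclassified_locus_rejected(self):
        with pytest.raises(ValueError, match="unclassified"):
            consolidate([_locus(1, 10, locus_id=1)], 100)

    def test_matches_chaining_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(1, 20))
            starts = np.sort(rng.choice(np.arange(1, 20000, 50), size=n, replace=False))
            loci = [
                _locus(int(s), int(s + rng.integers(10, 400)), locus_id=i + 1, gene="G")
                for i, s in enumerate(starts)
            ]
            distance = int(rng.integers(0, 500))
            entries = consolidate(loci, distance)
            expected = chain_by_gap([(l.start, l.end) for l in loci], distance)
            got = [
                [loci.index(next(l for l in loci if l.locus_id == lid)) for lid in e.member_locus_ids]
                for e in entries
            ]
            assert got == expected


class TestBedRoundTrip:
    def test_zero_based_half_open_conversion(self, tmp_path):
        loci = [_locus(1, 10, locus_id=1, gene="G"), _locus(101, 250, locus_id=2, gene="G", strand="-")]
        bed = tmp_path / "loci.bed"
        assert loci_to_bed(loci, bed) == 2
        lines = bed.read_text().strip().split("\n")
        assert lines[0].split("\t")[1:3] == ["0", "10"]
        back = bed_to_intervals(bed)
        assert back == [("c", 1, 10, "+"), ("c", 101, 250, "-")]
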