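"""EVE analytics: flags, degradation, ORFs, orthology, dating, rates, names, summaries."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from evescreen import analysis
from evescreen.analysis import (
    LocusRecord,
    compute_filter_flags,
    detect_degradation,
    estimate_min_age,
    find_orfs,
    format_nomenclature,
    infiltration_rate,
    parse_nomenclature,
    resolve_orthology,
    sampled_branch_length,
    summarize_counts,
)
from evescreen.fixtures import back_translate, random_protein, _mutate_protein
from evescreen.model import Locus, NomenclatureID, ScreenConfig

from oracles import all_pairs_mrca_depth, six_frame_orfs


def _tree(newick: str) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    t.is_rooted = True
    return t


def _locus(identity=75.0, start=500, end=1300, seq=None, contig_len=10_000):
    seq = seq or "ACGTACGTA" * ((end - start + 1) // 9 + 1)
    seq = seq[: end - start + 1]
    return Locus(
        locus_id=1,
        target_file_id="t",
        contig_id="c",
        start=start,
        end=end,
        strand="+",
        extracted_sequence=seq,
        assigned_taxon="Fam",
        assigned_gene="N",
        classification_identity=identity,
    )


class TestFilterFlags:
    def test_all_three_exogenous_rules_fire(self):
        rng = np.random.default_rng(0)
        aa = random_protein(60, rng)
        seq = back_translate(aa, rng)
        locus = _locus(identity=99.2, start=1, end=len(seq), seq=seq, contig_len=len(seq))
        flags = compute_filter_flags(locus, contig_length=len(seq), reference_aa=aa)
        assert flags.high_identity_to_known_virus
        assert flags.lacks_flanks
        assert flags.intact_coding
        assert flags.putative_exogenous

    def test_degraded_central_locus_is_not_exogenous(self):
        rng = np.random.default_rng(1)
        aa = random_protein(60, rng)
        seq = list(back_translate(aa, rng))
        seq[30:33] = "TAA"
        seq[90:93] = "TAG"
        seq = "".join(seq)
        locus = _locus(identity=75.0, start=500, end=499 + len(seq), seq=seq)
        flags = compute_filter_flags(locus, contig_length=10_000, reference_aa=aa)
        assert not flags.high_identity_to_known_virus
        assert not flags.lacks_flanks
        assert not flags.intact_coding
        assert not flags.putative_exogenous

    def test_nonhost_virus_group_flag_from_side_data(self):
        locus = _locus()
        flags = compute_filter_flags(
            locus,
            contig_length=10_000,
            host_kingdom="Animalia",
            virus_host_kingdom="Plantae",  # e.g. a geminivirus-like match
        )
        assert flags.nonhost_virus_group

    def test_missing_contig_length_is_integrity_error(self):
        with pytest.raises(LookupError):
            compute_filter_flags(_locus(), contig_length=None)


class TestDetectDegradation:
    def test_intact_back_translation(self):
        rng = np.random.default_rng(3)
        aa = random_protein(80, rng)
        assert detect_degradation(back_translate(aa, rng), aa) == (0, 0)

    def test_one_inserted_in_frame_stop(self):
        rng = np.random.default_rng(3)
        aa = random_protein(80, rng)
        nt = back_translate(aa, rng)
        nt = nt[:120] + "TAA" + nt[120:]
        assert detect_degradation(nt, aa) == (1, 0)

    def test_one_single_nt_deletion(self):
        rng = np.random.default_rng(3)
        aa = random_protein(80, rng)
        nt = back_translate(aa, rng)
        nt = nt[:121] + nt[122:]
        assert detect_degradation(nt, aa) == (0, 1)

    def test_no_alignable_region_warns_and_returns_null(self):
        with pytest.warns(UserWarning):
            assert detect_degradation("AC", "MKVLF") == (None, None)


class TestFindOrfs:
    def _construct(self, n_sense=299):
        rng = np.random.default_rng(6)
        body = back_translate(random_protein(n_sense, rng), rng)
        return "ATG" + body + "TAA"

    def test_boundary_arithmetic_at_300_aa(self):
        seq = self._construct(299)  # ATG + 299 sense codons + TAA = 903 nt
        assert len(seq) == 903
        orfs = [o for o in find_orfs(seq, 300, kinds=("atg_initiated",)) if o.strand == "+"]
        assert len(orfs) == 1
        orf = orfs[0]
        assert orf.length_aa == 300
        assert (orf.start, orf.end) == (1, 903)
        assert find_orfs(seq, 301, kinds=("atg_initiated",)) == []

    def test_reverse_complement_same_orf_minus_strand(self):
        from evescreen.search import reverse_complement

        seq = self._construct(299)
        orfs = find_orfs(reverse_complement(seq), 300, kinds=("atg_initiated",))
        assert len(orfs) == 1
        assert orfs[0].strand == "-"
        assert orfs[0].length_aa == 300

    def test_matches_exhaustive_six_frame_oracle(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        for min_len in (20, 50):
            got = {
                (o.strand, o.frame, o.start, o.end, o.length_aa, o.kind)
                for o in find_orfs(seq, min_len)
            }
            assert got == six_frame_orfs(seq, min_len)

    def test_empty_sequence(self):
        assert find_orfs("", 10) == []


class TestResolveOrthology:
    def _records(self, seqs_species, taxon="FamV"):
        return [
            LocusRecord(i + 1, sp, taxon, seq) for i, (seq, sp) in enumerate(seqs_species)
        ]

    def test_shared_ancestral_insertion_forms_one_group(self):
        rng = np.random.default_rng(0)
        ancestral = back_translate(random_protein(150, rng), rng)
        a = _mutate_nt(ancestral, 0.02, rng)
        b = _mutate_nt(ancestral, 0.02, rng)
        groups = resolve_orthology(self._records([(a, "sp_a"), (b, "sp_b")]))
        assert len(groups) == 1
        assert groups[0].host_species == {"sp_a", "sp_b"}

    def test_distant_independent_insertions_stay_separate(self):
        rng = np.random.default_rng(1)
        aa = random_protein(150, rng)
        # independent back-translations + heavy divergence: identity << 80%
        a = _mutate_nt(back_translate(aa, rng), 0.30, rng)
        b = _mutate_nt(back_translate(aa, rng), 0.30, rng)
        from evescreen.analysis import _identity_pct

        assert _identity_pct(a, b) < 80.0  # oracle premise for this case
        groups = resolve_orthology(self._records([(a, "sp_a"), (b, "sp_z")]))
        assert len(groups) == 2

    def test_converged_state_is_a_fixed_point(self):
        rng = np.random.default_rng(2)
        seqs = [
            (back_translate(random_protein(120, rng), rng), f"sp_{i}") for i in range(4)
        ]
        records = self._records(seqs)
        groups1 = resolve_orthology(records)
        groups2 = resolve_orthology(records)
        assert [(g.group_id, sorted(g.member_loci)) for g in groups1] == [
            (g.group_id, sorted(g.member_loci)) for g in groups2
        ]

    def test_host_clade_constraint_blocks_cross_order_joining(self):
        rng = np.random.default_rng(3)
        seq = back_translate(random_protein(120, rng), rng)
        records = self._records([(seq, "sp_a"), (seq, "sp_far")])
        clades = {"sp_a": "Chiroptera", "sp_far": "Cypriniformes"}
        groups = resolve_orthology(records, host_clades=clades)
        assert len(groups) == 2
        # without clade data the identical sequences group together
        assert len(resolve_orthology(records)) == 1

    def test_event_count_bounded_by_locus_count(self):
        rng = np.random.default_rng(4)
        records = self._records(
            [(back_translate(random_protein(100, rng), rng), f"sp_{i}") for i in range(5)]
        )
        groups = resolve_orthology(records)
        assert len(groups) <= len(records)
        assert sum(g.n_members for g in groups) == len(records)


def _mutate_nt(nt, rate, rng):
    out = list(nt)
    mask = rng.random(len(out)) < rate
    for i in np.nonzero(mask)[0]:
        out[i] = [b for b in "ACGT" if b != out[i]][rng.integers(3)]
    return "".join(out)


class TestMinAge:
    TREE = "((A:96,B:96):104,(C:30,D:30):170);"

    def test_two_member_group_reads_mrca_depth(self):
        assert estimate_min_age(["A", "B"], _tree(self.TREE)) == pytest.approx(96.0)

    def test_single_species_group_has_no_age(self):
        assert estimate_min_age(["A"], _tree(self.TREE)) is None

    def test_missing_species_named_in_error(self):
        with pytest.raises(KeyError, match="Zz"):
            estimate_min_age(["A", "Zz"], _tree(self.TREE))

    def test_caterpillar_equals_all_pairs_oracle(self):
        newick = "((((A:10,B:10):10,C:20):10,D:30):10,E:40);"
        tree = _tree(newick)
        for members in (["A", "B", "C"], ["A", "C", "E"], ["B", "D"]):
            oracle = all_pairs_mrca_depth(_tree(newick), members)
            assert estimate_min_age(members, tree) == pytest.approx(oracle)

    def test_monotone_in_membership(self):
        tree = _tree(self.TREE)
        age_ab = estimate_min_age(["A", "B"], tree)
        age_abc = estimate_min_age(["A", "B", "C"], tree)
        assert age_abc >= age_ab


class TestInfiltrationRate:
    BALANCED = "((A:10,B:10):10,(C:10,D:10):10);"

    def _groups(self, n, family="FamV", species=("A",)):
        return [
            analysis.OrthologGroup(
                group_id=f"{family}.{i+1}",
                numeric_id=i + 1,
                virus_taxon=family,
                member_loci=[(i + 1, sp) for sp in species],
                reference_sequence="ACGT",
            )
            for i in range(n)
        ]

    def test_closed_form_three_events_per_hundred_my(self):
        tree = _tree("(A:50,B:50);")  # spanning subtree: 50 + 50 = 100 MY
        classes = {"A": "Mammalia", "B": "Mammalia"}
        est = infiltration_rate(
            self._groups(3, species=("A", "B")), "Mammalia", "FamV", tree, classes
        )
        assert est.branch_length_my == pytest.approx(100.0)
        assert est.rate_per_my == pytest.approx(0.03)

    def test_zero_events_is_rate_zero(self):
        tree = _tree(self.BALANCED)
        classes = {t: "Aves" for t in "ABCD"}
        est = infiltration_rate([], "Aves", "FamV", tree, classes)
        assert est.rate_per_my == 0.0 and est.n_events == 0

    def test_balanced_tree_hand_summed_edges(self):
        tree = _tree(self.BALANCED)
        classes = {t: "Aves" for t in "ABCD"}
        assert sampled_branch_length(tree, list("ABCD")) == pytest.approx(60.0)
        est = infiltration_rate(
            self._groups(6, species=("A",)), "Aves", "FamV", tree, classes
        )
        assert est.rate_per_my == pytest.approx(0.1)

    def test_rate_identity(self):
        tree = _tree(self.BALANCED)
        classes = {t: "Aves" for t in "ABCD"}
        est = infiltration_rate(self._groups(4, species=("A", "C")), "Aves", "FamV", tree, classes)
        assert est.rate_per_my * est.branch_length_my == pytest.approx(est.n_events)


class TestNomenclature:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("EBLL-Cultervirus.29-EptFus", ("EBLL", "Cultervirus", 29, "EptFus")),
            ("eflp-filo.1-Myotis", ("eflp", "filo", 1, "Myotis")),
        ],
    )
    def test_parse_known_identifiers(self, text, expected):
        nid = parse_nomenclature(text)
        assert (nid.classifier, nid.virus_taxon, nid.numeric_id, nid.distribution) == expected

    @pytest.mark.parametrize("text", ["EBLL-Cultervirus.29-EptFus", "eflp-filo.1-Myotis"])
    def test_round_trip(self, text):
        assert format_nomenclature(parse_nomenclature(text)) == text

    @pytest.mark.parametrize("bad", ["noseparators", "a-b-c", "x-y.z-w", "-a.1-b"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_nomenclature(bad)

    def test_fields_may_not_contain_dots(self):
        with pytest.raises(ValueError):
            NomenclatureID("E.V", "filo", 1, "Myotis")


class TestSummaries:
    def test_grouped_counts_on_constructed_table(self):
        df = pd.DataFrame({"family": ["X"] * 6 + ["Y"] * 4, "n_loci": [1] * 10})
        out = summarize_counts(df, ["family"])
        assert dict(zip(out["family"], out["total"])) == {"X": 6, "Y": 4}

    def test_partition_totals_conserved(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {
                "family": rng.choice(["X", "Y", "Z"], size=50),
                "host": rng.choice(["m", "a"], size=50),
                "n_loci": rng.integers(1, 10, size=50),
            }
        )
        total = df["n_loci"].sum()
        for cols in (["family"], ["host"], ["family", "host"]):
            assert summarize_counts(df, cols)["total"].sum() == total

    def test_per_genome_average_rounding(self):
        df = pd.DataFrame(
            {"host_class": ["Amphibia"], "n_loci": [17319], "n_genomes": [34]}
        )
        out = summarize_counts(df, ["host_class"], genomes_col="n_genomes")
        assert out["per_genome_average"].iloc[0] == 509.38

    def test_missing_grouping_column_is_an_error(self):
        with pytest.raises(KeyError):
            summarize_counts(pd.DataFrame({"n_loci": [1]}), ["family"])
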