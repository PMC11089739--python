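"""Search backends, coordinate mapping, and restart bookkeeping."""

import shutil

import numpy as np
import pytest

from evescreen.config import init_project
from evescreen.fixtures import back_translate, random_protein
from evescreen.model import Probe, ScreenConfig, TargetFile
from evescreen.search import (
    BlastBackend,
    NaiveBackend,
    SearchTask,
    bits_from_score,
    enumerate_pending,
    mark_done,
    naive_translated_search,
    reverse_complement,
    run_search,
)
from evescreen.store import Project

from oracles import smith_waterman_score


class TestNaiveTranslatedSearch:
    def test_exact_back_translation_maps_to_expected_interval(self):
        rng = np.random.default_rng(0)
        aa = random_protein(20, rng)
        nt = back_translate(aa, rng)
        contig = "A" * 100 + nt + "C" * 140
        hits = naive_translated_search(aa, contig)
        assert hits, "exact match must be found"
        best = hits[0]
        # 20 aa at nt offset 100: [101, 101 + 3*20 - 1] on the plus strand
        assert (best.subject_start, best.subject_end, best.strand) == (101, 160, "+")
        assert best.pct_identity == 100.0

    def test_reverse_strand_symmetry(self):
        rng = np.random.default_rng(0)
        aa = random_protein(20, rng)
        nt = back_translate(aa, rng)
        contig = "A" * 100 + nt + "C" * 140
        rc = reverse_complement(contig)
        hits = naive_translated_search(aa, rc)
        best = hits[0]
        # same element, opposite orientation: interval maps back symmetrically
        assert best.strand == "-"
        assert (len(contig) - best.subject_end + 1, len(contig) - best.subject_start + 1) == (
            101,
            160,
        )

    def test_no_hits_on_random_target_confirmed_by_oracle(self):
        """A short random probe finds nothing above threshold in a random
        contig — and the exhaustive Smith-Waterman oracle agrees that no
        local alignment reaches the reporting threshold in any frame."""
        rng = np.random.default_rng(1)
        probe = random_protein(15, rng)
        contig = "".join(rng.choice(list("ACGT"), size=300))
        cfg = ScreenConfig()
        hits = naive_translated_search(probe, contig, cfg)
        assert hits == []
        from evescreen.search import translate_frame

        for seq in (contig, reverse_complement(contig)):
            for frame in range(3):
                score = smith_waterman_score(probe, translate_frame(seq, frame))
                assert bits_from_score(score, cfg.lam, cfg.k) < cfg.min_report_bits

    def test_short_contig_yields_nothing(self):
        assert naive_translated_search("MKV", "AC") == []

    def test_scores_match_quadratic_oracle(self):
        """Engine scores equal an independent Gotoh DP on random pairs."""
        from Bio.Align import PairwiseAligner

        from evescreen.search import _aa_aligner

        cfg = ScreenConfig()
        aligner = _aa_aligner(cfg)
        rng = np.random.default_rng(7)
        for _ in range(30):
            q = random_protein(int(rng.integers(8, 16)), rng)
            s = random_protein(int(rng.integers(25, 60)), rng)
            assert aligner.score(q, s) == pytest.approx(smith_waterman_score(q, s))


def _single_target_project(tmp_path, contig: str, probes: list[Probe]):
    tdb = tmp_path / "tdb" / "sp_x" / "complete" / "v1"
    tdb.mkdir(parents=True)
    fasta = tdb / "sp_x.fasta"
    fasta.write_text(">c1\n" + contig + "\n")
    project = Project(tmp_path / "p.sqlite")
    target = TargetFile("sp_x", "v1", "complete", "sp_x/complete/v1/sp_x.fasta", str(fasta), (("c1", len(contig)),))
    project.register_targets([target])
    project.register_probes(probes)
    return project, target


class TestBackendCrossCheck:
    @pytest.mark.skipif(shutil.which("tblastn") is None, reason="BLAST+ not installed")
    def test_blast_and_naive_agree_on_exact_implant(self, tmp_path):
        rng = np.random.default_rng(3)
        aa = random_protein(80, rng)
        nt = back_translate(aa, rng)
        background = "".join(rng.choice(list("ACGT"), size=2000))
        contig = background[:1000] + nt + background[1000:]
        probe = Probe("VirusX_N", "VirusX", "N", "aa", aa)
        project, target = _single_target_project(tmp_path, contig, [probe])
        cfg = ScreenConfig()
        task_naive = SearchTask(probe, target, "naive", "d0")
        task_blast = SearchTask(probe, target, "tblastn", "d1")
        naive_hits = run_search(task_naive, NaiveBackend(cfg), cfg)
        blast_hits = run_search(task_blast, BlastBackend(cfg), cfg)
        assert naive_hits and blast_hits
        na, bl = naive_hits[0], blast_hits[0]
        assert (na.subject_start, na.subject_end, na.strand) == (
            bl.subject_start,
            bl.subject_end,
            bl.strand,
        ) == (1001, 1240, "+")


class TestEnumerationAndStatus:
    def _project(self, small_fixture):
        control, _ = small_fixture
        project, cfg = init_project(control)
        return project, cfg.screen

    def test_cartesian_product_then_resume(self, small_fixture):
        project, screen_cfg = self._project(small_fixture)
        tasks = enumerate_pending(project, screen_cfg, "naive")
        assert len(tasks) == 4  # 2 probes x 2 targets
        for task in tasks:
            mark_done(project, task)
        assert enumerate_pending(project, screen_cfg, "naive") == []

    def test_new_target_reopens_only_new_pairs(self, small_fixture, tmp_path):
        project, screen_cfg = self._project(small_fixture)
        for task in enumerate_pending(project, screen_cfg, "naive"):
            mark_done(project, task)
        fasta_dir = tmp_path / "extra" / "sp_c" / "complete" / "v1"
        fasta_dir.mkdir(parents=True)
        (fasta_dir / "sp_c.fasta").write_text(">c1\n" + "ACGT" * 50 + "\n")
        project.register_targets(
            [TargetFile("sp_c", "v1", "complete", "sp_c/complete/v1/sp_c.fasta",
                        str(fasta_dir / "sp_c.fasta"), (("c1", 200),))]
        )
        pending = enumerate_pending(project, screen_cfg, "naive")
        assert len(pending) == 2  # one per probe, only for the new target
        assert {t.target.file_id for t in pending} == {"sp_c/complete/v1/sp_c.fasta"}

    def test_parameter_change_reopens_everything(self, small_fixture):
        project, screen_cfg = self._project(small_fixture)
        for task in enumerate_pending(project, screen_cfg, "naive"):
            mark_done(project, task)
        changed = screen_cfg.with_overrides(gap_open=9)
        assert len(enumerate_pending(project, changed, "naive")) == 4

    def test_double_mark_is_single_record(self, small_fixture):
        project, screen_cfg = self._project(small_fixture)
        task = enumerate_pending(project, screen_cfg, "naive")[0]
        mark_done(project, task)
        mark_done(project, task)
        n = project.query(
            "SELECT COUNT(*) n FROM searches WHERE probe_id = ?", [task.probe.probe_id]
        )
        per_target = project.query(
            "SELECT COUNT(*) n FROM searches WHERE probe_id=? AND target_file_id=?",
            [task.probe.probe_id, task.target.file_id],
        )
        assert per_target["n"].iloc[0] == 1

    def test_marking_unknown_task_is_an_error(self, small_fixture):
        project, _ = self._project(small_fixture)
        with pytest.raises(LookupError):
            project.mark_search_done("ghost_probe", "ghost_target", "naive", "d")
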