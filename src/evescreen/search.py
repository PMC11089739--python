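"""Similarity-search execution: task enumeration, backends, restart bookkeeping.

Two interchangeable backends satisfy the same contract (``run(task) -> list
of RawHit``):

* :class:`BlastBackend` shells out to NCBI BLAST+ (``tblastn`` for amino-acid
  probes, ``blastn`` for nucleotide probes) with tabular output, formatting
  target databases lazily and caching the index beside the FASTA.
* :class:`NaiveBackend` is an in-process engine that runs a Smith–Waterman
  local alignment of the probe against all six translation frames of each
  contig (or against both strands for nucleotide probes).  Raw scores S are
  converted to bitscores via ``b = (lambda*S - ln K) / ln 2``; e-values are
  not computed (reported as 0 with the filtering done on bitscore, which is
  the screening currency throughout).

Every completed probe x target search is recorded in the status table with a
digest of the search parameters, so screening restarts non-redundantly and
any parameter change forces a re-screen.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .model import Probe, RawHit, ScreenConfig, TargetFile, parameter_digest
from .store import Project

__all__ = [
    "SearchTask",
    "NaiveBackend",
    "BlastBackend",
    "enumerate_pending",
    "run_search",
    "mark_done",
    "naive_translated_search",
    "select_backend",
    "reverse_complement",
    "translate_frame",
]


class SearchError(RuntimeError):
    """A backend failed; carries the tool's stderr where available."""


class EnvironmentError_(RuntimeError):
    """A required external executable is missing."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_frame(nt: str, frame: int) -> str:
    """Translate one forward frame (0-2), trimming to a codon multiple.

    Residues outside the scoring alphabet are replaced by ``X`` (zero-score
    columns under the screening matrix).
    """
    sub = nt[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    aa = str(Seq(sub).translate())
    return "".join(c if c in _MATRIX_ALPHABET else "X" for c in aa)


@lru_cache(maxsize=None)
def _protein_matrix():
    """BLOSUM62 with the X row/column zeroed (unknown residues score 0)."""
    m = substitution_matrices.load("BLOSUM62")
    for c in m.alphabet:
        m["X", c] = 0.0
        m[c, "X"] = 0.0
    return m


_MATRIX_ALPHABET = set(substitution_matrices.load("BLOSUM62").alphabet)


def _clean_aa(seq: str) -> str:
    return "".join(c if c in _MATRIX_ALPHABET else "X" for c in seq.upper())


def _clean_nt(seq: str) -> str:
    return "".join(c if c in "ACGT" else "N" for c in seq.upper())


@dataclass(frozen=True)
class SearchTask:
    probe: Probe
    target: TargetFile
    algorithm: str
    digest: str


def bits_from_score(score: float, lam: float, k: float) -> float:
    return (lam * score - math.log(k)) / math.log(2)


def _aa_aligner(config: ScreenConfig) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _protein_matrix()
    # affine gaps: a gap of length k costs open + k*extend
    aligner.open_gap_score = -(config.gap_open + config.gap_extend)
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def _nt_aligner(config: ScreenConfig) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = config.nt_match
    aligner.mismatch_score = config.nt_mismatch
    aligner.open_gap_score = -(config.nt_gap_open + config.nt_gap_extend)
    aligner.extend_gap_score = -config.nt_gap_extend
    return aligner


def best_local_alignment(aligner: PairwiseAligner, query: str, subject: str):
    """Best local alignment of query vs subject.

    Returns ``(score, q0, q1, s0, s1, pct_identity)`` with 0-based half-open
    coordinates, or ``None`` when no positive-scoring alignment exists.
    """
    if not query or not subject:
        return None
    score = aligner.score(query, subject)
    if score <= 0:
        return None
    aln = next(iter(aligner.align(query, subject)))
    qblocks, sblocks = aln.aligned
    if len(qblocks) == 0:
        return None
    q0, q1 = int(qblocks[0][0]), int(qblocks[-1][1])
    s0, s1 = int(sblocks[0][0]), int(sblocks[-1][1])
    matches = 0
    columns = 0
    for (qa, qb), (sa, sb) in zip(qblocks, sblocks):
        for i in range(qb - qa):
            columns += 1
            if query[qa + i] == subject[sa + i]:
                matches += 1
    # count gap columns between blocks toward alignment length
    for idx in range(1, len(qblocks)):
        columns += (qblocks[idx][0] - qblocks[idx - 1][1]) + (
            sblocks[idx][0] - sblocks[idx - 1][1]
        )
    identity = 100.0 * matches / columns if columns else 0.0
    return float(score), q0, q1, s0, s1, identity


def naive_translated_search(
    probe_aa: str,
    contig_nt: str,
    config: ScreenConfig | None = None,
    *,
    probe_id: str = "probe",
    target_file_id: str = "target",
    contig_id: str = "contig",
) -> list[RawHit]:
    """Smith–Waterman search of an amino-acid probe against all six frames.

    Frame coordinates are mapped back to 1-based inclusive nucleotide
    coordinates on the forward strand of the contig; matches found on the
    reverse-complement frames are reported with strand ``-``.  Contigs
    shorter than one codon yield no hits.
    """
    config = config or ScreenConfig()
    if len(contig_nt) < 3:
        return []
    probe_aa = _clean_aa(probe_aa)
    contig_nt = _clean_nt(contig_nt)
    aligner = _aa_aligner(config)
    L = len(contig_nt)
    hits = []
    for strand, seq in (("+", contig_nt), ("-", reverse_complement(contig_nt))):
        for frame in range(3):
            aa = translate_frame(seq, frame)
            res = best_local_alignment(aligner, probe_aa, aa)
            if res is None:
                continue
            score, q0, q1, s0, s1, identity = res
            bits = bits_from_score(score, config.lam, config.k)
            if bits < config.min_report_bits:
                continue
            nt_start = frame + 3 * s0 + 1
            nt_end = frame + 3 * s1
            if strand == "-":
                nt_start, nt_end = L - nt_end + 1, L - nt_start + 1
            hits.append(
                RawHit(
                    probe_id=probe_id,
                    target_file_id=target_file_id,
                    contig_id=contig_id,
                    subject_start=nt_start,
                    subject_end=nt_end,
                    strand=strand,
                    bitscore=round(bits, 2),
                    evalue=0.0,
                    pct_identity=round(identity, 2),
                    query_start=q0 + 1,
                    query_end=q1,
                )
            )
    hits.sort(key=lambda h: (-h.bitscore, h.contig_id, h.subject_start))
    return hits


def naive_nucleotide_search(
    probe_nt: str,
    contig_nt: str,
    config: ScreenConfig | None = None,
    *,
    probe_id: str = "probe",
    target_file_id: str = "target",
    contig_id: str = "contig",
) -> list[RawHit]:
    """Smith–Waterman search of a nucleotide probe against both strands."""
    config = config or ScreenConfig()
    if not contig_nt:
        return []
    probe_nt = _clean_nt(probe_nt)
    contig_nt = _clean_nt(contig_nt)
    aligner = _nt_aligner(config)
    L = len(contig_nt)
    hits = []
    for strand, seq in (("+", contig_nt), ("-", reverse_complement(contig_nt))):
        res = best_local_alignment(aligner, probe_nt, seq)
        if res is None:
            continue
        score, q0, q1, s0, s1, identity = res
        bits = bits_from_score(score, config.nt_lam, config.nt_k)
        if bits < config.min_report_bits:
            continue
        nt_start, nt_end = s0 + 1, s1
        if strand == "-":
            nt_start, nt_end = L - nt_end + 1, L - nt_start + 1
        hits.append(
            RawHit(
                probe_id=probe_id,
                target_file_id=target_file_id,
                contig_id=contig_id,
                subject_start=nt_start,
                subject_end=nt_end,
                strand=strand,
                bitscore=round(bits, 2),
                evalue=0.0,
                pct_identity=round(identity, 2),
                query_start=q0 + 1,
                query_end=q1,
            )
        )
    hits.sort(key=lambda h: (-h.bitscore, h.contig_id, h.subject_start))
    return hits


class NaiveBackend:
    """In-process search backend (hermetic; no external tools)."""

    name = "naive"

    def __init__(self, config: ScreenConfig | None = None):
        self.config = config or ScreenConfig()

    def run(self, task: SearchTask) -> list[RawHit]:
        from pyfaidx import Fasta

        idx = Fasta(task.target.path, rebuild=False)
        hits: list[RawHit] = []
        search = (
            naive_translated_search
            if task.probe.molecule == "aa"
            else naive_nucleotide_search
        )
        for contig_id in idx.keys():
            contig = str(idx[contig_id][:])
            hits.extend(
                search(
                    task.probe.sequence,
                    contig,
                    self.config,
                    probe_id=task.probe.probe_id,
                    target_file_id=task.target.file_id,
                    contig_id=contig_id,
                )
            )
        return hits


_BLAST_FIELDS = "qseqid sseqid qstart qend sstart send bitscore evalue pident"


class BlastBackend:
    """NCBI BLAST+ backend (tblastn for aa probes, blastn for nt probes).

    Target FASTA files are formatted with ``makeblastdb`` on first use; the
    index is cached beside the FASTA.  Subject coordinates arriving inverted
    (sstart > send) are interpreted as minus-strand matches and normalised to
    ``start <= end`` with an explicit strand flag.
    """

    name = "blast"

    def __init__(self, config: ScreenConfig | None = None):
        self.config = config or ScreenConfig()
        for exe in ("makeblastdb", "tblastn", "blastn"):
            if shutil.which(exe) is None:
                raise EnvironmentError_(f"BLAST+ executable {exe!r} not found on PATH")

    @staticmethod
    def _ensure_db(fasta_path: str) -> None:
        fasta = Path(fasta_path)
        if (fasta.parent / (fasta.name + ".nin")).exists():
            return
        proc = subprocess.run(
            ["makeblastdb", "-in", str(fasta), "-dbtype", "nucl"],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise SearchError(f"makeblastdb failed: {proc.stderr}")

    def run(self, task: SearchTask) -> list[RawHit]:
        self._ensure_db(task.target.path)
        program = "tblastn" if task.probe.molecule == "aa" else "blastn"
        with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as qf:
            qf.write(f">{task.probe.probe_id}\n{task.probe.sequence}\n")
            query_path = qf.name
        try:
            proc = subprocess.run(
                [
                    program,
                    "-query", query_path,
                    "-db", task.target.path,
                    "-outfmt", f"6 {_BLAST_FIELDS}",
                    "-evalue", str(self.config.evalue_ceiling),
                ],
                capture_output=True,
                text=True,
            )
        finally:
            Path(query_path).unlink(missing_ok=True)
        if proc.returncode != 0:
            raise SearchError(f"{program} failed: {proc.stderr}")
        return self._parse_tabular(proc.stdout, task)

    @staticmethod
    def _parse_tabular(text: str, task: SearchTask) -> list[RawHit]:
        hits = []
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise SearchError(f"unparseable tabular line: {line!r}")
            qseqid, sseqid, qstart, qend, sstart, send, bitscore, evalue, pident = fields
            s0, s1 = int(sstart), int(send)
            strand = "+" if s0 <= s1 else "-"
            if strand == "-":
                s0, s1 = s1, s0
            hits.append(
                RawHit(
                    probe_id=qseqid,
                    target_file_id=task.target.file_id,
                    contig_id=sseqid,
                    subject_start=s0,
                    subject_end=s1,
                    strand=strand,
                    bitscore=float(bitscore),
                    evalue=float(evalue),
                    pct_identity=float(pident),
                    query_start=int(qstart),
                    query_end=int(qend),
                )
            )
        return hits


def select_backend(name: str, config: ScreenConfig):
    """Resolve a backend name (``naive``, ``blast`` or ``auto``)."""
    if name == "naive":
        return NaiveBackend(config)
    if name == "blast":
        return BlastBackend(config)
    if name == "auto":
        try:
            return BlastBackend(config)
        except EnvironmentError_:
            return NaiveBackend(config)
    raise ValueError(f"unknown backend {name!r}")


def task_algorithm(probe: Probe, backend_name: str) -> str:
    if backend_name == "naive":
        return "naive"
    return "tblastn" if probe.molecule == "aa" else "blastn"


def enumerate_pending(
    project: Project, config: ScreenConfig, backend_name: str = "naive"
) -> list[SearchTask]:
    """All probe x target-file pairs without a matching 'done' status record.

    An empty list means screening is complete for the current probe/target
    sets and parameters; adding a probe or a target file later re-opens
    exactly the new pairs.
    """
    done = project.done_searches()
    params = config.search_parameters()
    tasks = []
    for probe in project.probes():
        algorithm = task_algorithm(probe, backend_name)
        digest = parameter_digest(algorithm, params)
        for target in project.targets():
            if (probe.probe_id, target.file_id, algorithm, digest) not in done:
                tasks.append(SearchTask(probe, target, algorithm, digest))
    return tasks


def run_search(task: SearchTask, backend, config: ScreenConfig) -> list[RawHit]:
    """Execute one search; an empty hit list is a valid outcome."""
    hits = backend.run(task)
    return [
        h
        for h in hits
        if h.evalue <= config.evalue_ceiling and h.bitscore >= config.min_report_bits
    ]


def mark_done(project: Project, task: SearchTask):
    """Record search completion (idempotent); excluded from future enumeration."""
    return project.mark_search_done(
        task.probe.probe_id, task.target.file_id, task.algorithm, task.digest
    )
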