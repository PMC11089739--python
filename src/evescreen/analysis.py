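"""Downstream EVE analytics over screening results.

Once screening has produced a classified, non-redundant results table, the
questions shift from "what matches?" to "what does it mean?":

* flagging rows likely to be contaminants (exogenous virus DNA, diet-derived
  plant-virus sequence) rather than germline elements;
* measuring germline degradation (stop codons, frameshifts) and residual
  coding capacity (ORFs);
* resolving orthologous loci — copies of one ancestral germline insertion
  inherited by descent — from independent (paralogous) insertions, which is
  what turns locus counts into incorporation-event counts;
* dating orthologous insertions by the divergence time of the host species
  that share them, and converting event counts into germline infiltration
  rates per million years of sampled host branch length;
* assigning standardized locus identifiers and producing the grouped count /
  per-genome-average summary tables used to compare host classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

try:
    import edlib
except ImportError:  # pragma: no cover - edlib is a hard dependency
    edlib = None

from Bio.Seq import Seq

from .model import (
    FilterFlags,
    Locus,
    NomenclatureID,
    ORF,
    OrthologGroup,
    RateEstimate,
    ScreenConfig,
)
from .search import _protein_matrix, reverse_complement

__all__ = [
    "compute_filter_flags",
    "detect_degradation",
    "find_orfs",
    "LocusRecord",
    "resolve_orthology",
    "load_timetree",
    "estimate_min_age",
    "sampled_branch_length",
    "infiltration_rate",
    "format_nomenclature",
    "parse_nomenclature",
    "summarize_counts",
    "summarize_project",
    "project_orthology_records",
    "published_erv_rt_counts",
    "published_eve_counts",
]

_STOPS = {"TAA", "TAG", "TGA"}
_DATA_DIR = Path(__file__).parent / "data"


# ---------------------------------------------------------------------------
# filter flags
# ---------------------------------------------------------------------------

def compute_filter_flags(
    locus: Locus,
    contig_length: int | None,
    config: ScreenConfig | None = None,
    reference_aa: str | None = None,
    host_kingdom: str | None = None,
    virus_host_kingdom: str | None = None,
) -> FilterFlags:
    """Contamination/degradation indicator flags for one classified locus.

    ``high_identity_to_known_virus`` fires at or above the configured
    nucleotide identity (default 98%), the level at which a match is
    indistinguishable from a previously sequenced exogenous virus.
    ``lacks_flanks`` fires when the locus abuts a contig edge within the
    flank margin — no flanking host sequence, so integration cannot be
    shown.  ``intact_coding`` requires zero stops and zero frameshifts
    across the virus-homologous region (measured against ``reference_aa``
    when given, otherwise by the cleanest reading frame).  The conjunction
    of the three marks a row as putatively exogenous.  ``nonhost_virus_group``
    fires when side data places the assigned virus group in a different host
    kingdom than the screened species (e.g. a plant-virus match in a
    vertebrate assembly, the signature of diet-derived contamination).
    """
    config = config or ScreenConfig()
    if contig_length is None:
        raise LookupError(
            f"contig length unknown for locus {locus.locus_id} "
            f"({locus.target_file_id}:{locus.contig_id})"
        )
    identity = locus.classification_identity or 0.0
    high_identity = identity >= config.exogenous_identity_pct
    margin = config.flank_margin_nt
    lacks_flanks = locus.start <= 1 + margin or locus.end >= contig_length - margin

    seq = locus.extracted_sequence or ""
    if reference_aa is not None and seq:
        n_stops, n_fs = detect_degradation(seq, reference_aa)
        intact = (n_stops == 0) and (n_fs == 0)
    elif seq:
        intact = _min_stop_count(seq) == 0
    else:
        intact = False

    nonhost = (
        host_kingdom is not None
        and virus_host_kingdom is not None
        and host_kingdom != virus_host_kingdom
    )
    return FilterFlags(
        high_identity_to_known_virus=high_identity,
        lacks_flanks=lacks_flanks,
        intact_coding=intact,
        nonhost_virus_group=nonhost,
    )


def _min_stop_count(nt: str) -> int:
    best = None
    for frame in range(3):
        sub = nt[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        stops = sum(1 for i in range(0, len(sub), 3) if sub[i : i + 3] in _STOPS)
        best = stops if best is None else min(best, stops)
    return best or 0


# ---------------------------------------------------------------------------
# degradation detection (frameshift-aware nucleotide-vs-protein alignment)
# ---------------------------------------------------------------------------

def detect_degradation(
    locus_nt: str,
    reference_aa: str,
    *,
    gap_penalty: float = -12.0,
    frameshift_penalty: float = -15.0,
) -> tuple[int | None, int | None]:
    """Count stop codons and frameshifts in the virus-homologous region.

    Aligns the locus nucleotide sequence against the reference protein with
    a local, frameshift-aware dynamic program: one reference residue is
    normally consumed together with 3 nt (scored by the protein matrix on
    the translated codon), but may consume 2 or 4 nt at a frameshift
    penalty.  Whole-codon gaps on either side cost ``gap_penalty``.

    Along the optimal path, every consumed in-frame triple that translates
    to a stop is counted as a stop codon, and every 2/4-nt step as a
    frameshift (an indel whose length is not a multiple of 3).  Returns
    ``(None, None)`` with a warning when no positive-scoring homologous
    region exists.
    """
    import warnings

    nt = "".join(c if c in "ACGT" else "N" for c in locus_nt.upper())
    aa = reference_aa.upper()
    n, m = len(nt), len(aa)
    if n < 3 or m == 0:
        warnings.warn("no alignable region for degradation detection", stacklevel=2)
        return None, None

    matrix = _protein_matrix()
    alphabet = matrix.alphabet

    def codon_aa(i: int) -> str:
        codon = nt[i : i + 3]
        if "N" in codon:
            return "X"
        c = str(Seq(codon).translate())
        return c if c in alphabet else "X"

    # substitution score of the codon ending at nt position i vs each ref residue
    codon_scores = np.zeros((n + 1, m + 1))
    aa_idx = [alphabet.index(c) if c in alphabet else alphabet.index("X") for c in aa]
    mat = np.asarray(matrix)
    for i in range(3, n + 1):
        row = mat[alphabet.index(codon_aa(i - 3))]
        codon_scores[i, 1:] = row[aa_idx]

    H = np.zeros((n + 1, m + 1))
    neg = -1e9
    for j in range(1, m + 1):
        prev = H[:, j - 1]
        cand = np.full(n + 1, neg)
        cand[3:] = np.maximum(cand[3:], prev[:-3] + codon_scores[3:, j])
        cand[2:] = np.maximum(cand[2:], prev[:-2] + frameshift_penalty)
        cand[4:] = np.maximum(cand[4:], prev[:-4] + frameshift_penalty)
        cand = np.maximum(cand, prev + gap_penalty)  # reference residue unmatched
        cand = np.maximum(cand, 0.0)
        # chains of whole-codon insertions in the nucleotide sequence:
        # H[i][j] = max(cand[i], H[i-3][j] + gap) — a stride-3 prefix max
        col = cand.copy()
        for c in range(3):
            lane = col[c::3]
            k = np.arange(lane.size)
            shifted = np.maximum.accumulate(lane - k * gap_penalty)
            col[c::3] = np.maximum(lane, shifted + k * gap_penalty)
        H[:, j] = np.maximum(col, 0.0)

    best = float(H.max())
    if best <= 0:
        warnings.warn("no alignable region for degradation detection", stacklevel=2)
        return None, None

    i, j = np.unravel_index(int(H.argmax()), H.shape)
    i, j = int(i), int(j)
    n_stops = 0
    n_fs = 0
    eps = 1e-6
    while H[i, j] > eps:
        h = H[i, j]
        if i >= 3 and j >= 1 and abs(h - (H[i - 3, j - 1] + codon_scores[i, j])) < eps:
            if nt[i - 3 : i] in _STOPS:
                n_stops += 1
            i, j = i - 3, j - 1
        elif i >= 3 and abs(h - (H[i - 3, j] + gap_penalty)) < eps:
            if nt[i - 3 : i] in _STOPS:
                n_stops += 1
            i = i - 3
        elif i >= 2 and j >= 1 and abs(h - (H[i - 2, j - 1] + frameshift_penalty)) < eps:
            n_fs += 1
            i, j = i - 2, j - 1
        elif i >= 4 and j >= 1 and abs(h - (H[i - 4, j - 1] + frameshift_penalty)) < eps:
            n_fs += 1
            i, j = i - 4, j - 1
        elif j >= 1 and abs(h - (H[i, j - 1] + gap_penalty)) < eps:
            j = j - 1
        else:  # pragma: no cover - defensive
            break
    return n_stops, n_fs


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------

def find_orfs(
    nt_seq: str,
    min_len_aa: int = 300,
    kinds: Sequence[str] = ("atg_initiated", "open_coding_region"),
) -> list[ORF]:
    """Scan all six frames for ORFs and open coding regions.

    An *open coding region* is a maximal stop-free segment of one frame; an
    *ATG-initiated ORF* starts at the first ATG of such a segment and runs
    to its terminating stop (included in the coordinates) or the frame end.
    ``length_aa`` counts coding codons only (the stop is not a residue).
    Coordinates are 1-based inclusive on the forward orientation of the
    input sequence; minus-strand ORFs are mapped back accordingly.  Results
    are sorted by length descending.
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    seq = nt_seq.upper()
    L = len(seq)
    orfs: list[ORF] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            codons = [(i, s[i : i + 3]) for i in range(frame, L - 2, 3)]
            if not codons:
                continue
            # split into stop-free segments; remember the terminating stop
            seg_start = 0
            segments = []  # (first_codon_idx, last_codon_idx_exclusive, has_stop)
            for idx, (_, codon) in enumerate(codons):
                if codon in _STOPS:
                    segments.append((seg_start, idx, True))
                    seg_start = idx + 1
            segments.append((seg_start, len(codons), False))
            for a, b, has_stop in segments:
                n_codons = b - a
                if n_codons <= 0:
                    continue
                nt_a = codons[a][0] + 1
                nt_b = codons[b - 1][0] + 3
                if "open_coding_region" in kinds and n_codons >= min_len_aa:
                    orfs.append(
                        _oriented_orf(strand, frame, nt_a, nt_b, n_codons, "open_coding_region", L)
                    )
                if "atg_initiated" in kinds:
                    atg = next(
                        (idx for idx in range(a, b) if codons[idx][1] == "ATG"), None
                    )
                    if atg is not None:
                        coding = b - atg
                        if coding >= min_len_aa:
                            end_nt = nt_b + 3 if has_stop else nt_b
                            orfs.append(
                                _oriented_orf(
                                    strand, frame, codons[atg][0] + 1, end_nt,
                                    coding, "atg_initiated", L,
                                )
                            )
    orfs.sort(key=lambda o: (-o.length_aa, o.strand, o.frame, o.start, o.kind))
    return orfs


def _oriented_orf(strand: str, frame: int, start: int, end: int, length_aa: int, kind: str, L: int) -> ORF:
    if strand == "-":
        start, end = L - end + 1, L - start + 1
    return ORF(strand=strand, frame=frame, start=start, end=end, length_aa=length_aa, kind=kind)


# ---------------------------------------------------------------------------
# ortholog / paralog resolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusRecord:
    """Input record for ortholog resolution: one classified EVE locus."""

    locus_id: int
    host_species: str
    virus_taxon: str
    sequence: str


def _identity_pct(a: str, b: str) -> float:
    """Global alignment identity, as a percentage of the longer sequence."""
    if not a or not b:
        return 0.0
    if edlib is not None:
        dist = edlib.align(a, b, task="distance", mode="NW")["editDistance"]
    else:  # pragma: no cover
        raise RuntimeError("edlib is required for identity computation")
    return 100.0 * (1.0 - dist / max(len(a), len(b)))


def resolve_orthology(
    records: Sequence[LocusRecord],
    host_clades: Mapping[str, str] | None = None,
    config: ScreenConfig | None = None,
) -> list[OrthologGroup]:
    """Partition EVE loci into groups of putatively orthologous insertions.

    Each group represents one inferred germline incorporation event.  A
    locus joins an existing group of the same virus taxon when its identity
    to the group's reference sequence meets ``ortholog_identity_pct``
    (default 80%) and its host species lies within the group's host clade
    (same value of ``host_clades``, typically the host order; pass ``None``
    to disable the clade constraint).  Otherwise it founds a new group with
    the next free numeric id for that virus taxon.  Assignment passes repeat
    — references added by new groups can capture previously assigned loci —
    until a fixed point, so re-running on a converged state is the identity.
    """
    config = config or ScreenConfig()
    host_clades = host_clades or {}
    use_clades = config.ortholog_host_rank is not None and bool(host_clades)

    ordered = sorted(records, key=lambda r: (r.virus_taxon, r.host_species, r.locus_id))
    groups: list[OrthologGroup] = []
    counters: dict[str, int] = {}
    assignment: dict[int, str] = {}
    # clade sets grow live within a pass so later records can join groups
    # founded earlier in the same pass; memberships are rebuilt at pass end
    group_clades: dict[str, set] = {}
    group_members: dict[str, set[int]] = {}

    def best_group(rec: LocusRecord) -> OrthologGroup | None:
        best: tuple[float, str] | None = None
        best_grp = None
        for grp in groups:
            if grp.virus_taxon != rec.virus_taxon:
                continue
            if group_members.get(grp.group_id) == {rec.locus_id}:
                continue  # its own singleton is not an alternative
            if use_clades and host_clades.get(rec.host_species) not in group_clades[grp.group_id]:
                continue
            ident = _identity_pct(rec.sequence, grp.reference_sequence)
            if ident < config.ortholog_identity_pct:
                continue
            key = (-ident, grp.group_id)
            if best is None or key < best:
                best = key
                best_grp = grp
        return best_grp

    changed = 0
    for _ in range(config.ortholog_max_iter):
        changed = 0
        for rec in ordered:
            grp = best_group(rec)
            if grp is None:
                current = assignment.get(rec.locus_id)
                if current is not None and group_members.get(current) == {rec.locus_id}:
                    continue  # stays the founder of its own group
                counters[rec.virus_taxon] = counters.get(rec.virus_taxon, 0) + 1
                grp = OrthologGroup(
                    group_id=f"{rec.virus_taxon}.{counters[rec.virus_taxon]}",
                    numeric_id=counters[rec.virus_taxon],
                    virus_taxon=rec.virus_taxon,
                    reference_sequence=rec.sequence,
                )
                groups.append(grp)
                group_clades[grp.group_id] = {host_clades.get(rec.host_species)}
                group_members[grp.group_id] = set()
            if assignment.get(rec.locus_id) != grp.group_id:
                assignment[rec.locus_id] = grp.group_id
                changed += 1
            group_clades[grp.group_id].add(host_clades.get(rec.host_species))
            group_members[grp.group_id].add(rec.locus_id)
        # rebuild memberships (and clade/member maps) from the assignment map
        by_id = {g.group_id: g for g in groups}
        for g in groups:
            g.member_loci = []
        for rec in ordered:
            by_id[assignment[rec.locus_id]].member_loci.append(
                (rec.locus_id, rec.host_species)
            )
        groups = [g for g in groups if g.member_loci]
        group_members = {g.group_id: {lid for lid, _ in g.member_loci} for g in groups}
        group_clades = {
            g.group_id: {host_clades.get(sp) for _, sp in g.member_loci} for g in groups
        }
        if changed == 0:
            return groups
    raise RuntimeError(
        f"ortholog resolution did not converge after {config.ortholog_max_iter} "
        f"iterations ({changed} residual reassignments)"
    )


# ---------------------------------------------------------------------------
# dating and infiltration rates
# ---------------------------------------------------------------------------

def load_timetree(path) -> "dendropy.Tree":
    """Read a newick time tree (branch lengths in MY), keeping underscores literal."""
    import dendropy

    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def _node_ages(tree) -> dict:
    """Node age = max root-ward distance to a descendant leaf (MY)."""
    ages = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            ages[node] = max(
                ages[ch] + (ch.edge.length or 0.0) for ch in node.child_nodes()
            )
    return ages


def estimate_min_age(member_species: Iterable[str], tree) -> float | None:
    """Minimum insertion age: divergence time of the host species sharing it.

    ``tree`` is a dendropy ultrametric tree with branch lengths in MY.
    Returns the depth of the MRCA of the member species, or ``None`` for a
    single-species group (orthology across two or more species is required
    to date an insertion).
    """
    species = sorted(set(member_species))
    labels = {t.label for t in tree.taxon_namespace}
    for sp in species:
        if sp not in labels:
            raise KeyError(f"species {sp!r} absent from the time tree")
    if len(species) < 2:
        return None
    mrca = tree.mrca(taxon_labels=species)
    return _node_ages(tree)[mrca]


def sampled_branch_length(tree, tip_labels: Iterable[str]) -> float:
    """Total branch length (MY) of the minimal subtree spanning the tips.

    An edge contributes iff it lies on a path between two selected tips,
    i.e. the selected tips split across the edge.  Paraphyletic tip sets are
    handled naturally — the spanning subtree simply crosses the deeper nodes.
    """
    selected = set(tip_labels)
    if not selected:
        return 0.0
    labels = {t.label for t in tree.taxon_namespace}
    missing = selected - labels
    if missing:
        raise KeyError(f"species absent from the time tree: {sorted(missing)}")
    below: dict = {}
    total = 0.0
    n_sel = len(selected)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            count = 1 if (node.taxon is not None and node.taxon.label in selected) else 0
        else:
            count = sum(below[ch] for ch in node.child_nodes())
        below[node] = count
        if node.parent_node is not None and 0 < count < n_sel:
            total += node.edge.length or 0.0
    return total


def infiltration_rate(
    groups: Sequence[OrthologGroup],
    host_class: str,
    virus_family: str,
    tree,
    class_membership: Mapping[str, str],
) -> RateEstimate:
    """Germline infiltration rate for one host class x virus family.

    ``n_events`` counts the distinct ortholog groups of that family whose
    members include a species of the class; the denominator is the branch
    length (MY) of the minimal subtree spanning the *sampled* species of the
    class, so the rate is events per MY of surveyed host evolution.
    """
    class_tips = [sp for sp, cls in class_membership.items() if cls == host_class]
    n_events = sum(
        1
        for g in groups
        if g.virus_taxon == virus_family
        and any(class_membership.get(sp) == host_class for sp in g.host_species)
    )
    branch = sampled_branch_length(tree, class_tips)
    if n_events == 0:
        rate = 0.0
    elif branch <= 0:
        raise ZeroDivisionError(
            f"zero sampled branch length for class {host_class!r} with "
            f"{n_events} events"
        )
    else:
        rate = n_events / branch
    return RateEstimate(
        host_class=host_class,
        virus_family=virus_family,
        n_events=n_events,
        branch_length_my=branch,
        rate_per_my=rate,
    )


# ---------------------------------------------------------------------------
# nomenclature
# ---------------------------------------------------------------------------

_NOMEN_RE = re.compile(r"^(?P<cls>[^-]+)-(?P<mid>.+)-(?P<dist>[^-]+)$")


def format_nomenclature(nid: NomenclatureID) -> str:
    """Serialize as ``<classifier>-<virus_taxon>.<numeric_id>-<distribution>``."""
    return f"{nid.classifier}-{nid.virus_taxon}.{nid.numeric_id}-{nid.distribution}"


def parse_nomenclature(text: str) -> NomenclatureID:
    """Inverse of :func:`format_nomenclature`.

    Splits at the FIRST ``-`` (classifier), the LAST ``-`` (distribution) and
    the ``.`` inside the middle token (virus taxon vs numeric id).
    """
    m = _NOMEN_RE.match(text)
    if not m:
        raise ValueError(f"malformed nomenclature id {text!r} (expected cls-taxon.N-dist)")
    mid = m.group("mid")
    if "." not in mid:
        raise ValueError(f"malformed nomenclature id {text!r}: middle token lacks '.'")
    taxon, _, num = mid.rpartition(".")
    if not num.isdigit():
        raise ValueError(f"malformed nomenclature id {text!r}: numeric id {num!r}")
    return NomenclatureID(
        classifier=m.group("cls"),
        virus_taxon=taxon,
        numeric_id=int(num),
        distribution=m.group("dist"),
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_counts(
    df: pd.DataFrame,
    group_by: Sequence[str],
    total_col: str = "n_loci",
    genomes_col: str | None = None,
    events_col: str | None = None,
) -> pd.DataFrame:
    """Grouped totals with optional per-genome averages and event counts.

    Per-genome averages are ``total / n_genomes`` rounded to 2 decimal
    places.  Totals over any grouping sum to the unpartitioned total (counts
    are conserved across partitions).
    """
    for col in list(group_by) + [total_col]:
        if col not in df.columns:
            raise KeyError(f"grouping column {col!r} absent from table")
    agg = {total_col: "sum"}
    if genomes_col:
        agg[genomes_col] = "sum"
    if events_col:
        agg[events_col] = "sum"
    out = df.groupby(list(group_by), as_index=False).agg(agg)
    out = out.rename(columns={total_col: "total"})
    if genomes_col:
        out["per_genome_average"] = (out["total"] / out[genomes_col]).round(2)
    if events_col:
        out = out.rename(columns={events_col: "n_events"})
    return out


def summarize_project(
    project,
    group_by: Sequence[str] = ("assigned_taxon",),
    exclude_categories: Sequence[str] = (),
    exclude_taxa: Sequence[str] = (),
    min_bitscore: float | None = None,
    groups: Sequence[OrthologGroup] | None = None,
) -> pd.DataFrame:
    """Summary table over the project's results rows.

    Grouping columns may come from the results table itself or from the
    species metadata (``species_name``) joined through target files; side
    tables previously imported can be joined by the caller through
    :meth:`Project.query` for arbitrary groupings.  ``exclude_categories``
    removes rows whose assigned taxon belongs to an excluded RSL category
    (e.g. transposons); ``exclude_taxa`` removes named taxa outright.
    Exclusion is list-based and non-destructive: stored rows are untouched.
    """
    df = project.query(
        "SELECT r.*, t.species_name FROM results r "
        "JOIN target_files t ON r.target_file_id = t.file_id"
    )
    if min_bitscore is not None:
        df = df[df["classification_bitscore"] >= min_bitscore]
    if exclude_categories:
        placeholders = ",".join("?" for _ in exclude_categories)
        excluded = project.query(
            f"SELECT DISTINCT taxon_name FROM rsl WHERE category IN ({placeholders})",
            list(exclude_categories),
        )["taxon_name"].tolist()
        df = df[~df["assigned_taxon"].isin(excluded)]
    if exclude_taxa:
        df = df[~df["assigned_taxon"].isin(list(exclude_taxa))]
    for col in group_by:
        if col not in df.columns:
            raise KeyError(f"grouping column {col!r} absent from results")
    out = df.groupby(list(group_by), as_index=False).size().rename(columns={"size": "total"})
    n_genomes = project.query(
        "SELECT COUNT(DISTINCT file_id) AS n FROM target_files"
    )["n"].iloc[0]
    if n_genomes:
        out["per_genome_average"] = (out["total"] / n_genomes).round(2)
    if groups is not None and list(group_by) == ["assigned_taxon"]:
        events = {}
        for g in groups:
            events[g.virus_taxon] = events.get(g.virus_taxon, 0) + 1
        out["n_events"] = out["assigned_taxon"].map(events).fillna(0).astype(int)
    return out


def project_orthology_records(
    project,
    exclude_categories: Sequence[str] = ("transposon", "host_gene"),
) -> tuple[list[LocusRecord], dict[str, str], dict[str, str]]:
    """Assemble ortholog-resolution inputs from a project store.

    Returns ``(records, host_clades, class_membership)``: one record per
    classified locus whose assigned taxon is not unclassified and not in an
    excluded RSL category, the species -> host-order map, and the species ->
    host-class map (both from the ``host_taxonomy`` side table when
    imported, empty otherwise).
    """
    df = project.query(
        "SELECT r.locus_id, r.assigned_taxon, r.extracted_sequence, t.species_name "
        "FROM results r JOIN target_files t ON r.target_file_id = t.file_id "
        "WHERE r.assigned_taxon IS NOT NULL AND r.assigned_taxon != 'unclassified' "
        "AND r.extracted_sequence IS NOT NULL"
    )
    if exclude_categories:
        placeholders = ",".join("?" for _ in exclude_categories)
        excluded = set(
            project.query(
                f"SELECT DISTINCT taxon_name FROM rsl WHERE category IN ({placeholders})",
                list(exclude_categories),
            )["taxon_name"]
        )
        df = df[~df["assigned_taxon"].isin(excluded)]
    records = [
        LocusRecord(
            locus_id=int(row.locus_id),
            host_species=row.species_name,
            virus_taxon=row.assigned_taxon,
            sequence=row.extracted_sequence,
        )
        for row in df.itertuples(index=False)
    ]
    host_clades: dict[str, str] = {}
    class_membership: dict[str, str] = {}
    names = project.query("SELECT name FROM side_tables")["name"].tolist()
    if "host_taxonomy" in names:
        tax = project.query("SELECT * FROM host_taxonomy")
        if "host_order" in tax.columns:
            host_clades = dict(zip(tax["species_name"], tax["host_order"]))
        if "host_class" in tax.columns:
            class_membership = dict(zip(tax["species_name"], tax["host_class"]))
    return records, host_clades, class_membership


def published_erv_rt_counts() -> pd.DataFrame:
    """Published survey counts of RT-encoding ERV loci per vertebrate class and clade."""
    return pd.read_csv(_DATA_DIR / "erv_rt_counts.tsv", sep="\t")


def published_eve_counts() -> pd.DataFrame:
    """Published survey counts of non-retroviral EVE loci and incorporation events per virus family."""
    return pd.read_csv(_DATA_DIR / "nonretroviral_eve_counts.tsv", sep="\t")


def published_eve_counts_by_class() -> pd.DataFrame:
    """Published survey counts of non-retroviral EVE loci per virus family x host class."""
    return pd.read_csv(_DATA_DIR / "nonretroviral_eve_by_class.tsv", sep="\t")
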