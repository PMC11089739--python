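"""Locus classification against the reference sequence library (RSL).

Each extracted locus is compared to every RSL entry and assigned the
identity (taxon name, gene name) of its best-matching reference, with the
bitscore as the ranking and filtering currency.  Because assignment is a
pure function of (sequence, RSL, parameters), updating the RSL and
re-running classification is the central curation move: adding
cross-matching host genes, transposons, or retroviral glycoproteins to the
RSL flips spurious assignments without touching the stored loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model import Locus, ReferenceSequence, ScreenConfig
from .search import naive_nucleotide_search, naive_translated_search
from .store import ConfigurationError, Project

__all__ = ["Classification", "classify_locus", "classify_and_store", "reclassify", "filter_by_bitscore"]

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Classification:
    assigned_taxon: str
    assigned_gene: str | None
    bitscore: float
    evalue: float
    identity: float
    ref_id: str | None


def _score_against(ref: ReferenceSequence, locus_seq: str, config: ScreenConfig):
    """Best alignment of one RSL entry vs a locus nucleotide sequence."""
    if ref.molecule == "aa":
        hits = naive_translated_search(ref.sequence, locus_seq, config)
    else:
        hits = naive_nucleotide_search(ref.sequence, locus_seq, config)
    if not hits:
        return None
    best = hits[0]
    return best.bitscore, best.evalue, best.pct_identity


def classify_locus(
    locus_seq: str,
    rsl: Sequence[ReferenceSequence],
    config: ScreenConfig | None = None,
) -> Classification:
    """Assign a locus the identity of its best-matching RSL sequence.

    The winner is the entry with maximal bitscore; ties break by lower
    e-value, then lexicographically smallest ``ref_id``.  If no entry
    reaches the classification floor (the screening bitscore cutoff), the
    locus is recorded as unclassified rather than dropped, preserving an
    audit trail for marginal hits.
    """
    config = config or ScreenConfig()
    if not rsl:
        raise ConfigurationError("reference sequence library is empty")
    best: tuple | None = None  # (-bits, evalue, ref_id, identity, ref)
    for ref in rsl:
        scored = _score_against(ref, locus_seq, config)
        if scored is None:
            continue
        bits, evalue, identity = scored
        key = (-bits, evalue, ref.ref_id)
        if best is None or key < best[:3]:
            best = key + (identity, ref)
    if best is None or -best[0] < config.bitscore_count_cutoff:
        bits = -best[0] if best else 0.0
        return Classification(UNCLASSIFIED, None, bits, 0.0, 0.0, None)
    neg_bits, evalue, ref_id, identity, ref = best
    return Classification(ref.taxon_name, ref.gene_name, -neg_bits, evalue, identity, ref_id)


def classify_and_store(project: Project, locus: Locus, config: ScreenConfig | None = None) -> Classification:
    """Classify one stored locus against the project RSL and persist the result."""
    if locus.extracted_sequence is None:
        raise ValueError(f"locus {locus.locus_id} has no extracted sequence")
    cls = classify_locus(locus.extracted_sequence, project.rsl(), config)
    locus.assigned_taxon = cls.assigned_taxon
    locus.assigned_gene = cls.assigned_gene
    locus.classification_bitscore = cls.bitscore
    locus.classification_evalue = cls.evalue
    locus.classification_identity = cls.identity
    project.upsert_locus(locus)
    return cls


def reclassify(
    project: Project,
    sql_constraint: str | None = None,
    config: ScreenConfig | None = None,
    rsl: Sequence[ReferenceSequence] | None = None,
) -> int:
    """Re-score results rows against the current RSL; returns changed-row count.

    ``sql_constraint`` is a WHERE-clause fragment over the results table
    (e.g. ``"classification_bitscore < 90"``); ``None`` selects every row,
    and a constraint matching nothing returns 0.  Unselected rows are never
    touched.  A row counts as changed when its (taxon, gene) assignment
    moves; scores are refreshed either way.
    """
    config = config or ScreenConfig()
    rsl = list(rsl) if rsl is not None else project.rsl()
    loci = project.loci(where=sql_constraint)
    n_changed = 0
    for locus in loci:
        if locus.extracted_sequence is None:
            continue
        cls = classify_locus(locus.extracted_sequence, rsl, config)
        if (locus.assigned_taxon, locus.assigned_gene) != (cls.assigned_taxon, cls.assigned_gene):
            n_changed += 1
        locus.assigned_taxon = cls.assigned_taxon
        locus.assigned_gene = cls.assigned_gene
        locus.classification_bitscore = cls.bitscore
        locus.classification_evalue = cls.evalue
        locus.classification_identity = cls.identity
        project.upsert_locus(locus)
    return n_changed


def filter_by_bitscore(rows: Sequence, cutoff_bits: float) -> list:
    """Keep rows with classification bitscore >= cutoff (inclusive), order preserved."""
    out = []
    for row in rows:
        bits = row.classification_bitscore if isinstance(row, Locus) else row
        if bits is not None and bits >= cutoff_bits:
            out.append(row)
    return out
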