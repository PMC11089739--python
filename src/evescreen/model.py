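"""Domain types for database-integrated genome screening.

The screening model distinguishes three tiers of sequence records:

* :class:`RawHit` — a single local similarity-search match against a target
  contig, as emitted by a search backend.
* :class:`Locus` — a defragmented, non-redundant results-table row: one or
  more raw hits merged into a single genomic interval, with its extracted
  nucleotide sequence and its classification against the reference sequence
  library (RSL).
* :class:`ConsolidatedLocus` — adjacent classified loci concatenated (not
  merged) into a multi-gene structure record.

Coordinates are 1-based inclusive throughout, with ``start <= end`` always;
orientation lives exclusively in the ``strand`` field.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "TargetFile",
    "Probe",
    "ReferenceSequence",
    "SearchRecord",
    "RawHit",
    "Locus",
    "ConsolidatedLocus",
    "ScreenConfig",
    "FilterFlags",
    "ORF",
    "OrthologGroup",
    "RateEstimate",
    "NomenclatureID",
    "parse_header",
    "format_header",
    "parameter_digest",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZXJUO*")
NT_ALPHABET = set("ACGTUNRYSWKMBDHV")


def parse_header(header: str) -> tuple[str, str]:
    """Split a ``taxon_name_gene_name`` FASTA header into its two fields.

    The taxon name may itself contain underscores; the LAST underscore is the
    delimiter, so ``"Bornaviridae_Cultervirus_N"`` parses as taxon
    ``"Bornaviridae_Cultervirus"`` and gene ``"N"``.
    """
    if "_" not in header:
        raise ValueError(
            f"header {header!r} does not follow the 'taxon_gene' dialect "
            "(no underscore delimiter)"
        )
    taxon, _, gene = header.rpartition("_")
    if not taxon or not gene:
        raise ValueError(f"header {header!r} has an empty taxon or gene field")
    return taxon, gene


def format_header(taxon_name: str, gene_name: str) -> str:
    """Inverse of :func:`parse_header`; the gene name must not contain '_'."""
    if "_" in gene_name:
        raise ValueError(f"gene name {gene_name!r} may not contain underscores")
    return f"{taxon_name}_{gene_name}"


@dataclass(frozen=True)
class TargetFile:
    """One genome-assembly FASTA file in the target database (TDb).

    Metadata is derived from the directory layout
    ``<root>/<species_name>/<data_type>/<assembly_version>/<file>.fasta``.
    """

    species_name: str
    assembly_version: str
    data_type: str
    file_id: str
    path: str
    contigs: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        seen = set()
        for cid, length in self.contigs:
            if cid in seen:
                raise ValueError(f"duplicate contig id {cid!r} in {self.file_id}")
            seen.add(cid)
            if length < 1:
                raise ValueError(f"contig {cid!r} has non-positive length {length}")

    def contig_length(self, contig_id: str) -> int:
        for cid, length in self.contigs:
            if cid == contig_id:
                return length
        raise KeyError(f"contig {contig_id!r} not in target file {self.file_id!r}")


@dataclass(frozen=True)
class Probe:
    """A query sequence driving a similarity search (usually an RSL subset)."""

    probe_id: str
    taxon_name: str
    gene_name: str
    molecule: str  # "aa" or "nt"
    sequence: str

    def __post_init__(self) -> None:
        if self.molecule not in ("aa", "nt"):
            raise ValueError(f"molecule must be 'aa' or 'nt', got {self.molecule!r}")
        if not self.sequence:
            raise ValueError(f"probe {self.probe_id!r} has an empty sequence")
        alphabet = AA_ALPHABET if self.molecule == "aa" else NT_ALPHABET
        bad = set(self.sequence.upper()) - alphabet
        if bad:
            raise ValueError(
                f"probe {self.probe_id!r}: residues {sorted(bad)} invalid for "
                f"molecule {self.molecule!r}"
            )


@dataclass(frozen=True)
class ReferenceSequence:
    """One entry of the reference sequence library (RSL).

    ``category`` records what the sequence represents: an exogenous virus
    protein/gene, a locus-level EVE reference, a cross-matching host gene, or
    a transposable element.
    """

    ref_id: str
    taxon_name: str
    gene_name: str
    molecule: str
    sequence: str
    category: str = "virus"

    CATEGORIES = ("virus", "eve_locus", "host_gene", "transposon")

    def __post_init__(self) -> None:
        if self.molecule not in ("aa", "nt"):
            raise ValueError(f"molecule must be 'aa' or 'nt', got {self.molecule!r}")
        if self.category not in self.CATEGORIES:
            raise ValueError(f"unknown RSL category {self.category!r}")

    @property
    def header(self) -> str:
        return format_header(self.taxon_name, self.gene_name)


@dataclass
class SearchRecord:
    """Completion record for one probe x target-file search."""

    probe_id: str
    target_file_id: str
    algorithm: str
    parameter_digest: str
    status: str = "pending"
    completed_at: str | None = None

    def __post_init__(self) -> None:
        if (self.status == "done") != (self.completed_at is not None):
            raise ValueError("status 'done' requires completed_at, and vice versa")


@dataclass(frozen=True)
class RawHit:
    """A single similarity-search match in subject (contig) coordinates."""

    probe_id: str
    target_file_id: str
    contig_id: str
    subject_start: int
    subject_end: int
    strand: str
    bitscore: float
    evalue: float
    pct_identity: float
    query_start: int
    query_end: int

    def __post_init__(self) -> None:
        if self.subject_start > self.subject_end:
            raise ValueError("subject_start must be <= subject_end")
        if self.subject_start < 1:
            raise ValueError("subject coordinates are 1-based")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.bitscore < 0 or self.evalue < 0:
            raise ValueError("bitscore and e-value must be non-negative")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity must lie in [0, 100]")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.subject_start, self.subject_end)


@dataclass
class Locus:
    """A defragmented, classified results-table row."""

    locus_id: int | None
    target_file_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    extracted_sequence: str | None = None
    assigned_taxon: str | None = None
    assigned_gene: str | None = None
    classification_bitscore: float | None = None
    classification_evalue: float | None = None
    classification_identity: float | None = None
    best_probe_id: str | None = None
    n_merged_hits: int = 1

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError("locus interval must satisfy 1 <= start <= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if (
            self.extracted_sequence is not None
            and len(self.extracted_sequence) != self.end - self.start + 1
        ):
            raise ValueError(
                "extracted_sequence length must equal end - start + 1 "
                f"({len(self.extracted_sequence)} != {self.end - self.start + 1})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ConsolidatedLocus:
    """Adjacent classified loci concatenated into one structure record."""

    consolidated_id: int | None
    target_file_id: str
    contig_id: str
    member_locus_ids: tuple[int, ...]
    span_start: int
    span_end: int
    structure: str

    def __post_init__(self) -> None:
        if not self.member_locus_ids:
            raise ValueError("a consolidated locus needs at least one member")
        if self.span_start > self.span_end:
            raise ValueError("span_start must be <= span_end")


@dataclass
class ScreenConfig:
    """Tunable screening parameters.

    The two bitscore cutoffs follow common screening practice: 60 bits as the
    counting threshold (below which matches are rarely confirmable as
    virus-derived) and 90 bits as a conservative high-confidence threshold for
    cross-species copy-number comparison.
    """

    bitscore_count_cutoff: float = 60.0
    bitscore_highconf_cutoff: float = 90.0
    defragment_range_nt: int = 100
    consolidate_distance_nt: int = 200
    exogenous_identity_pct: float = 98.0
    orf_min_len_aa: int = 300
    flank_margin_nt: int = 0
    # search backend parameters
    evalue_ceiling: float = 10.0
    min_report_bits: float = 30.0
    # scoring constants for the naive backend (gapped BLOSUM62 statistics)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041
    # nucleotide scoring for the naive nt backend
    nt_match: int = 2
    nt_mismatch: int = -3
    nt_gap_open: int = 5
    nt_gap_extend: int = 2
    nt_lam: float = 0.625
    nt_k: float = 0.41
    # ortholog resolution
    ortholog_identity_pct: float = 80.0
    ortholog_host_rank: str | None = "host_order"
    ortholog_max_iter: int = 10
    random_seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "bitscore_count_cutoff",
            "bitscore_highconf_cutoff",
            "defragment_range_nt",
            "consolidate_distance_nt",
        ):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")

    def search_parameters(self) -> dict:
        """The parameter subset that affects search output (digested per search)."""
        return {
            "evalue_ceiling": self.evalue_ceiling,
            "min_report_bits": self.min_report_bits,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "lam": self.lam,
            "k": self.k,
            "nt_match": self.nt_match,
            "nt_mismatch": self.nt_mismatch,
            "nt_gap_open": self.nt_gap_open,
            "nt_gap_extend": self.nt_gap_extend,
        }

    def with_overrides(self, **kwargs) -> "ScreenConfig":
        return replace(self, **kwargs)


def parameter_digest(algorithm: str, params: dict) -> str:
    """Stable digest of search parameters; any change forces re-screening."""
    canon = algorithm + "|" + "|".join(f"{k}={params[k]}" for k in sorted(params))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class FilterFlags:
    """Per-locus contamination/degradation indicator flags.

    ``putative_exogenous`` marks rows likely derived from a contaminating
    exogenous virus rather than a germline element: near-perfect identity to a
    known virus, no flanking host sequence, and an intact coding region.
    """

    high_identity_to_known_virus: bool
    lacks_flanks: bool
    intact_coding: bool
    nonhost_virus_group: bool

    @property
    def putative_exogenous(self) -> bool:
        return (
            self.high_identity_to_known_virus
            and self.lacks_flanks
            and self.intact_coding
        )


@dataclass(frozen=True)
class ORF:
    """An open reading frame or open coding region within a locus sequence.

    Coordinates are 1-based inclusive on the locus nucleotide sequence
    (plus-strand orientation of the stored sequence); ``frame`` is the offset
    0-2 within the given strand.
    """

    strand: str
    frame: int
    start: int
    end: int
    length_aa: int
    kind: str  # "atg_initiated" | "open_coding_region"

    def __post_init__(self) -> None:
        if self.kind not in ("atg_initiated", "open_coding_region"):
            raise ValueError(f"unknown ORF kind {self.kind!r}")


@dataclass
class OrthologGroup:
    """A set of loci inferred to descend from one germline incorporation event."""

    group_id: str
    numeric_id: int
    virus_taxon: str
    member_loci: list[tuple[int, str]] = field(default_factory=list)
    reference_sequence: str = ""
    min_age_my: float | None = None
    amplified_lineage: bool = False

    @property
    def host_species(self) -> set[str]:
        return {sp for _, sp in self.member_loci}

    @property
    def n_members(self) -> int:
        return len(self.member_loci)


@dataclass(frozen=True)
class RateEstimate:
    """Germline infiltration rate: incorporation events per MY of sampled branch length."""

    host_class: str
    virus_family: str
    n_events: int
    branch_length_my: float
    rate_per_my: float

    def __post_init__(self) -> None:
        if self.rate_per_my < 0:
            raise ValueError("rate must be non-negative")


@dataclass(frozen=True)
class NomenclatureID:
    """Standardized locus identifier: ``<classifier>-<virus_taxon>.<numeric_id>-<distribution>``.

    The classifier denotes the EVE type (EBLL, ECLL, eflp, ECV, EPV, eHBV, ...),
    the middle token names the virus taxon the element derives from plus a
    numeric ID unique to the integration locus (or founding event for
    amplified lineages), and the final token gives the host-taxon distribution.
    """

    classifier: str
    virus_taxon: str
    numeric_id: int
    distribution: str

    def __post_init__(self) -> None:
        for fld in (self.classifier, self.virus_taxon, self.distribution):
            if "." in fld:
                raise ValueError(f"nomenclature field {fld!r} may not contain '.'")
        if self.numeric_id < 1:
            raise ValueError("numeric_id must be >= 1")


def total_merged_hits(loci: Iterable[Locus]) -> int:
    """Sum of raw hits absorbed across loci (conservation check helper)."""
    return sum(l.n_merged_hits for l in loci)
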