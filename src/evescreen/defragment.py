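"""Hit defragmentation: merge fragmented raw hits into non-redundant loci.

Local similarity searches fragment contiguous matches whenever internal
similarity dips, so one genomic element typically surfaces as several raw
hits.  Merging joins hits (and previously merged loci) on the same contig
and strand that overlap or lie within ``defragment_range_nt`` of each other
— the transitive closure of that adjacency relation — into a single results
row whose hull covers all members.

Consolidation is the complementary, coarser operation: adjacent *classified*
loci within ``consolidate_distance_nt`` are concatenated into a multi-gene
structure record (e.g. ``"NP(+)-L(+)"``) without touching the underlying
rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .model import ConsolidatedLocus, Locus, RawHit

__all__ = [
    "merge_hits",
    "extract_locus_sequence",
    "consolidate",
    "loci_to_bed",
    "bed_to_intervals",
]


@dataclass
class _Item:
    start: int
    end: int
    locus: Locus | None = None  # None for raw hits
    hit: RawHit | None = None


def _gap(left_end: int, right_start: int) -> int:
    return right_start - left_end - 1


def merge_hits(
    existing_loci: Sequence[Locus],
    new_hits: Sequence[RawHit],
    range_nt: int,
) -> tuple[list[Locus], list[Locus]]:
    """Merge new raw hits into the existing locus set.

    Returns ``(updated_loci, changed_loci)`` where ``changed_loci`` are the
    rows that need re-extraction and re-classification (fresh loci, plus any
    existing locus whose hull grew or that absorbed a sibling).  Merging is
    same-contig, same-strand only, independent of input order, and
    idempotent: re-presenting hits already contained in an existing hull
    changes nothing.

    When several existing loci collapse into one, the survivor keeps the
    smallest member ``locus_id`` (classification is recomputed downstream,
    never averaged); a hit contained inside an existing hull does not
    increment ``n_merged_hits``, so the hit-count conservation invariant
    holds across restarts.
    """
    if range_nt < 0:
        raise ValueError("defragment range must be >= 0")
    by_region: dict[tuple[str, str, str], list[_Item]] = {}
    for locus in existing_loci:
        key = (locus.target_file_id, locus.contig_id, locus.strand)
        by_region.setdefault(key, []).append(_Item(locus.start, locus.end, locus=locus))
    for hit in new_hits:
        key = (hit.target_file_id, hit.contig_id, hit.strand)
        by_region.setdefault(key, []).append(
            _Item(hit.subject_start, hit.subject_end, hit=hit)
        )

    updated: list[Locus] = []
    changed: list[Locus] = []
    for (file_id, contig_id, strand), items in sorted(by_region.items()):
        items.sort(key=lambda it: (it.start, it.end))
        clusters: list[list[_Item]] = []
        for item in items:
            if clusters and _gap(max(m.end for m in clusters[-1]), item.start) <= range_nt:
                clusters[-1].append(item)
            else:
                clusters.append([item])
        for members in clusters:
            member_loci = [m.locus for m in members if m.locus is not None]
            member_hits = [m.hit for m in members if m.hit is not None]
            hull_start = min(m.start for m in members)
            hull_end = max(m.end for m in members)
            if (
                len(member_loci) == 1
                and member_loci[0].start == hull_start
                and member_loci[0].end == hull_end
            ):
                # hull unchanged: contained hits are already represented
                updated.append(member_loci[0])
                continue
            n_hits = sum(l.n_merged_hits for l in member_loci)
            for hit in member_hits:
                contained = any(
                    l.start <= hit.subject_start and hit.subject_end <= l.end
                    for l in member_loci
                )
                if not contained:
                    n_hits += 1
            best_probe = None
            scored = [h for h in member_hits if h is not None]
            if scored:
                best_probe = max(scored, key=lambda h: h.bitscore).probe_id
            elif member_loci:
                best_probe = member_loci[0].best_probe_id
            keep_id = min(
                (l.locus_id for l in member_loci if l.locus_id is not None),
                default=None,
            )
            merged = Locus(
                locus_id=keep_id,
                target_file_id=file_id,
                contig_id=contig_id,
                start=hull_start,
                end=hull_end,
                strand=strand,
                best_probe_id=best_probe,
                n_merged_hits=max(n_hits, 1),
            )
            updated.append(merged)
            changed.append(merged)
    updated.sort(key=lambda l: (l.target_file_id, l.contig_id, l.strand, l.start))
    return updated, changed


def extract_locus_sequence(locus: Locus, fasta_index) -> str:
    """Extract the locus nucleotide sequence from an indexed target FASTA.

    Plus-strand loci return the literal substring; minus-strand loci the
    reverse complement.  ``fasta_index`` is a :class:`pyfaidx.Fasta`.
    """
    if locus.contig_id not in fasta_index:
        raise KeyError(f"contig {locus.contig_id!r} not in target FASTA")
    contig = fasta_index[locus.contig_id]
    length = len(contig)
    if locus.start < 1 or locus.end > length:
        raise IndexError(
            f"locus [{locus.start}, {locus.end}] out of bounds for contig "
            f"{locus.contig_id!r} (length {length})"
        )
    record = contig[locus.start - 1 : locus.end]
    seq = str(record.reverse.complement) if locus.strand == "-" else str(record)
    return seq.upper()


def consolidate(loci: Sequence[Locus], distance_nt: int) -> list[ConsolidatedLocus]:
    """Concatenate adjacent classified loci into multi-gene structure records.

    Loci on one contig (either strand) whose successive gaps are at most
    ``distance_nt`` form one entry; members are ordered by ascending start
    and the structure string lists their ``gene(strand)`` tokens in that
    order.  Member rows are left untouched.
    """
    if distance_nt < 0:
        raise ValueError("consolidation distance must be >= 0")
    for locus in loci:
        if locus.assigned_gene is None:
            raise ValueError(
                f"locus {locus.locus_id} is unclassified; classify before consolidating"
            )
        if locus.locus_id is None:
            raise ValueError("consolidation requires stored loci with ids")
    by_contig: dict[tuple[str, str], list[Locus]] = {}
    for locus in loci:
        by_contig.setdefault((locus.target_file_id, locus.contig_id), []).append(locus)

    out: list[ConsolidatedLocus] = []
    for (file_id, contig_id), group in sorted(by_contig.items()):
        group.sort(key=lambda l: (l.start, l.end))
        chains: list[list[Locus]] = []
        for locus in group:
            if chains and _gap(max(m.end for m in chains[-1]), locus.start) <= distance_nt:
                chains[-1].append(locus)
            else:
                chains.append([locus])
        for chain in chains:
            structure = "-".join(f"{l.assigned_gene}({l.strand})" for l in chain)
            out.append(
                ConsolidatedLocus(
                    consolidated_id=None,
                    target_file_id=file_id,
                    contig_id=contig_id,
                    member_locus_ids=tuple(l.locus_id for l in chain),
                    span_start=min(l.start for l in chain),
                    span_end=max(l.end for l in chain),
                    structure=structure,
                )
            )
    return out


def loci_to_bed(loci: Iterable[Locus], out_path: str | Path) -> int:
    """Write loci as BED (0-based half-open); returns the line count."""
    n = 0
    with open(out_path, "w") as fh:
        for locus in loci:
            name = f"locus_{locus.locus_id}" if locus.locus_id is not None else "locus"
            score = int(round(locus.classification_bitscore or 0))
            fh.write(
                f"{locus.contig_id}\t{locus.start - 1}\t{locus.end}\t{name}\t{score}\t{locus.strand}\n"
            )
            n += 1
    return n


def bed_to_intervals(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a BED file back into 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            contig, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) > 5 else "+"
            out.append((contig, start0 + 1, end0, strand))
    return out
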