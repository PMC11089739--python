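"""Deterministic synthetic genomes with implanted, degraded viral elements.

Real EVE screens run against published whole-genome assemblies; for testing
every pipeline stage hermetically, this module fabricates a miniature study
system: i.i.d. background genomes at a stated GC content, viral "source"
proteins, and implants made by back-translating a source protein, degrading
it (substitutions, indels, forced in-frame stops — the mutational scars of
long germline residence), and writing it into the background at recorded
coordinates.  Ground truth (coordinates, family, gene, orthology group) is
emitted alongside as TSV (1-based inclusive) and BED (0-based half-open).

All randomness flows from a single integer seed through per-purpose
counter-keyed numpy Generator streams, so individual pieces are reproducible
independently of call order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import format_header
from .search import reverse_complement

__all__ = [
    "ImplantSpec",
    "GenomeParams",
    "TruthRecord",
    "degrade",
    "back_translate",
    "random_protein",
    "generate_target",
    "make_rsl_and_probes",
    "standard_fixture",
    "evaluate_recovery",
    "FixtureBundle",
]

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"],
    "D": ["GAT", "GAC"],
    "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"],
    "E": ["GAA", "GAG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "K": ["AAA", "AAG"],
    "M": ["ATG"],
    "F": ["TTT", "TTC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
}
_AA20 = "".join(sorted(_CODONS))
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ImplantSpec:
    """One planned germline incorporation (or set of copies thereof).

    With ``shared=True`` the *same* degraded insertion sequence is written
    into every listed host species — an orthologous insertion inherited from
    a common ancestor — with a small amount of per-species divergence on
    top.  Otherwise each listed species receives ``n_copies`` independent
    implants (independent back-translations and degradations), i.e. separate
    incorporation events.
    """

    virus_family: str
    gene_name: str
    source_aa: str
    host_species: tuple[str, ...]
    n_copies: int = 1
    shared: bool = False
    sub_rate: float = 0.15
    indel_rate: float = 0.0
    stop_gain_count: int = 0
    species_divergence: float = 0.02
    strand: str = "random"  # "+", "-", or "random"
    category: str = "virus"

    def __post_init__(self) -> None:
        for name in ("sub_rate", "indel_rate", "species_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class GenomeParams:
    species: tuple[str, ...]
    n_contigs: int = 2
    contig_length: int = 25_000
    gc: float = 0.41
    data_type: str = "complete"
    assembly_version: str = "v1"


@dataclass(frozen=True)
class TruthRecord:
    species: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    virus_family: str
    gene: str
    group_label: str


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def back_translate(aa: str, rng: np.random.Generator) -> str:
    """Random synonymous back-translation (uniform codon choice)."""
    return "".join(_CODONS[c][rng.integers(len(_CODONS[c]))] for c in aa.upper())


def degrade(
    seq: str,
    sub_rate: float,
    indel_rate: float = 0.0,
    stop_gain_count: int = 0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Mutate a nucleotide sequence to emulate germline decay.

    Substitutions are per-site Bernoulli(sub_rate) draws to a different
    base; indels occur per site at ``indel_rate`` with geometric lengths
    capped at 3 nt (insertion or deletion with equal probability); finally
    ``stop_gain_count`` distinct frame-0 codons are overwritten with TAA.
    Zero rates and zero stops return the sequence unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bases = list(seq.upper())
    if sub_rate > 0:
        mask = rng.random(len(bases)) < sub_rate
        for i in np.nonzero(mask)[0]:
            choices = [b for b in "ACGT" if b != bases[i]]
            bases[i] = choices[rng.integers(3)]
    if indel_rate > 0:
        out = []
        for b in bases:
            if rng.random() < indel_rate:
                length = min(int(rng.geometric(0.5)), 3)
                if rng.random() < 0.5:
                    out.append("".join(rng.choice(_BASES, size=length)) + b)
                else:
                    continue  # deletion of this base (length-1 deletions dominate)
            else:
                out.append(b)
        bases = list("".join(out))
    if stop_gain_count > 0:
        n_codons = len(bases) // 3
        inner = np.arange(2, max(n_codons - 2, 3))
        picks = rng.choice(inner, size=min(stop_gain_count, inner.size), replace=False)
        for c in picks:
            bases[3 * c : 3 * c + 3] = list("TAA")
    return "".join(bases)


def _background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


@dataclass
class _PlannedImplant:
    species: str
    sequence: str  # plus-strand nt as it will appear in the genome
    strand: str
    virus_family: str
    gene: str
    group_label: str


def _plan_implants(specs: list[ImplantSpec], seed: int) -> list[_PlannedImplant]:
    planned = []
    event_counter: dict[str, int] = {}
    for si, spec in enumerate(specs):
        rng = _rng(seed, 1, si)
        if spec.shared:
            event_counter[spec.virus_family] = event_counter.get(spec.virus_family, 0) + 1
            label = f"{spec.virus_family}.{event_counter[spec.virus_family]}"
            ancestral = degrade(
                back_translate(spec.source_aa, rng),
                spec.sub_rate,
                spec.indel_rate,
                spec.stop_gain_count,
                rng,
            )
            for sp in spec.host_species:
                derived = degrade(ancestral, spec.species_divergence, 0.0, 0, rng)
                strand = spec.strand if spec.strand != "random" else ("+", "-")[rng.integers(2)]
                seq = derived if strand == "+" else reverse_complement(derived)
                planned.append(
                    _PlannedImplant(sp, seq, strand, spec.virus_family, spec.gene_name, label)
                )
        else:
            for sp in spec.host_species:
                for _ in range(spec.n_copies):
                    event_counter[spec.virus_family] = event_counter.get(spec.virus_family, 0) + 1
                    label = f"{spec.virus_family}.{event_counter[spec.virus_family]}"
                    insert = degrade(
                        back_translate(spec.source_aa, rng),
                        spec.sub_rate,
                        spec.indel_rate,
                        spec.stop_gain_count,
                        rng,
                    )
                    strand = spec.strand if spec.strand != "random" else ("+", "-")[rng.integers(2)]
                    seq = insert if strand == "+" else reverse_complement(insert)
                    planned.append(
                        _PlannedImplant(sp, seq, strand, spec.virus_family, spec.gene_name, label)
                    )
    return planned


def generate_target(
    specs: list[ImplantSpec],
    genome_params: GenomeParams,
    seed: int,
    out_dir: str | Path,
) -> tuple[Path, pd.DataFrame]:
    """Emit a target-database directory plus ground-truth tables.

    Layout: ``<out>/tdb/<species>/<data_type>/<assembly>/<species>.fasta``.
    Implants overwrite background sequence at their recorded coordinates
    (contig lengths stay fixed), spaced so no two lie within merge range of
    each other.  Returns the TDb root and the truth table, also written as
    ``truth.tsv`` (1-based) and ``truth.bed`` (0-based half-open).
    """
    out_dir = Path(out_dir)
    tdb_root = out_dir / "tdb"
    planned = _plan_implants(specs, seed)
    by_species: dict[str, list[_PlannedImplant]] = {sp: [] for sp in genome_params.species}
    for imp in planned:
        if imp.species not in by_species:
            raise ValueError(f"implant species {imp.species!r} not in genome_params.species")
        by_species[imp.species].append(imp)

    truth_rows = []
    for sp_idx, species in enumerate(genome_params.species):
        contigs = {
            f"{species}_contig{c+1}": _background(
                genome_params.contig_length, genome_params.gc, _rng(seed, 0, sp_idx, c)
            )
            for c in range(genome_params.n_contigs)
        }
        place_rng = _rng(seed, 2, sp_idx)
        cursor = {cid: 1000 for cid in contigs}
        for k, imp in enumerate(by_species[species]):
            cid = list(contigs)[k % genome_params.n_contigs]
            arr = contigs[cid]
            start0 = cursor[cid] + int(place_rng.integers(0, 500))
            end0 = start0 + len(imp.sequence)
            if end0 + 1000 > len(arr):
                raise ValueError(
                    f"implant of {len(imp.sequence)} nt does not fit contig {cid} "
                    f"(length {len(arr)}, cursor {cursor[cid]})"
                )
            arr[start0:end0] = np.array(list(imp.sequence))
            cursor[cid] = end0 + 1500
            truth_rows.append(
                TruthRecord(
                    species=species,
                    contig=cid,
                    start=start0 + 1,
                    end=end0,
                    strand=imp.strand,
                    virus_family=imp.virus_family,
                    gene=imp.gene,
                    group_label=imp.group_label,
                )
            )
        fasta_dir = tdb_root / species / genome_params.data_type / genome_params.assembly_version
        fasta_dir.mkdir(parents=True, exist_ok=True)
        with open(fasta_dir / f"{species}.fasta", "w") as fh:
            for cid, arr in contigs.items():
                fh.write(f">{cid}\n")
                s = "".join(arr)
                for i in range(0, len(s), 70):
                    fh.write(s[i : i + 70] + "\n")

    truth = pd.DataFrame([dataclasses.asdict(t) for t in truth_rows])
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    with open(out_dir / "truth.bed", "w") as fh:
        for t in truth_rows:
            fh.write(
                f"{t.contig}\t{t.start - 1}\t{t.end}\t{t.group_label}\t0\t{t.strand}\n"
            )
    return tdb_root, truth


def make_rsl_and_probes(
    specs: list[ImplantSpec],
    decoys: list[tuple[str, str, str, str]],
    out_dir: str | Path,
) -> tuple[Path, Path, dict[str, str]]:
    """Write the reference library and probe set for a fixture.

    The RSL holds each implant's source protein plus the decoy entries
    (``(taxon, gene, aa_sequence, category)`` tuples, e.g. host genes and
    transposons); probes are the virus sources only — a subset of the RSL,
    as in a real screen.  Returns (rsl_path, probe_path, category_map).
    """
    if not specs:
        raise ValueError("at least one implant spec is required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rsl_path = out_dir / "rsl.faa"
    probe_path = out_dir / "probes.faa"
    category_map: dict[str, str] = {}
    seen: dict[str, str] = {}
    for spec in specs:
        header = format_header(spec.virus_family, spec.gene_name)
        if header in seen and seen[header] != spec.source_aa:
            raise ValueError(f"conflicting source sequences for RSL entry {header}")
        seen[header] = spec.source_aa
        category_map[header] = spec.category
    with open(rsl_path, "w") as fh:
        for header, seq in seen.items():
            fh.write(f">{header}\n{seq}\n")
        for taxon, gene, seq, category in decoys:
            header = format_header(taxon, gene)
            category_map[header] = category
            fh.write(f">{header}\n{seq}\n")
    with open(probe_path, "w") as fh:
        for header, seq in seen.items():
            fh.write(f">{header}\n{seq}\n")
    with open(out_dir / "rsl_categories.tsv", "w") as fh:
        fh.write("ref_id\tcategory\n")
        for header, category in category_map.items():
            fh.write(f"{header}\t{category}\n")
    return rsl_path, probe_path, category_map


# ---------------------------------------------------------------------------
# the standard end-to-end fixture
# ---------------------------------------------------------------------------

_SPECIES = (
    "bat_alpha",
    "bat_beta",
    "rodent_gamma",
    "frog_delta",
    "fish_epsilon",
    "snake_zeta",
)

_HOST_TAXONOMY = [
    ("bat_alpha", "Chiroptera", "Mammalia"),
    ("bat_beta", "Chiroptera", "Mammalia"),
    ("rodent_gamma", "Rodentia", "Mammalia"),
    ("frog_delta", "Anura", "Amphibia"),
    ("fish_epsilon", "Cypriniformes", "Actinopterygii"),
    ("snake_zeta", "Squamata", "Reptilia"),
]

# ultrametric, branch lengths in MY: bats split 25, mammal root 96,
# amniote root 312, tetrapod root 352, vertebrate root 430
_TREE_NEWICK = (
    "(((((bat_alpha:25,bat_beta:25):71,rodent_gamma:96):216,snake_zeta:312):40,"
    "frog_delta:352):78,fish_epsilon:430);"
)

_FAMILIES = [
    ("Bornaviridae", "N"),
    ("Filoviridae", "VP35"),
    ("Circoviridae", "Rep"),
    ("Parvoviridae", "NS1"),
    ("Hepadnaviridae", "P"),
]


@dataclass
class FixtureBundle:
    root: Path
    control_file: Path
    tdb_root: Path
    rsl_path: Path
    probe_path: Path
    truth: pd.DataFrame
    truth_tsv: Path
    tree_path: Path
    host_taxonomy_tsv: Path
    category_map: dict[str, str]
    expected_events: dict[str, int] = field(default_factory=dict)


def standard_fixture(out_dir: str | Path, seed: int = 42, sub_rate: float = 0.15) -> FixtureBundle:
    """Build the canonical end-to-end study system.

    Five virus families with ~240-aa source proteins; 30 viral implants at
    the given substitution rate distributed over six species, including one
    orthologous insertion shared by the two bat species (so 29 distinct
    incorporation events: Bornaviridae 7, Filoviridae 6, Circoviridae 6,
    Parvoviridae 5, Hepadnaviridae 5); plus one transposon implant whose
    sequence is a diverged copy of the hepadnavirus source — a virus/TE
    chimera that a virus probe finds but the RSL's transposon entry claims
    on classification, reproducing the cross-match filtering logic.  Also
    emits a time-calibrated species tree (MY) and a host-taxonomy side
    table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    src_rng = _rng(seed, 9)
    sources = {fam: random_protein(240, src_rng) for fam, _ in _FAMILIES}
    genes = dict(_FAMILIES)

    def spec(fam, species, n=1, shared=False, stops=1):
        return ImplantSpec(
            virus_family=fam,
            gene_name=genes[fam],
            source_aa=sources[fam],
            host_species=tuple(species) if isinstance(species, (list, tuple)) else (species,),
            n_copies=n,
            shared=shared,
            sub_rate=sub_rate,
            indel_rate=0.0,
            stop_gain_count=stops,
        )

    specs = [
        # Bornaviridae: 8 loci, 7 events (one 2-species ortholog pair)
        spec("Bornaviridae", ["bat_alpha", "bat_beta"], shared=True),
        spec("Bornaviridae", "bat_alpha", n=2),
        spec("Bornaviridae", "rodent_gamma", n=2),
        spec("Bornaviridae", "frog_delta", n=1),
        spec("Bornaviridae", "fish_epsilon", n=1),
        # Filoviridae: 6 loci / 6 events
        spec("Filoviridae", "bat_alpha", n=2),
        spec("Filoviridae", "bat_beta", n=1),
        spec("Filoviridae", "rodent_gamma", n=2),
        spec("Filoviridae", "frog_delta", n=1),
        # Circoviridae: 6 loci / 6 events
        spec("Circoviridae", "rodent_gamma", n=2),
        spec("Circoviridae", "frog_delta", n=1),
        spec("Circoviridae", "fish_epsilon", n=2),
        spec("Circoviridae", "snake_zeta", n=1),
        # Parvoviridae: 5 loci / 5 events
        spec("Parvoviridae", "bat_beta", n=1),
        spec("Parvoviridae", "rodent_gamma", n=1),
        spec("Parvoviridae", "frog_delta", n=1),
        spec("Parvoviridae", "snake_zeta", n=2),
        # Hepadnaviridae: 5 loci / 5 events
        spec("Hepadnaviridae", "bat_alpha", n=1),
        spec("Hepadnaviridae", "fish_epsilon", n=2),
        spec("Hepadnaviridae", "snake_zeta", n=2),
    ]
    expected_events = {
        "Bornaviridae": 7,
        "Filoviridae": 6,
        "Circoviridae": 6,
        "Parvoviridae": 5,
        "Hepadnaviridae": 5,
    }

    # virus/TE chimera: a transposon carrying hepadnavirus-derived sequence
    te_rng = _rng(seed, 10)
    te_aa = _mutate_protein(sources["Hepadnaviridae"], 0.08, te_rng)
    te_spec = ImplantSpec(
        virus_family="Teratorn",
        gene_name="P",
        source_aa=te_aa,
        host_species=("fish_epsilon",),
        sub_rate=0.05,
        stop_gain_count=0,
        category="transposon",
    )
    specs.append(te_spec)

    genome_params = GenomeParams(species=_SPECIES)
    tdb_root, truth = generate_target(specs, genome_params, seed, out_dir)

    decoys = [
        ("HostGene", "PolB", random_protein(240, _rng(seed, 11)), "host_gene"),
    ]
    rsl_path, probe_path, category_map = make_rsl_and_probes(specs, decoys, out_dir)

    tree_path = out_dir / "timetree.nwk"
    tree_path.write_text(_TREE_NEWICK + "\n")
    host_tsv = out_dir / "host_taxonomy.tsv"
    pd.DataFrame(_HOST_TAXONOMY, columns=["species_name", "host_order", "host_class"]).to_csv(
        host_tsv, sep="\t", index=False
    )

    control_file = out_dir / "control.yaml"
    control_file.write_text(
        "project:\n"
        "  name: fixture\n"
        "  db: fixture.sqlite\n"
        "paths:\n"
        "  target_database: tdb\n"
        "  probes: probes.faa\n"
        "  reference_library: rsl.faa\n"
        "  reference_categories: rsl_categories.tsv\n"
        "screen:\n"
        f"  random_seed: {seed}\n"
        "backend: naive\n"
    )
    return FixtureBundle(
        root=out_dir,
        control_file=control_file,
        tdb_root=tdb_root,
        rsl_path=rsl_path,
        probe_path=probe_path,
        truth=truth,
        truth_tsv=out_dir / "truth.tsv",
        tree_path=tree_path,
        host_taxonomy_tsv=host_tsv,
        category_map=category_map,
        expected_events=expected_events,
    )


def _mutate_protein(aa: str, rate: float, rng: np.random.Generator) -> str:
    out = list(aa)
    mask = rng.random(len(out)) < rate
    for i in np.nonzero(mask)[0]:
        choices = [c for c in _AA20 if c != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def evaluate_recovery(loci: pd.DataFrame, truth: pd.DataFrame, min_overlap: float = 0.5) -> pd.DataFrame:
    """Match truth implants to recovered loci.

    A truth record is *recovered* when exactly one locus on the same contig
    and strand overlaps at least ``min_overlap`` of the truth interval, and
    *correct* when that locus's assigned taxon equals the truth family.
    Returns the truth table with ``recovered``, ``n_overlapping``,
    ``assigned_taxon`` and ``correct_family`` columns.
    """
    rows = []
    for t in truth.itertuples(index=False):
        overlapping = loci[
            (loci["contig_id"] == t.contig)
            & (loci["strand"] == t.strand)
            & (loci["end"] >= t.start)
            & (loci["start"] <= t.end)
        ]
        frac = 0.0
        assigned = None
        if len(overlapping) > 0:
            best = overlapping.iloc[0]
            ov = min(best["end"], t.end) - max(best["start"], t.start) + 1
            frac = ov / (t.end - t.start + 1)
            assigned = best["assigned_taxon"]
        recovered = len(overlapping) == 1 and frac >= min_overlap
        rows.append(
            {
                **t._asdict(),
                "recovered": recovered,
                "n_overlapping": len(overlapping),
                "assigned_taxon": assigned,
                "correct_family": bool(recovered and assigned == t.virus_family),
            }
        )
    return pd.DataFrame(rows)
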