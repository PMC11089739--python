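"""Project store: an embedded, file-backed SQL database of screening results.

A screening project is a single SQLite file holding the status table
(searches performed), the results table (defragmented, classified loci), the
consolidated-loci table, the probe/reference libraries, target-database
metadata, and any number of user-imported "side" tables (host taxonomy,
virus taxonomy, ...) that extend the power of SQL queries over the results.

The store is deliberately embedded — zero-setup, single file, trivially
copyable — while remaining fully ANSI-SQL-queryable for downstream analysis.
"""

from __future__ import annotations

import datetime
import sqlite3
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyfaidx import Fasta

from .model import (
    ConsolidatedLocus,
    Locus,
    Probe,
    ReferenceSequence,
    SearchRecord,
    TargetFile,
    parse_header,
)

__all__ = ["Project", "ConfigurationError", "discover_targets", "load_probe_fasta", "load_rsl_fasta"]


class ConfigurationError(ValueError):
    """A control-file or project-configuration problem, naming the field."""


_SCHEMA = """
CREATE TABLE IF NOT EXISTS target_files (
    file_id TEXT PRIMARY KEY,
    species_name TEXT NOT NULL,
    data_type TEXT NOT NULL,
    assembly_version TEXT NOT NULL,
    path TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS contigs (
    file_id TEXT NOT NULL,
    contig_id TEXT NOT NULL,
    length_nt INTEGER NOT NULL CHECK (length_nt >= 1),
    PRIMARY KEY (file_id, contig_id)
);
CREATE TABLE IF NOT EXISTS probes (
    probe_id TEXT PRIMARY KEY,
    taxon_name TEXT NOT NULL,
    gene_name TEXT NOT NULL,
    molecule TEXT NOT NULL,
    sequence TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS rsl (
    ref_id TEXT PRIMARY KEY,
    taxon_name TEXT NOT NULL,
    gene_name TEXT NOT NULL,
    molecule TEXT NOT NULL,
    sequence TEXT NOT NULL,
    category TEXT NOT NULL DEFAULT 'virus'
);
CREATE TABLE IF NOT EXISTS searches (
    probe_id TEXT NOT NULL,
    target_file_id TEXT NOT NULL,
    algorithm TEXT NOT NULL,
    parameter_digest TEXT NOT NULL,
    status TEXT NOT NULL DEFAULT 'pending',
    completed_at TEXT,
    UNIQUE (probe_id, target_file_id, algorithm, parameter_digest)
);
CREATE TABLE IF NOT EXISTS results (
    locus_id INTEGER PRIMARY KEY AUTOINCREMENT,
    target_file_id TEXT NOT NULL,
    contig_id TEXT NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL,
    strand TEXT NOT NULL,
    extracted_sequence TEXT,
    assigned_taxon TEXT,
    assigned_gene TEXT,
    classification_bitscore REAL,
    classification_evalue REAL,
    classification_identity REAL,
    best_probe_id TEXT,
    n_merged_hits INTEGER NOT NULL DEFAULT 1
);
CREATE TABLE IF NOT EXISTS consolidated (
    consolidated_id INTEGER PRIMARY KEY AUTOINCREMENT,
    target_file_id TEXT NOT NULL,
    contig_id TEXT NOT NULL,
    span_start INTEGER NOT NULL,
    span_end INTEGER NOT NULL,
    structure TEXT NOT NULL,
    member_locus_ids TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS side_tables (
    name TEXT PRIMARY KEY,
    key_column TEXT NOT NULL
);
"""


def discover_targets(tdb_root: str | Path) -> list[TargetFile]:
    """Enumerate target files under ``<root>/<species>/<data_type>/<assembly>/*.fasta``.

    Species, data type and assembly version are derived from the path
    segments; ``file_id`` is the POSIX-style path relative to the root.
    Contig ids and lengths are read through a FASTA index (created on first
    use, cached beside the file).
    """
    root = Path(tdb_root)
    if not root.is_dir():
        raise ConfigurationError(f"target database path {root} is not a directory")
    targets = []
    for fasta_path in sorted(root.glob("*/*/*/*.fasta")) + sorted(root.glob("*/*/*/*.fa")):
        rel = fasta_path.relative_to(root)
        species, data_type, assembly = rel.parts[:3]
        idx = Fasta(str(fasta_path), build_index=True, rebuild=False)
        contigs = tuple((name, len(idx[name])) for name in idx.keys())
        targets.append(
            TargetFile(
                species_name=species,
                data_type=data_type,
                assembly_version=assembly,
                file_id=rel.as_posix(),
                path=str(fasta_path),
                contigs=contigs,
            )
        )
    return targets


def _read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    path = Path(path)
    if not path.is_file():
        raise ConfigurationError(f"FASTA path {path} does not exist")
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    return records


def _guess_molecule(sequence: str) -> str:
    letters = set(sequence.upper()) - {"-", "*"}
    return "nt" if letters <= set("ACGTUN") else "aa"


def load_probe_fasta(path: str | Path) -> list[Probe]:
    """Load probes from FASTA in the ``taxon_gene`` header dialect."""
    probes = []
    for header, seq in _read_fasta(path):
        taxon, gene = parse_header(header)
        probes.append(
            Probe(
                probe_id=header,
                taxon_name=taxon,
                gene_name=gene,
                molecule=_guess_molecule(seq),
                sequence=seq,
            )
        )
    return probes


def load_rsl_fasta(path: str | Path, category_map: dict[str, str] | None = None) -> list[ReferenceSequence]:
    """Load the reference sequence library from FASTA.

    ``category_map`` optionally assigns a category per header (or per taxon
    name); unmapped entries default to ``virus``.
    """
    refs = []
    category_map = category_map or {}
    for header, seq in _read_fasta(path):
        taxon, gene = parse_header(header)
        category = category_map.get(header, category_map.get(taxon, "virus"))
        refs.append(
            ReferenceSequence(
                ref_id=header,
                taxon_name=taxon,
                gene_name=gene,
                molecule=_guess_molecule(seq),
                sequence=seq,
                category=category,
            )
        )
    return refs


class Project:
    """Handle on a screening project's SQLite store.

    Creating a :class:`Project` on an existing database file is a no-op with
    respect to content: the schema statements are ``CREATE TABLE IF NOT
    EXISTS`` and registration methods upsert.
    """

    def __init__(self, db_path: str | Path):
        self.db_path = str(db_path)
        self._conn = sqlite3.connect(self.db_path)
        self._conn.row_factory = sqlite3.Row
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    # -- lifecycle -------------------------------------------------------

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "Project":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- registration ----------------------------------------------------

    def register_targets(self, targets: Iterable[TargetFile]) -> int:
        n = 0
        with self._conn:
            for t in targets:
                self._conn.execute(
                    "INSERT OR REPLACE INTO target_files VALUES (?,?,?,?,?)",
                    (t.file_id, t.species_name, t.data_type, t.assembly_version, t.path),
                )
                for cid, length in t.contigs:
                    self._conn.execute(
                        "INSERT OR REPLACE INTO contigs VALUES (?,?,?)",
                        (t.file_id, cid, length),
                    )
                n += 1
        return n

    def register_probes(self, probes: Iterable[Probe]) -> int:
        n = 0
        with self._conn:
            for p in probes:
                self._conn.execute(
                    "INSERT OR REPLACE INTO probes VALUES (?,?,?,?,?)",
                    (p.probe_id, p.taxon_name, p.gene_name, p.molecule, p.sequence),
                )
                n += 1
        return n

    def register_rsl(self, refs: Iterable[ReferenceSequence]) -> int:
        n = 0
        with self._conn:
            for r in refs:
                self._conn.execute(
                    "INSERT OR REPLACE INTO rsl VALUES (?,?,?,?,?,?)",
                    (r.ref_id, r.taxon_name, r.gene_name, r.molecule, r.sequence, r.category),
                )
                n += 1
        return n

    # -- typed accessors -------------------------------------------------

    def targets(self) -> list[TargetFile]:
        rows = self._conn.execute("SELECT * FROM target_files ORDER BY file_id").fetchall()
        out = []
        for row in rows:
            contigs = tuple(
                (c["contig_id"], c["length_nt"])
                for c in self._conn.execute(
                    "SELECT contig_id, length_nt FROM contigs WHERE file_id=? ORDER BY contig_id",
                    (row["file_id"],),
                )
            )
            out.append(
                TargetFile(
                    species_name=row["species_name"],
                    data_type=row["data_type"],
                    assembly_version=row["assembly_version"],
                    file_id=row["file_id"],
                    path=row["path"],
                    contigs=contigs,
                )
            )
        return out

    def target(self, file_id: str) -> TargetFile:
        for t in self.targets():
            if t.file_id == file_id:
                return t
        raise KeyError(f"unknown target file {file_id!r}")

    def probes(self) -> list[Probe]:
        rows = self._conn.execute("SELECT * FROM probes ORDER BY probe_id").fetchall()
        return [Probe(row["probe_id"], row["taxon_name"], row["gene_name"], row["molecule"], row["sequence"]) for row in rows]

    def rsl(self, category: str | None = None) -> list[ReferenceSequence]:
        sql = "SELECT * FROM rsl"
        params: tuple = ()
        if category is not None:
            sql += " WHERE category=?"
            params = (category,)
        rows = self._conn.execute(sql + " ORDER BY ref_id", params).fetchall()
        return [
            ReferenceSequence(
                row["ref_id"], row["taxon_name"], row["gene_name"],
                row["molecule"], row["sequence"], row["category"],
            )
            for row in rows
        ]

    # -- search status ---------------------------------------------------

    def done_searches(self) -> set[tuple[str, str, str, str]]:
        rows = self._conn.execute(
            "SELECT probe_id, target_file_id, algorithm, parameter_digest "
            "FROM searches WHERE status='done'"
        ).fetchall()
        return {(r[0], r[1], r[2], r[3]) for r in rows}

    def mark_search_done(self, probe_id: str, target_file_id: str, algorithm: str, digest: str) -> SearchRecord:
        nprobe = self._conn.execute("SELECT COUNT(*) FROM probes WHERE probe_id=?", (probe_id,)).fetchone()[0]
        ntarget = self._conn.execute("SELECT COUNT(*) FROM target_files WHERE file_id=?", (target_file_id,)).fetchone()[0]
        if not nprobe or not ntarget:
            raise LookupError(
                f"cannot mark unknown search done (probe={probe_id!r}, target={target_file_id!r})"
            )
        ts = datetime.datetime.now(datetime.timezone.utc).isoformat()
        with self._conn:
            self._conn.execute(
                "INSERT INTO searches (probe_id, target_file_id, algorithm, parameter_digest, status, completed_at) "
                "VALUES (?,?,?,?,'done',?) "
                "ON CONFLICT (probe_id, target_file_id, algorithm, parameter_digest) DO NOTHING",
                (probe_id, target_file_id, algorithm, digest, ts),
            )
        row = self._conn.execute(
            "SELECT * FROM searches WHERE probe_id=? AND target_file_id=? AND algorithm=? AND parameter_digest=?",
            (probe_id, target_file_id, algorithm, digest),
        ).fetchone()
        return SearchRecord(row["probe_id"], row["target_file_id"], row["algorithm"],
                            row["parameter_digest"], row["status"], row["completed_at"])

    # -- results table ---------------------------------------------------

    def loci(self, where: str | None = None, params: Sequence = ()) -> list[Locus]:
        sql = "SELECT * FROM results"
        if where:
            sql += f" WHERE {where}"
        sql += " ORDER BY target_file_id, contig_id, strand, start"
        return [self._row_to_locus(r) for r in self._conn.execute(sql, params)]

    @staticmethod
    def _row_to_locus(row: sqlite3.Row) -> Locus:
        return Locus(
            locus_id=row["locus_id"],
            target_file_id=row["target_file_id"],
            contig_id=row["contig_id"],
            start=row["start"],
            end=row["end"],
            strand=row["strand"],
            extracted_sequence=row["extracted_sequence"],
            assigned_taxon=row["assigned_taxon"],
            assigned_gene=row["assigned_gene"],
            classification_bitscore=row["classification_bitscore"],
            classification_evalue=row["classification_evalue"],
            classification_identity=row["classification_identity"],
            best_probe_id=row["best_probe_id"],
            n_merged_hits=row["n_merged_hits"],
        )

    def upsert_locus(self, locus: Locus) -> int:
        """Insert (locus_id None) or update a results-table row; returns locus_id."""
        vals = (
            locus.target_file_id, locus.contig_id, locus.start, locus.end, locus.strand,
            locus.extracted_sequence, locus.assigned_taxon, locus.assigned_gene,
            locus.classification_bitscore, locus.classification_evalue,
            locus.classification_identity, locus.best_probe_id, locus.n_merged_hits,
        )
        with self._conn:
            if locus.locus_id is None:
                cur = self._conn.execute(
                    "INSERT INTO results (target_file_id, contig_id, start, end, strand, "
                    "extracted_sequence, assigned_taxon, assigned_gene, classification_bitscore, "
                    "classification_evalue, classification_identity, best_probe_id, n_merged_hits) "
                    "VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?)",
                    vals,
                )
                locus.locus_id = cur.lastrowid
            else:
                self._conn.execute(
                    "UPDATE results SET target_file_id=?, contig_id=?, start=?, end=?, strand=?, "
                    "extracted_sequence=?, assigned_taxon=?, assigned_gene=?, classification_bitscore=?, "
                    "classification_evalue=?, classification_identity=?, best_probe_id=?, n_merged_hits=? "
                    "WHERE locus_id=?",
                    vals + (locus.locus_id,),
                )
        return locus.locus_id

    def delete_loci(self, locus_ids: Iterable[int]) -> None:
        with self._conn:
            self._conn.executemany(
                "DELETE FROM results WHERE locus_id=?", [(i,) for i in locus_ids]
            )

    def replace_loci_for_region(
        self, target_file_id: str, contig_id: str, strand: str, loci: list[Locus]
    ) -> None:
        """Atomically replace all results rows of one (file, contig, strand)."""
        with self._conn:
            self._conn.execute(
                "DELETE FROM results WHERE target_file_id=? AND contig_id=? AND strand=?",
                (target_file_id, contig_id, strand),
            )
            for locus in loci:
                cur = self._conn.execute(
                    "INSERT INTO results (target_file_id, contig_id, start, end, strand, "
                    "extracted_sequence, assigned_taxon, assigned_gene, classification_bitscore, "
                    "classification_evalue, classification_identity, best_probe_id, n_merged_hits) "
                    "VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?)",
                    (
                        locus.target_file_id, locus.contig_id, locus.start, locus.end, locus.strand,
                        locus.extracted_sequence, locus.assigned_taxon, locus.assigned_gene,
                        locus.classification_bitscore, locus.classification_evalue,
                        locus.classification_identity, locus.best_probe_id, locus.n_merged_hits,
                    ),
                )
                locus.locus_id = cur.lastrowid

    def store_consolidated(self, entries: list[ConsolidatedLocus]) -> int:
        with self._conn:
            self._conn.execute("DELETE FROM consolidated")
            for e in entries:
                cur = self._conn.execute(
                    "INSERT INTO consolidated (target_file_id, contig_id, span_start, span_end, "
                    "structure, member_locus_ids) VALUES (?,?,?,?,?,?)",
                    (
                        e.target_file_id, e.contig_id, e.span_start, e.span_end,
                        e.structure, ",".join(map(str, e.member_locus_ids)),
                    ),
                )
                e.consolidated_id = cur.lastrowid
        return len(entries)

    # -- side tables -----------------------------------------------------

    def import_side_table(self, name: str, tsv_path: str | Path, key_column: str) -> int:
        """Load a TSV (header required) as a side table; replaces any prior table.

        Keys must be unique.  Keys not present anywhere in the project (as a
        host species or an RSL taxon) are retained but trigger a warning, so
        typos in side data are visible without blocking annotation of
        yet-unscreened taxa.
        """
        path = Path(tsv_path)
        with open(path) as fh:
            first = fh.readline()
        if not first.strip() or "\t" not in first:
            raise ValueError(f"side table {path} has no tab-delimited header row")
        df = pd.read_csv(path, sep="\t", dtype=str)
        return self.import_side_frame(name, df, key_column)

    def import_side_frame(
        self, name: str, df: pd.DataFrame, key_column: str | Sequence[str]
    ) -> int:
        """Register a DataFrame as a side table (composite keys allowed)."""
        key_columns = [key_column] if isinstance(key_column, str) else list(key_column)
        for col in key_columns:
            if col not in df.columns:
                raise ValueError(f"key column {col!r} missing from side table {name!r}")
        keyed = df[key_columns]
        dupes = keyed[keyed.duplicated()].itertuples(index=False, name=None)
        dupes = sorted(set(dupes))
        if dupes:
            raise ValueError(f"duplicate keys in side table {name!r}: {dupes}")
        known = {r[0] for r in self._conn.execute("SELECT species_name FROM target_files")}
        known |= {r[0] for r in self._conn.execute("SELECT taxon_name FROM rsl")}
        known |= {r[0] for r in self._conn.execute("SELECT assigned_taxon FROM results WHERE assigned_taxon IS NOT NULL")}
        if known and len(key_columns) == 1:
            unknown = [k for k in df[key_columns[0]] if k not in known]
            if unknown:
                warnings.warn(
                    f"side table {name!r}: {len(unknown)} key(s) not present in project "
                    f"(e.g. {unknown[:3]}); rows retained",
                    stacklevel=2,
                )
        with self._conn:
            df.to_sql(name, self._conn, if_exists="replace", index=False)
            self._conn.execute(
                "INSERT OR REPLACE INTO side_tables VALUES (?,?)",
                (name, ",".join(key_columns)),
            )
        return len(df)

    def drop_side_table(self, name: str) -> None:
        registered = self._conn.execute(
            "SELECT COUNT(*) FROM side_tables WHERE name=?", (name,)
        ).fetchone()[0]
        if not registered:
            raise KeyError(f"no side table named {name!r}")
        with self._conn:
            self._conn.execute(f'DROP TABLE IF EXISTS "{name}"')
            self._conn.execute("DELETE FROM side_tables WHERE name=?", (name,))

    # -- SQL surface -----------------------------------------------------

    def query(self, sql: str, params: Sequence = ()) -> pd.DataFrame:
        """Run a read-only SQL statement against the project store.

        The statement is executed on a read-only connection, so any write
        attempt is refused by the engine itself; syntax errors surface
        verbatim as :class:`sqlite3.OperationalError`.
        """
        self._conn.commit()
        ro = sqlite3.connect(f"file:{self.db_path}?mode=ro", uri=True)
        try:
            cur = ro.execute(sql, tuple(params))
            columns = [d[0] for d in cur.description] if cur.description else []
            return pd.DataFrame(cur.fetchall(), columns=columns)
        finally:
            ro.close()

    # -- FASTA export ----------------------------------------------------

    def export_fasta(self, out_path: str | Path, sql_constraint: str | None = None) -> int:
        """Write selected results rows as FASTA; returns the record count.

        Headers encode ``locus_<id> <taxon> <gene> <file>:<contig>:<start>-<end>(<strand>)``.
        An empty selection produces an empty file and succeeds.
        """
        where = f" WHERE {sql_constraint}" if sql_constraint else ""
        rows = self._conn.execute(
            "SELECT locus_id, target_file_id, contig_id, start, end, strand, "
            f"extracted_sequence, assigned_taxon, assigned_gene FROM results{where} ORDER BY locus_id"
        ).fetchall()
        n = 0
        with open(out_path, "w") as fh:
            for row in rows:
                if row["extracted_sequence"] is None:
                    raise ValueError(f"locus {row['locus_id']} has no extracted sequence")
                header = (
                    f"locus_{row['locus_id']} {row['assigned_taxon'] or 'unclassified'} "
                    f"{row['assigned_gene'] or 'NULL'} "
                    f"{row['target_file_id']}:{row['contig_id']}:{row['start']}-{row['end']}({row['strand']})"
                )
                fh.write(f">{header}\n")
                seq = row["extracted_sequence"]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
                n += 1
        return n
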