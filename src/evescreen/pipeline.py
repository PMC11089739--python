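"""The screening loop: enumerate -> search -> merge -> extract -> classify -> record.

Screening proceeds search by search.  After each search, its raw hits are
merged into the results table (defragmentation), changed loci are
re-extracted and re-classified, and only then is the search recorded as
done.  That ordering makes interruption safe at any point: a killed run
re-executes at most the searches not yet recorded, and merging is
idempotent for hits already absorbed, so the final results table is
identical to an uninterrupted run's.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

from pyfaidx import Fasta

from .classify import classify_and_store
from .config import ProjectConfig, init_project
from .defragment import extract_locus_sequence, merge_hits
from .model import ScreenConfig
from .search import enumerate_pending, mark_done, run_search, select_backend
from .store import Project

__all__ = ["RunReport", "run_screen", "screen_project"]

log = logging.getLogger("evescreen")


@dataclass
class RunReport:
    searches_run: int = 0
    hits_found: int = 0
    loci_created: int = 0
    loci_updated: int = 0
    loci_deleted: int = 0
    seconds: float = 0.0
    parameters: dict = field(default_factory=dict)
    interrupted: bool = False


def screen_project(
    project: Project,
    config: ScreenConfig,
    backend_name: str = "naive",
    max_searches: int | None = None,
) -> RunReport:
    """Run all outstanding searches for a project (resumable).

    ``max_searches`` stops after that many searches — the remainder stays
    pending, exactly as after an interruption — which is how the restart
    contract is exercised in tests.
    """
    t0 = time.monotonic()
    backend = select_backend(backend_name, config)
    report = RunReport(parameters={"backend": backend.name, **config.search_parameters()})
    fasta_cache: dict[str, Fasta] = {}

    while True:
        tasks = enumerate_pending(project, config, backend_name)
        if not tasks:
            break
        for task in tasks:
            if max_searches is not None and report.searches_run >= max_searches:
                report.interrupted = True
                report.seconds = time.monotonic() - t0
                return report
            hits = run_search(task, backend, config)
            report.searches_run += 1
            report.hits_found += len(hits)
            if hits:
                existing = project.loci(
                    where="target_file_id=?", params=(task.target.file_id,)
                )
                existing_ids = {l.locus_id for l in existing}
                updated, changed = merge_hits(existing, hits, config.defragment_range_nt)
                kept_ids = {l.locus_id for l in updated if l.locus_id is not None}
                deleted = existing_ids - kept_ids
                if task.target.path not in fasta_cache:
                    fasta_cache[task.target.path] = Fasta(task.target.path, rebuild=False)
                idx = fasta_cache[task.target.path]
                for locus in changed:
                    locus.extracted_sequence = extract_locus_sequence(locus, idx)
                    project.upsert_locus(locus)
                    classify_and_store(project, locus, config)
                    if locus.locus_id in existing_ids:
                        report.loci_updated += 1
                    else:
                        report.loci_created += 1
                project.delete_loci(deleted)
                report.loci_deleted += len(deleted)
            mark_done(project, task)
            log.info(
                "search %s vs %s: %d hits",
                task.probe.probe_id,
                task.target.file_id,
                len(hits),
            )
    report.seconds = time.monotonic() - t0
    log.info(
        "screen complete: %d searches, %d hits, %d loci created, %d updated (%.1fs)",
        report.searches_run,
        report.hits_found,
        report.loci_created,
        report.loci_updated,
        report.seconds,
    )
    return report


def run_screen(control_file, max_searches: int | None = None) -> tuple[Project, RunReport]:
    """Initialise (or reopen) a project from a control file and screen it."""
    project, cfg = init_project(control_file)
    report = screen_project(project, cfg.screen, cfg.backend, max_searches=max_searches)
    return project, report
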