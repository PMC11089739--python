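"""Control-file parsing and project initialisation.

A screening project is described by a control file: a small YAML document
with three sections —

.. code-block:: yaml

    project:
      name: demo
      db: demo.sqlite            # optional; defaults to <name>.sqlite
    paths:
      target_database: tdb/      # <root>/<species>/<data_type>/<assembly>/*.fasta
      probes: probes.faa
      reference_library: rsl.faa
    screen:                      # optional overrides of ScreenConfig defaults
      bitscore_count_cutoff: 60
      defragment_range_nt: 100
    backend: naive               # naive | blast | auto

Relative paths are resolved against the control file's directory.  The
parser validates every field and raises :class:`ConfigurationError` naming
the offending field.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .model import ScreenConfig
from .store import ConfigurationError, Project, discover_targets, load_probe_fasta, load_rsl_fasta

__all__ = ["ProjectConfig", "parse_control_file", "init_project"]

_BACKENDS = ("naive", "blast", "auto")
_SCREEN_FIELDS = {f.name for f in dataclasses.fields(ScreenConfig)}


@dataclasses.dataclass
class ProjectConfig:
    name: str
    db_path: Path
    tdb_path: Path
    probe_path: Path
    rsl_path: Path
    screen: ScreenConfig
    backend: str = "naive"
    categories_path: Path | None = None


def parse_control_file(path: str | Path) -> ProjectConfig:
    path = Path(path)
    if not path.is_file():
        raise ConfigurationError(f"control file {path} does not exist")
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"control file {path} is not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigurationError("control file must be a mapping of sections")
    base = path.parent

    project = doc.get("project") or {}
    name = project.get("name")
    if not name:
        raise ConfigurationError("control file missing 'project: name'")

    paths = doc.get("paths") or {}
    missing = [k for k in ("target_database", "probes", "reference_library") if not paths.get(k)]
    if missing:
        labels = {
            "target_database": "target database path",
            "probes": "probe path",
            "reference_library": "reference library path",
        }
        raise ConfigurationError(
            "control file missing " + ", ".join(labels[k] for k in missing)
        )

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    tdb = resolve(paths["target_database"])
    if not tdb.is_dir():
        raise ConfigurationError(f"target database path {tdb} is not a directory")
    probe_path = resolve(paths["probes"])
    if not probe_path.is_file():
        raise ConfigurationError(f"probe path {probe_path} does not exist")
    rsl_path = resolve(paths["reference_library"])
    if not rsl_path.is_file():
        raise ConfigurationError(f"reference library path {rsl_path} does not exist")
    categories_path = None
    if paths.get("reference_categories"):
        categories_path = resolve(paths["reference_categories"])
        if not categories_path.is_file():
            raise ConfigurationError(
                f"reference categories path {categories_path} does not exist"
            )

    screen_doc = doc.get("screen") or {}
    unknown = set(screen_doc) - _SCREEN_FIELDS
    if unknown:
        raise ConfigurationError(f"unknown screen parameter(s): {sorted(unknown)}")
    screen = ScreenConfig(**screen_doc)

    backend = doc.get("backend", "naive")
    if backend not in _BACKENDS:
        raise ConfigurationError(f"backend must be one of {_BACKENDS}, got {backend!r}")

    db_path = resolve(project.get("db", f"{name}.sqlite"))
    return ProjectConfig(
        name=name,
        db_path=db_path,
        tdb_path=tdb,
        probe_path=probe_path,
        rsl_path=rsl_path,
        screen=screen,
        backend=backend,
        categories_path=categories_path,
    )


def init_project(control_file: str | Path) -> tuple[Project, ProjectConfig]:
    """Create (or reopen) the project store described by a control file.

    Registers targets, probes and the RSL; re-invocation on an existing
    project upserts the same rows and drops nothing, so it is an idempotent
    no-op when inputs are unchanged.
    """
    cfg = parse_control_file(control_file)
    cfg.db_path.parent.mkdir(parents=True, exist_ok=True)
    project = Project(cfg.db_path)
    project.register_targets(discover_targets(cfg.tdb_path))
    project.register_probes(load_probe_fasta(cfg.probe_path))
    category_map = None
    if cfg.categories_path is not None:
        category_map = {}
        with open(cfg.categories_path) as fh:
            header = fh.readline()  # ref_id <tab> category
            for line in fh:
                if line.strip():
                    ref_id, category = line.rstrip("\n").split("\t")[:2]
                    category_map[ref_id] = category
    project.register_rsl(load_rsl_fasta(cfg.rsl_path, category_map))
    return project, cfg
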