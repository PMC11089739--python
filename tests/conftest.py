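from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from evescreen.fixtures import GenomeParams, ImplantSpec, random_protein, standard_fixture
from evescreen.pipeline import run_screen


def check_non_redundancy(project, range_nt: int) -> None:
    """Assert the post-merge invariant: loci on one (file, contig, strand)
    are pairwise separated by more than the defragment range."""
    loci = project.loci()
    by_region = {}
    for l in loci:
        by_region.setdefault((l.target_file_id, l.contig_id, l.strand), []).append(l)
    for region, group in by_region.items():
        group.sort(key=lambda l: l.start)
        for a, b in zip(group, group[1:]):
            gap = b.start - a.end - 1
            assert gap > range_nt, (
                f"loci {a.locus_id} and {b.locus_id} in {region} separated by "
                f"{gap} <= {range_nt}"
            )


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The canonical seed-42 study system (generated once per session)."""
    return standard_fixture(tmp_path_factory.mktemp("stdfix"), seed=42)


@pytest.fixture(scope="session")
def screened(fixture_bundle):
    """The seed-42 fixture after a complete screening run."""
    project, report = run_screen(fixture_bundle.control_file)
    project.import_side_table(
        "host_taxonomy", fixture_bundle.host_taxonomy_tsv, key_column="species_name"
    )
    return project, report, fixture_bundle


def make_small_fixture(out_dir: Path, seed: int = 7):
    """A miniature 2-species, 2-family system for fast pipeline tests."""
    import numpy as np

    from evescreen.fixtures import generate_target, make_rsl_and_probes

    rng = np.random.default_rng(seed + 1000)
    src_a = random_protein(180, rng)
    src_b = random_protein(180, rng)
    specs = [
        ImplantSpec("FamA", "N", src_a, ("sp_a",), n_copies=1, sub_rate=0.1),
        ImplantSpec("FamA", "N", src_a, ("sp_b",), n_copies=1, sub_rate=0.1),
        ImplantSpec("FamB", "L", src_b, ("sp_a",), n_copies=1, sub_rate=0.1),
        ImplantSpec("FamB", "L", src_b, ("sp_b",), n_copies=1, sub_rate=0.1),
    ]
    params = GenomeParams(species=("sp_a", "sp_b"), n_contigs=1, contig_length=9000)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tdb, truth = generate_target(specs, params, seed, out_dir)
    make_rsl_and_probes(specs, [], out_dir)
    control = out_dir / "control.yaml"
    control.write_text(
        "project:\n  name: small\n  db: small.sqlite\n"
        "paths:\n  target_database: tdb\n  probes: probes.faa\n"
        "  reference_library: rsl.faa\n  reference_categories: rsl_categories.tsv\n"
        "backend: naive\n"
    )
    return control, truth


@pytest.fixture()
def small_fixture(tmp_path):
    return make_small_fixture(tmp_path)
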