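from __future__ import annotations

import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

from circseam import (
    Dialect,
    FixtureSpec,
    make_fixture,
    open_genome,
    parse_records,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def write_fasta(path: Path, contigs: dict[str, str], width: int = 60) -> Path:
    with path.open("w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


@pytest.fixture(scope="session")
def std_fixture(tmp_path_factory):
    """A 10-circle synthetic dataset used across modules."""
    out = tmp_path_factory.mktemp("std_fixture")
    return make_fixture(
        FixtureSpec(seed=11, n_circles=10, gc=0.6, contig_len=20_000), out
    )


@pytest.fixture(scope="session")
def std_genome(std_fixture):
    return open_genome(std_fixture.genome_fasta)


@pytest.fixture(scope="session")
def std_batch(std_fixture):
    return parse_records(std_fixture.call_files[Dialect.BED])


@pytest.fixture()
def toy_genome(tmp_path):
    """Two short hand-written contigs."""
    path = write_fasta(
        tmp_path / "toy.fa",
        {"chrA": "ACGTACGT", "chrB": "AAAACCCC"},
    )
    return open_genome(path)
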