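import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from subsysfocus.subsystem_db import build_clustered_database
from subsysfocus.synthetic import generate_community, generate_reads, generate_subsystem_db


@pytest.fixture(scope="session")
def small_proteins():
    """12 subsystems x 2 families x 3 sequences at ~95% family identity."""
    return generate_subsystem_db(
        n_level1=3, n_level3_per_level1=4, families_per_subsystem=2,
        seqs_per_family=3, within_family_identity=95.0, seed=11,
        min_len=80, max_len=160,
    )


@pytest.fixture(scope="session")
def small_db(small_proteins):
    return build_clustered_database(small_proteins, 100.0)


@pytest.fixture(scope="session")
def small_db_90(small_proteins):
    return build_clustered_database(small_proteins, 90.0)


@pytest.fixture(scope="session")
def small_community(small_db):
    genomes, truth = generate_community(
        small_db, n_genera=3, species_per_genus=2, subsystems_per_genus=4, seed=7,
    )
    return genomes, truth


@pytest.fixture(scope="session")
def small_reads(small_community):
    genomes, _truth = small_community
    abundances = {"Genus0": 0.5, "Genus1": 0.3, "Genus2": 0.2}
    reads, truths = generate_reads(
        genomes, abundances, n_reads=120, read_length=120, error_rate=0.0, seed=3,
    )
    return reads, truths
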