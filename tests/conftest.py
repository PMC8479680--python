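import pytest

from hogmapper import (
    HOGHierarchy,
    Protein,
    ReferenceDB,
    build_kmer_table,
)
from hogmapper.synthetic import SimParams, make_fixture


@pytest.fixture
def toy_hierarchy():
    """One family with two sibling sub-HOGs, one nested; plus a second family."""
    rows = [
        ("H1", None, "root"),
        ("H1.1", "H1", "dup1"),
        ("H1.2", "H1", "dup1"),
        ("H1.1.1", "H1.1", "dup2"),
        ("H1.1.2", "H1.1", "dup2"),
        ("G1", None, "root"),
        ("G1.1", "G1", "dup1"),
    ]
    return HOGHierarchy(rows)


@pytest.fixture
def toy_db(toy_hierarchy):
    prots = {
        "A_P1": Protein("A_P1", "A", "ACDEFGHIK", "H1.1.1"),
        "B_P2": Protein("B_P2", "B", "ACDEFGMNP", "H1.1.2"),
        "A_P3": Protein("A_P3", "A", "WYWYWYACD", "H1.2"),
        "B_P4": Protein("B_P4", "B", "KLMNPQRST", "G1.1"),
        "C_P5": Protein("C_P5", "C", "ACDKLMNPQ", "H1"),
    }
    return ReferenceDB(prots, toy_hierarchy, k=3)


@pytest.fixture(scope="session")
def small_fixture():
    """3-family / ~40-protein synthetic fixture used by the oracle tests (k=3)."""
    params = SimParams(
        n_families=3, n_species=8, duplication_rate=1.0, seed=11, root_length=80
    )
    return make_fixture(params, k=3)


@pytest.fixture(scope="session")
def small_table(small_fixture):
    return build_kmer_table(small_fixture.reference)


@pytest.fixture(scope="session")
def full_small_table(small_fixture):
    """Table over the *full* small DB (query species included): self-query tests."""
    return build_kmer_table(small_fixture.full)
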