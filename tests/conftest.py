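import pytest

from rflp_typer import build_key, published_key
from rflp_typer.fixtures import (
    default_pattern_table,
    generate_fixture_set,
    mtorf_alignment,
    pochistone_alignment,
)


@pytest.fixture(scope="session")
def fixture_set():
    return generate_fixture_set(seed=1)


@pytest.fixture(scope="session")
def fixture_set_extra():
    return generate_fixture_set(seed=1, include_extra_haplotypes=True)


@pytest.fixture(scope="session")
def pattern_table(fixture_set):
    return default_pattern_table(fixture_set)


@pytest.fixture(scope="session")
def greedy_key(pattern_table):
    return build_key(pattern_table)


@pytest.fixture(scope="session")
def lab_key(pattern_table):
    """The fixed published cascade."""
    return published_key(pattern_table)


@pytest.fixture(scope="session")
def mtorf_aln(fixture_set):
    """mtORF alignment with haplotype grouping (eydouxi+meandrina pooled)."""
    return mtorf_alignment(fixture_set, group_by="haplotype")


@pytest.fixture(scope="session")
def mtorf_aln_extra(fixture_set_extra):
    return mtorf_alignment(fixture_set_extra, group_by="haplotype")


@pytest.fixture(scope="session")
def hist_aln(fixture_set):
    return pochistone_alignment(fixture_set)
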