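import pytest

from h1yinyang import fixtures
from h1yinyang.synthetic_data import SyntheticFamilyConfig, generate_family


@pytest.fixture(scope="session")
def h1_records():
    """The nine bundled synthetic H1 stand-ins (met-cleaved numbering)."""
    return fixtures.synthetic_h1_records()


@pytest.fixture(scope="session")
def h1_by_id(h1_records):
    return {r.id: r for r in h1_records}


@pytest.fixture(scope="session")
def fixture_tables(h1_records):
    phospho, glyco = fixtures.fixture_score_tables(h1_records)
    return {
        "phospho": phospho,
        "glyco": glyco,
        "evidence": fixtures.fixture_evidence(h1_records),
        "conservation": fixtures.fixture_conservation(h1_records),
        "motifs": fixtures.fixture_motif_hits(h1_records),
    }


@pytest.fixture(scope="session")
def small_family():
    return generate_family(SyntheticFamilyConfig(seed=11, length=120, n_motifs=5))
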