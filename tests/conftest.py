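import pytest

from goxprofile.conservation import load_property_table
from goxprofile.motifs import load_known_patterns
from goxprofile.seqio import SequenceRecord
from goxprofile.synthetic import SimulationConfig, simulate_family


@pytest.fixture(scope="session")
def known_patterns():
    return load_known_patterns()


@pytest.fixture(scope="session")
def props():
    return load_property_table()


@pytest.fixture
def make_record():
    def _make(accession, residues, **kw):
        kw.setdefault("description", accession)
        return SequenceRecord(accession=accession, residues=residues, **kw)

    return _make


@pytest.fixture(scope="session")
def small_family():
    """24-sequence, 2-clade family with 10% planted exclusion keywords."""
    return simulate_family(
        SimulationConfig(n_sequences=24, n_clades=2, keyword_fraction=0.1, seed=3)
    )
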