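import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from histodiff import QuantTable, default_mass_table
from histodiff.synthetic_reference import QUERY_PROTEINS

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mass_table():
    return default_mass_table()


@pytest.fixture(scope="session")
def reference_proteins():
    """Synthetic tilapia-style histone tails carrying the worked sites."""
    return dict(QUERY_PROTEINS)


def make_quant_table(rows):
    """rows: (modified_sequence, digest, sample_id, area)"""
    return QuantTable(pd.DataFrame(
        rows, columns=["modified_sequence", "digest", "sample_id", "normalized_area"]
    ))


@pytest.fixture
def h3_two_form_table():
    """One modified + one unmodified H3 K14 peptide in one digest/sample."""
    return make_quant_table([
        ("K[+112]STGGK[+42]APR", "trypsin_propionyl", "s1", 200.0),
        ("K[+112]STGGK[+56]APR", "trypsin_propionyl", "s1", 800.0),
    ])
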