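import pytest

from mrmquant.masses import default_mass_table
from mrmquant.proteome import extract_chain
from mrmquant.reference_data import REFERENCE_PEPTIDES
from mrmquant.synthetic import demo_proteins, reference_assay, reference_sample_sheet


@pytest.fixture(scope="session")
def masses():
    return default_mass_table()


@pytest.fixture(scope="session")
def ref_peptides():
    return REFERENCE_PEPTIDES


@pytest.fixture(scope="session")
def demo_precursors():
    return demo_proteins()


@pytest.fixture(scope="session")
def demo_matures(demo_precursors):
    return [extract_chain(p, "mature") for p in demo_precursors]


@pytest.fixture(scope="session")
def ref_assay():
    return reference_assay()


@pytest.fixture(scope="session")
def ref_sheet():
    return reference_sample_sheet()
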