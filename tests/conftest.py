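import pytest

from genid_audit import build_index, load_fixture


@pytest.fixture(scope="session")
def table1():
    """Six-gene published annotation fixture (Hg17/Hg18/Hg19)."""
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table1_plus_optc():
    return load_fixture("table1_hg19_plus_optc")


@pytest.fixture(scope="session")
def table2():
    """Published multi-database position rows for rs2844871."""
    return load_fixture("table2")


@pytest.fixture(scope="session")
def rs2844871(table2):
    (snp,) = table2
    return snp


@pytest.fixture(scope="session")
def index1(table1):
    return build_index(table1)


SIX_TERM_LIST = ["TOSO", "PIGR", "FCAMR", "ADRA1A", "ADRA1B", "ADRA1D"]
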