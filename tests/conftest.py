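from pathlib import Path

import pytest

from radiomir import load_direction_table, load_table1

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def table1():
    """The packaged transcription of the in vitro screen table."""
    return load_table1()


@pytest.fixture(scope="session")
def direction_table():
    return load_direction_table()


@pytest.fixture(scope="session")
def table1_by_id(table1):
    return {r.mirna_id: r for r in table1}


@pytest.fixture
def regression_hits_path():
    return DATA_DIR / "hits_atm_null_regression.tsv"
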