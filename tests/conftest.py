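import pandas as pd
import pytest

from dupletscan import datasets


@pytest.fixture(scope="session")
def zro2_table() -> pd.DataFrame:
    return datasets.zro2_table()


@pytest.fixture(scope="session")
def zno_table() -> pd.DataFrame:
    return datasets.zno_table()


@pytest.fixture(scope="session")
def all_reference_rows(zro2_table, zno_table) -> pd.DataFrame:
    """The 20 published peptide rows (both substrates), with provenance."""
    zro2 = zro2_table.assign(substrate="ZrO2")
    zno = zno_table.assign(substrate="ZnO")
    return pd.concat([zro2, zno], ignore_index=True)
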