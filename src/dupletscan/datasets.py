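"""Bundled peptide fixtures.

The 16 zirconia-binding and 4 zinc-oxide-binding 12-mers that survive
the 25% charged-residue filter ship with the package, together with
their published reference columns (charge counts, duplet flag, net
charge at pH 7 and pI), so the full screening pipeline runs with zero
downloads.  Note that HYPTAKFHAERL appears in both sets; the two sets
are treated as independent per-substrate inputs.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .seqio import SequenceRecord

FIXTURES = {
    "zro2": "zro2_peptides.txt",
    "zno": "zno_peptides.txt",
}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("dupletscan.data").joinpath(name)))


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled one-per-line peptide list
    (``zro2`` or ``zno``)."""
    try:
        return _data_path(FIXTURES[name.lower()])
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURES))}"
        ) from None


def _reference(name: str) -> pd.DataFrame:
    return pd.read_csv(_data_path(name), sep="\t")


def zro2_table() -> pd.DataFrame:
    """Published reference rows for the highly charged ZrO₂-binding peptides."""
    return _reference("zro2_reference.tsv")


def zno_table() -> pd.DataFrame:
    """Published reference rows for the highly charged ZnO-binding peptides."""
    return _reference("zno_reference.tsv")


def _records(df: pd.DataFrame, prefix: str) -> list[SequenceRecord]:
    return [
        SequenceRecord(id=f"{prefix}_{i + 1:02d}", residues=seq)
        for i, seq in enumerate(df["Sequence"])
    ]


def zro2_peptides() -> list[SequenceRecord]:
    """The 16 highly charged zirconia-binding 12-mers."""
    return _records(zro2_table(), "zro2")


def zno_peptides() -> list[SequenceRecord]:
    """The 4 highly charged zinc-oxide-binding 12-mers."""
    return _records(zno_table(), "zno")
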