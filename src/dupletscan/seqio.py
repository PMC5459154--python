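"""Sequence input/output, validation and deduplication.

Protein and peptide sequences enter the pipeline either as multi-record
FASTA files or as plain peptide lists (one sequence per line, or a
delimited table with a sequence column).  All residues are validated
against the amino-acid alphabet extended with the ambiguity codes B
(Asx), Z (Glx) and X (unknown).  Exact-duplicate peptides are collapsed
to the "technical diversity" of a selection experiment: each distinct
sequence counts once, however many clones carried it.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUITY_AA = frozenset("BZX")
ALPHABET = STANDARD_AA | AMBIGUITY_AA


def validate_residues(residues: str, *, record_id: str = "?") -> str:
    """Uppercase *residues* and check every character against the alphabet.

    Returns the validated (uppercased) string.  Raises ``ValueError``
    naming the record and the 1-based position of the first offending
    character.
    """
    seq = residues.strip().upper()
    if not seq:
        raise ValueError(f"record {record_id!r}: empty sequence")
    for pos, ch in enumerate(seq, start=1):
        if ch not in ALPHABET:
            raise ValueError(
                f"record {record_id!r}: invalid residue {ch!r} at position {pos}"
            )
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """An identified amino-acid sequence with a validated alphabet."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residues", validate_residues(self.residues, record_id=self.id)
        )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly empty) multi-record FASTA file.

    Headers are split at the first whitespace into id and description;
    residues are uppercased and validated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split(None, 1)
        description = parts[1] if len(parts) == 2 else ""
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq), description=description)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA (60-column wrapping is not applied; peptide
    and motif sequences are short and single-line entries round-trip
    byte-identically)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(f"{header}\n{rec.residues}\n")


def _sequence_column(df: pd.DataFrame, column: str | int | None) -> pd.Series:
    if isinstance(column, int):
        if column >= df.shape[1]:
            raise ValueError(f"column index {column} out of range")
        return df.iloc[:, column]
    if isinstance(column, str):
        for name in df.columns:
            if str(name).lower() == column.lower():
                return df[name]
        raise ValueError(f"no column named {column!r} in table")
    for name in df.columns:
        if str(name).lower() in ("sequence", "seq", "peptide"):
            return df[name]
    return df.iloc[:, 0]


def read_peptide_list(
    path: str | Path, column: str | int | None = None
) -> list[SequenceRecord]:
    """Read peptides from a plain list or a delimited table.

    A file whose first non-empty line contains a tab or comma is parsed
    as a table (header row expected); *column* selects the sequence
    column by name or 0-based index, defaulting to a column named
    ``Sequence`` (case-insensitive) or the first column.  Otherwise the
    file is read one sequence per line.  Records get auto-generated ids
    ``pep_0001`` ... unless the table carries an ``id`` column.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    delimited = "\t" in first or "," in first

    if delimited:
        sep = "\t" if "\t" in first else ","
        df = pd.read_csv(path, sep=sep, dtype=str)
        seqs = _sequence_column(df, column)
        ids: Sequence[str] | None = None
        for name in df.columns:
            if str(name).lower() == "id":
                ids = df[name].astype(str).tolist()
                break
        records = []
        for i, raw in enumerate(seqs):
            rid = ids[i] if ids is not None else f"pep_{i + 1:04d}"
            if raw is None or (isinstance(raw, float) and pd.isna(raw)) or not str(raw).strip():
                raise ValueError(f"record {rid!r}: empty sequence cell (row {i + 1})")
            records.append(SequenceRecord(id=rid, residues=str(raw)))
        return records

    records = []
    n = 0
    for line in text.splitlines():
        seq = line.strip()
        if not seq or seq.startswith("#"):
            continue
        n += 1
        records.append(SequenceRecord(id=f"pep_{n:04d}", residues=seq))
    return records


def dedupe(records: Iterable[SequenceRecord]) -> list[SequenceRecord]:
    """Collapse exact-sequence duplicates, keeping the first occurrence.

    Near-duplicates (sequences differing in any residue) are kept
    separate; the result preserves input order and the operation is
    idempotent.
    """
    seen: set[str] = set()
    out: list[SequenceRecord] = []
    for rec in records:
        if rec.residues not in seen:
            seen.add(rec.residues)
            out.append(rec)
    return out


def _round_half_up(value: float, places: int) -> str:
    quantum = Decimal(1).scaleb(-places)
    return str(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def format_cell(column: str, value: Any) -> str:
    """Render one table cell: pI-like columns at 2 decimals (half-up),
    percentage columns at 1 decimal, booleans as Yes/No."""
    if isinstance(value, bool):
        return "Yes" if value else "No"
    if value is None:
        return ""
    if isinstance(value, float):
        name = column.lower()
        if name == "pi" or name.endswith("_pi") or name.endswith("pi"):
            return _round_half_up(value, 2)
        if "percent" in name or "mol" in name or name.endswith("%"):
            return _round_half_up(value, 1)
        return f"{value:.6g}"
    return str(value)


def _cell(row: Mapping[str, Any] | Any, column: str) -> Any:
    if isinstance(row, Mapping):
        if column not in row:
            raise ValueError(f"row missing column {column!r}")
        return row[column]
    if not hasattr(row, column):
        raise ValueError(f"row missing column {column!r}")
    return getattr(row, column)


def write_table(
    rows: Iterable[Mapping[str, Any] | Any],
    schema: Sequence[str],
    path: str | Path,
) -> None:
    """Write rows (mappings or attribute-bearing objects) as a TSV with a
    header line, UTF-8, LF endings, input order preserved."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(schema) + "\n")
        for row in rows:
            fh.write(
                "\t".join(format_cell(col, _cell(row, col)) for col in schema) + "\n"
            )
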