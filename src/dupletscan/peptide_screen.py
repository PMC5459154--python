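"""Re-evaluation of inorganic-binding peptide sets.

Mirrors how phage-display peptide pools are re-screened for the duplet
motif: collapse to technical diversity, keep peptides whose {K,R,D,E}
fraction clears a threshold (25% for 12-mers, the analogue of the 20%
protein criterion), then tabulate per-peptide charge counts, duplet
flag and orientations, integer net charge at pH 7 (counting rule) and
isoelectric point, sorted by pI ascending as such tables are printed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .duplet_motif import find_duplets
from .physchem import (
    CRITERION_CHARGED,
    DEFAULT_SCHEME,
    ChargeScheme,
    PKaSet,
    charged_fraction,
    count_charges,
    isoelectric_point,
)
from .seqio import SequenceRecord, dedupe


@dataclass
class PeptideScreenRecord:
    """One screened peptide: charge counts, duplet flag/orientations,
    counting-rule net charge at pH 7 and pI."""

    sequence: str
    n_negative: int
    n_positive: int
    has_duplet: bool
    orientations: list[str] = field(default_factory=list)
    net_charge: int = 0
    pI: float = float("nan")


@dataclass
class HistBin:
    """One half-open pI histogram bin [low, high) with count and percent;
    the outermost bins are open-ended."""

    low: float
    high: float
    count: int
    percent: float

    @property
    def label(self) -> str:
        import math

        if math.isinf(self.low):
            return f"<{self.high:g}"
        if math.isinf(self.high):
            return f">={self.low:g}"
        return f"[{self.low:g},{self.high:g})"


@dataclass
class ScreenSummary:
    """Aggregate view of one screened peptide set."""

    n_input: int
    n_unique: int
    n_highly_charged: int
    n_with_duplet: int
    fraction_with_duplet: float  # percent of highly charged peptides
    orientation_tally: dict[str, int] = field(default_factory=dict)
    pI_histogram: list[HistBin] = field(default_factory=list)


def evaluate_peptide(
    seq: str,
    scheme: ChargeScheme = DEFAULT_SCHEME,
    pka: PKaSet | None = None,
) -> PeptideScreenRecord:
    """Compute the full screen row for one peptide sequence."""
    n_neg, n_pos = count_charges(seq, scheme)
    hits = find_duplets(seq)
    return PeptideScreenRecord(
        sequence=seq.upper(),
        n_negative=n_neg,
        n_positive=n_pos,
        has_duplet=bool(hits),
        orientations=[h.orientation for h in hits],
        net_charge=n_pos - n_neg,
        pI=isoelectric_point(seq, pka),
    )


def pI_histogram(
    records: Sequence[PeptideScreenRecord],
    bin_edges: Sequence[float] = (7.0, 8.0, 8.5),
) -> list[HistBin]:
    """Bin record pI values into (−inf, e₀), [e₀, e₁), …, [eₙ, +inf).

    Edges must be strictly increasing; percentages use the number of
    records as denominator (all-zero bins for an empty input).
    """
    edges = [float(e) for e in bin_edges]
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError(f"bin edges must be strictly increasing: {edges}")
    bounds = [float("-inf"), *edges, float("inf")]
    counts = [0] * (len(bounds) - 1)
    for rec in records:
        for i, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
            if lo <= rec.pI < hi:
                counts[i] += 1
                break
    total = len(records)
    return [
        HistBin(lo, hi, c, 100.0 * c / total if total else 0.0)
        for (lo, hi), c in zip(zip(bounds, bounds[1:]), counts)
    ]


def screen_peptides(
    records: Iterable[SequenceRecord],
    min_charged_frac: float = 0.25,
    scheme: ChargeScheme = DEFAULT_SCHEME,
    pka: PKaSet | None = None,
    bin_edges: Sequence[float] = (7.0, 8.0, 8.5),
) -> tuple[list[PeptideScreenRecord], ScreenSummary]:
    """Deduplicate, filter by charged fraction, and tabulate peptides.

    Returns the passing rows sorted by pI ascending (ties broken by
    sequence, so the output is stable under input shuffling) together
    with a :class:`ScreenSummary`.
    """
    records = list(records)
    if not records:
        raise ValueError("screen_peptides needs at least one input record")
    unique = dedupe(records)
    passing_seqs = [
        r.residues
        for r in unique
        if charged_fraction(r.residues, CRITERION_CHARGED) >= min_charged_frac
    ]
    rows = [evaluate_peptide(s, scheme, pka) for s in passing_seqs]
    rows.sort(key=lambda r: (r.pI, r.sequence))

    flagged = [r for r in rows if r.has_duplet]
    tally: Counter[str] = Counter()
    for r in flagged:
        tally.update(r.orientations)
    summary = ScreenSummary(
        n_input=len(records),
        n_unique=len(unique),
        n_highly_charged=len(rows),
        n_with_duplet=len(flagged),
        fraction_with_duplet=100.0 * len(flagged) / len(rows) if rows else 0.0,
        orientation_tally=dict(tally),
        pI_histogram=pI_histogram(rows, bin_edges),
    )
    return rows, summary
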