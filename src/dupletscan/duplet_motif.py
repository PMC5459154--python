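"""Duplet motif detection and minimal-window protein screening.

A *duplet* is a pair of adjacent residues of opposite charge: one of
{K, R} next to one of {D, E}, in either order (KD, DK, KE, EK, RD, DR,
RE, ER).  Duplets are counted under a non-overlap rule with a greedy
left-to-right scan — for unit-length pairs the greedy earliest-end
choice attains the true maximum number of non-overlapping pairs.  Under
this convention the Ni₃B-binding heptamer LGFREKE carries exactly two
duplets (RE, KE), not the three overlapping pairs a sliding count would
give.

Proteins are screened with the biomineralization-protein criterion: at
least ``k`` duplets (default 5) within a window of at most
``max_window`` residues (default 50) that itself holds a minimum
charged fraction (default 20% of {K, R, D, E}).  The screen reports the
*minimal* window containing k duplets together with the composition
statistics usually tabulated for such regions: window length, K/R/D/E
counts, mol% charged under the extended set, and the window and
full-sequence isoelectric points.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

from .physchem import (
    CRITERION_CHARGED,
    DEFAULT_SCHEME,
    ChargeScheme,
    PKaSet,
    charged_fraction,
    isoelectric_point,
)
from .seqio import SequenceRecord

ACIDIC = frozenset("DE")
BASIC = frozenset("KR")

ACIDIC_FIRST = "acidic_first"
BASIC_FIRST = "basic_first"


def is_duplet_pair(a: str, b: str) -> bool:
    """True iff residues *a*, *b* form an oppositely charged adjacent pair."""
    return (a in ACIDIC and b in BASIC) or (a in BASIC and b in ACIDIC)


@dataclass(frozen=True)
class DupletHit:
    """One adjacent oppositely charged pair.

    ``start`` is the 0-based index of the first residue; ``orientation``
    is ``acidic_first`` when the acidic residue leads (e.g. ER) and
    ``basic_first`` otherwise (e.g. KD).
    """

    start: int
    pair: str
    orientation: str

    @property
    def end(self) -> int:
        return self.start + 2


def _hit(seq: str, i: int) -> DupletHit:
    pair = seq[i : i + 2]
    orientation = ACIDIC_FIRST if pair[0] in ACIDIC else BASIC_FIRST
    return DupletHit(start=i, pair=pair, orientation=orientation)


def find_duplets(seq: str) -> list[DupletHit]:
    """Maximal set of mutually non-overlapping duplets, greedy left-to-right.

    Scan i = 0 … len−2; when seq[i], seq[i+1] form a duplet, emit it and
    advance by two, else by one.
    """
    seq = seq.upper()
    hits: list[DupletHit] = []
    i, n = 0, len(seq)
    while i < n - 1:
        if is_duplet_pair(seq[i], seq[i + 1]):
            hits.append(_hit(seq, i))
            i += 2
        else:
            i += 1
    return hits


def has_duplet(seq: str) -> bool:
    """True iff the sequence contains at least one duplet."""
    seq = seq.upper()
    return any(is_duplet_pair(seq[i], seq[i + 1]) for i in range(len(seq) - 1))


def duplet_positions(seq: str) -> list[int]:
    """All start indices of adjacent opposite-charge pairs (overlaps allowed)."""
    seq = seq.upper()
    return [i for i in range(len(seq) - 1) if is_duplet_pair(seq[i], seq[i + 1])]


@dataclass
class MotifRegion:
    """A contiguous window carrying ≥ k non-overlapping duplets plus its
    composition statistics (0-based half-open coordinates)."""

    seq_id: str
    start: int
    end: int
    duplets: list[DupletHit] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    mol_percent_charged: float = 0.0
    pI_region: float = float("nan")

    @property
    def length_aa(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def build_region(
    seq: str,
    seq_id: str,
    start: int,
    end: int,
    duplets: list[DupletHit],
    scheme: ChargeScheme = DEFAULT_SCHEME,
    pka: PKaSet | None = None,
) -> MotifRegion:
    """Assemble a :class:`MotifRegion` with its window statistics."""
    window = seq.upper()[start:end]
    counts = {res: window.count(res) for res in "KRDE"}
    return MotifRegion(
        seq_id=seq_id,
        start=start,
        end=end,
        duplets=sorted(duplets, key=lambda h: h.start),
        counts=counts,
        mol_percent_charged=100.0 * charged_fraction(window, scheme.extended_charged),
        pI_region=isoelectric_point(window, pka),
    )


def minimal_duplet_window(
    seq: str,
    k: int = 5,
    *,
    seq_id: str = "",
    scheme: ChargeScheme = DEFAULT_SCHEME,
    pka: PKaSet | None = None,
) -> MotifRegion | None:
    """Shortest window containing at least *k* non-overlapping duplets.

    Anchors on every duplet start position, greedily chains the next
    non-overlapping duplets (earliest start = earliest end for
    unit-length pairs, which is optimal) and minimizes the span from the
    anchor to the end of the k-th chained duplet.  Ties go to the
    smallest start.  Returns ``None`` when no window exists.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    seq = seq.upper()
    positions = duplet_positions(seq)
    best: tuple[int, int, list[int]] | None = None  # (length, start, chain)
    for anchor_idx, anchor in enumerate(positions):
        chain = [anchor]
        cursor = anchor
        while len(chain) < k:
            nxt = bisect_left(positions, cursor + 2)
            if nxt == len(positions):
                chain = []
                break
            cursor = positions[nxt]
            chain.append(cursor)
        if not chain:
            break  # later anchors cannot reach k duplets either
        length = chain[-1] + 2 - anchor
        if best is None or length < best[0]:
            best = (length, anchor, chain)
    if best is None:
        return None
    _, start, chain = best
    return build_region(
        seq,
        seq_id,
        start,
        chain[-1] + 2,
        [_hit(seq, p) for p in chain],
        scheme,
        pka,
    )


@dataclass
class ProteinScreenRecord:
    """A protein passing the duplet-window criterion: the motif region
    plus full-sequence length, pI and extended mol% charged."""

    seq_id: str
    motif: MotifRegion
    full_length_aa: int
    full_pI: float
    full_mol_percent_charged: float


def screen_protein(
    record: SequenceRecord,
    k: int = 5,
    max_window: int = 50,
    min_charged_frac: float = 0.20,
    scheme: ChargeScheme = DEFAULT_SCHEME,
    pka: PKaSet | None = None,
) -> ProteinScreenRecord | None:
    """Apply the duplet-rich-region criterion to one protein.

    Returns ``None`` when no window with *k* duplets exists, when the
    minimal such window exceeds *max_window* residues, or when the
    window's {K, R, D, E} fraction falls below *min_charged_frac*.
    (If the minimal window exceeds *max_window*, no window of at most
    *max_window* residues can hold k duplets.)
    """
    seq = record.residues
    region = minimal_duplet_window(seq, k, seq_id=record.id, scheme=scheme, pka=pka)
    if region is None or region.length_aa > max_window:
        return None
    window = seq[region.start : region.end]
    if charged_fraction(window, CRITERION_CHARGED) < min_charged_frac:
        return None
    return ProteinScreenRecord(
        seq_id=record.id,
        motif=region,
        full_length_aa=len(seq),
        full_pI=isoelectric_point(seq, pka),
        full_mol_percent_charged=100.0
        * charged_fraction(seq, scheme.extended_charged),
    )
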