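"""Residue charge classification, net charge and isoelectric point.

Two notions of "charged" coexist in this kind of screening and both are
kept explicit here:

* the **criterion set** {K, R, D, E} — the residues that can form a
  duplet and that feed the 20%/25% charged-fraction filters, and
* the **extended set** {R, K, E, D, B, H, Z} — histidine and the
  ambiguity codes Asx/Glx included — used for the reported
  "mol% charged" composition statistic.

Net charge is computed two ways.  The *counting rule* is simply
``#{K,R} − #{D,E}`` (termini and His excluded); it reproduces the
integer "net charge at pH 7" columns of published peptide tables.  The
*titration model* is a standard Henderson–Hasselbalch sum over the
N-terminus, C-terminus and the ionizable side chains D, E, C, Y, H, K,
R; the isoelectric point is the unique pH where that sum crosses zero.
pKa constants differ between programs, so pKa sets are named, swappable
objects; three published sets ship with the package.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from scipy.optimize import brentq

CRITERION_CHARGED = frozenset("KRDE")

_TITRATABLE = frozenset("DECYHKR")
_BASIC_SIDE = "KRH"
_ACIDIC_SIDE_FULL = "DECY"
_ACIDIC_SIDE_NO_CY = "DE"


@dataclass(frozen=True)
class ChargeScheme:
    """Which residues count as positive/negative, and the extended
    charged set used for mol% composition."""

    positive: frozenset = frozenset("KR")
    negative: frozenset = frozenset("DE")
    extended_charged: frozenset = frozenset("RKEDBHZ")

    def __post_init__(self) -> None:
        if self.positive & self.negative:
            raise ValueError("positive and negative residue sets overlap")
        if not (self.positive | self.negative) <= self.extended_charged:
            raise ValueError("extended_charged must contain positive and negative sets")


DEFAULT_SCHEME = ChargeScheme()


@dataclass(frozen=True)
class PKaSet:
    """A named set of pKa constants for the titratable groups.

    ``side_chain`` must cover D, E, C, Y, H, K and R; all values must
    lie strictly inside (0, 14).
    """

    name: str
    n_term: float
    c_term: float
    side_chain: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = _TITRATABLE - set(self.side_chain)
        if missing:
            raise ValueError(f"pKa set {self.name!r} missing side chains: {sorted(missing)}")
        values = [self.n_term, self.c_term, *self.side_chain.values()]
        if not all(0.0 < v < 14.0 for v in values):
            raise ValueError(f"pKa set {self.name!r}: all pKa values must be in (0, 14)")

    @classmethod
    def from_dict(cls, name: str, data: Mapping) -> "PKaSet":
        return cls(
            name=name,
            n_term=float(data["n_term"]),
            c_term=float(data["c_term"]),
            side_chain={k.upper(): float(v) for k, v in data["side_chain"].items()},
        )

    @classmethod
    def from_json(cls, path: str | Path, name: str | None = None) -> "PKaSet":
        """Load a set from a JSON file holding either one set
        (``{"n_term": ..., "c_term": ..., "side_chain": {...}}``) or a
        mapping of named sets, in which case *name* selects one."""
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if "n_term" in data:
            return cls.from_dict(name or Path(path).stem, data)
        if name is None:
            raise ValueError("file holds multiple pKa sets; a name is required")
        if name not in data:
            raise ValueError(f"no pKa set named {name!r} in {path}")
        return cls.from_dict(name, data[name])


def _bundled_sets() -> dict[str, PKaSet]:
    text = resources.files("dupletscan.data").joinpath("pka_sets.json").read_text()
    raw = json.loads(text)
    return {name: PKaSet.from_dict(name, spec) for name, spec in raw.items()}


_BUNDLED: dict[str, PKaSet] | None = None


def available_pka_sets() -> list[str]:
    global _BUNDLED
    if _BUNDLED is None:
        _BUNDLED = _bundled_sets()
    return sorted(_BUNDLED)


def get_pka_set(name: str) -> PKaSet:
    global _BUNDLED
    if _BUNDLED is None:
        _BUNDLED = _bundled_sets()
    try:
        return _BUNDLED[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown pKa set {name!r}; available: {', '.join(sorted(_BUNDLED))}"
        ) from None


def default_pka_set() -> PKaSet:
    return get_pka_set("emboss")


def count_charges(seq: str, scheme: ChargeScheme = DEFAULT_SCHEME) -> tuple[int, int]:
    """Return ``(n_negative, n_positive)`` residue counts under *scheme*.

    Under the default scheme His, Asx, Glx and the termini contribute
    nothing.
    """
    seq = seq.upper()
    n_neg = sum(1 for ch in seq if ch in scheme.negative)
    n_pos = sum(1 for ch in seq if ch in scheme.positive)
    return n_neg, n_pos


def charged_fraction(seq: str, residue_set: frozenset | set = CRITERION_CHARGED) -> float:
    """Fraction of residues belonging to *residue_set* (0..1)."""
    seq = seq.upper()
    if not seq:
        raise ValueError("charged_fraction of an empty sequence is undefined")
    return sum(1 for ch in seq if ch in residue_set) / len(seq)


def net_charge_counting(seq: str, scheme: ChargeScheme = DEFAULT_SCHEME) -> int:
    """Integer net charge by the counting rule: positives minus negatives."""
    n_neg, n_pos = count_charges(seq, scheme)
    return n_pos - n_neg


def net_charge_hh(
    seq: str,
    pH: float,
    pka: PKaSet | None = None,
    include_cys_tyr: bool = True,
) -> float:
    """Henderson–Hasselbalch net charge (elementary charges) at *pH*.

    Each basic group (N-terminus, K, R, H) contributes
    ``1 / (1 + 10**(pH − pKa))`` and each acidic group (C-terminus, D,
    E and — unless disabled — C, Y) contributes
    ``−1 / (1 + 10**(pKa − pH))``.  One N- and one C-terminal group per
    peptide; B, Z and X do not titrate.
    """
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH {pH} outside (0, 14)")
    seq = seq.upper()
    if not seq:
        raise ValueError("net_charge_hh of an empty sequence is undefined")
    if pka is None:
        pka = default_pka_set()

    def basic(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pk))

    def acidic(pk: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pk - pH))

    counts = Counter(seq)
    charge = basic(pka.n_term) + acidic(pka.c_term)
    for res in _BASIC_SIDE:
        if counts[res]:
            charge += counts[res] * basic(pka.side_chain[res])
    acid_res = _ACIDIC_SIDE_FULL if include_cys_tyr else _ACIDIC_SIDE_NO_CY
    for res in acid_res:
        if counts[res]:
            charge += counts[res] * acidic(pka.side_chain[res])
    return charge


def isoelectric_point(
    seq: str,
    pka: PKaSet | None = None,
    tol: float = 1e-4,
    include_cys_tyr: bool = True,
) -> float:
    """pH at which the titration net charge is zero, to within *tol*.

    The charge is strictly decreasing in pH and the free termini
    guarantee a sign change inside (0, 14), so the root is unique; it is
    bracketed and refined with Brent's method.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("isoelectric_point of an empty sequence is undefined")
    if pka is None:
        pka = default_pka_set()

    def f(pH: float) -> float:
        return net_charge_hh(seq, pH, pka, include_cys_tyr=include_cys_tyr)

    return float(brentq(f, 1e-3, 14.0 - 1e-3, xtol=tol))
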