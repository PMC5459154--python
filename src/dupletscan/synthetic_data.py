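"""Synthetic inputs with machine-readable ground truth.

Two generators emulate the statistical structure the screens assume:

* **Peptide libraries.**  Random 12-mers drawn per position from either
  a uniform 20-residue profile or the NNK 32-codon profile of a
  phage-display library (N = any base, K = G/T; 31 coding codons after
  the single amber stop, giving residue weights 3/31 for L, R, S, 2/31
  for A, G, P, T, V and 1/31 for the rest).  An optional amplification
  bias thins clones whose counting net charge reaches +2 or that carry
  two or more arginines — the charge conditions reported to impair
  phage propagation — keeping each such clone with a configurable
  Bernoulli retention probability.

* **Proteins with planted motifs.**  Background residues drawn from a
  configurable composition, with one region of known length carrying an
  exact number of non-overlapping duplets; spacer residues inside the
  region come from a charge-free alphabet so the planted duplet count
  is exact, and (for two or more duplets) the region starts and ends on
  a duplet so that on a charge-free background the minimal k-duplet
  window coincides with the planted window.

All randomness flows from a single integer seed per spec.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .duplet_motif import DupletHit, MotifRegion, build_region, find_duplets, _hit
from .physchem import DEFAULT_SCHEME, ChargeScheme, PKaSet, net_charge_counting
from .seqio import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: residues that can never form a duplet nor carry criterion charge
SPACER_ALPHABET = "AGSTNQPLVIFMWYHC"

NNK32 = "NNK32"
UNIFORM20 = "uniform20"


def nnk_codons() -> list[str]:
    """The 32 NNK codons (third base G or T)."""
    return [a + b + c for a in "ACGT" for b in "ACGT" for c in "GT"]


def nnk_amino_acid_frequencies() -> dict[str, float]:
    """Amino-acid frequencies of an NNK library, conditioned on coding.

    Enumerates the 32 NNK codons, translates them with the standard
    genetic code and drops the single stop (TAG); the 31 coding codons
    give weights 3/31 (L, R, S), 2/31 (A, G, P, T, V) and 1/31 for the
    remaining twelve residues.
    """
    counts: Counter[str] = Counter()
    for codon in nnk_codons():
        aa = str(Seq(codon).translate())
        if aa == "*":
            continue
        counts[aa] += 1
    total = sum(counts.values())
    return {aa: counts[aa] / total for aa in sorted(counts)}


def uniform_frequencies() -> dict[str, float]:
    """Uniform composition over the 20 standard residues."""
    return {aa: 1.0 / len(AA20) for aa in AA20}


def charge_free_composition() -> dict[str, float]:
    """Uniform composition over the 16 residues outside {K, R, D, E}."""
    residues = [aa for aa in AA20 if aa not in "KRDE"]
    return {aa: 1.0 / len(residues) for aa in residues}


@dataclass(frozen=True)
class AmplificationBias:
    """Bernoulli thinning of clones with amplification-impairing charge."""

    net_charge_threshold: int = 2
    arginine_threshold: int = 2
    penalty_factor: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.penalty_factor <= 1.0:
            raise ValueError("penalty_factor must be in [0, 1]")


@dataclass(frozen=True)
class LibrarySpec:
    """Parameters of one simulated peptide library."""

    n_clones: int
    peptide_length: int = 12
    codon_scheme: str = NNK32
    amplification_bias: AmplificationBias | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.peptide_length < 1:
            raise ValueError("peptide_length must be >= 1")
        if self.codon_scheme not in (NNK32, UNIFORM20):
            raise ValueError(f"unknown codon scheme {self.codon_scheme!r}")


def generate_library(spec: LibrarySpec) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Draw a peptide library and its per-clone ground truth.

    Returns the surviving clones as records plus a truth table covering
    every generated clone with columns ``clone_id, sequence, net_charge,
    n_arginine, n_duplets, biased, retained``.  With an amplification
    bias, flagged clones (counting net charge ≥ threshold OR arginine
    count ≥ threshold) survive only with probability ``penalty_factor``;
    without bias every clone is retained.  Fully reproducible from the
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = (
        nnk_amino_acid_frequencies()
        if spec.codon_scheme == NNK32
        else uniform_frequencies()
    )
    alphabet = np.array(list(freqs))
    probs = np.array([freqs[aa] for aa in alphabet])
    probs = probs / probs.sum()

    draws = rng.choice(len(alphabet), size=(spec.n_clones, spec.peptide_length), p=probs)
    seqs = ["".join(alphabet[row]) for row in draws]

    net = np.array([net_charge_counting(s) for s in seqs])
    n_arg = np.array([s.count("R") for s in seqs])
    n_dup = np.array([len(find_duplets(s)) for s in seqs])

    bias = spec.amplification_bias
    if bias is not None:
        flagged = (net >= bias.net_charge_threshold) | (n_arg >= bias.arginine_threshold)
        keep_draw = rng.random(spec.n_clones) < bias.penalty_factor
        retained = ~flagged | keep_draw
    else:
        flagged = np.zeros(spec.n_clones, dtype=bool)
        retained = np.ones(spec.n_clones, dtype=bool)

    truth = pd.DataFrame(
        {
            "clone_id": [f"clone_{i + 1:06d}" for i in range(spec.n_clones)],
            "sequence": seqs,
            "net_charge": net,
            "n_arginine": n_arg,
            "n_duplets": n_dup,
            "biased": flagged,
            "retained": retained,
        }
    )
    records = [
        SequenceRecord(id=cid, residues=s)
        for cid, s, keep in zip(truth.clone_id, seqs, retained)
        if keep
    ]
    return records, truth


@dataclass(frozen=True)
class PlantedMotifSpec:
    """Parameters of one background protein with a planted duplet region."""

    protein_length: int = 300
    region_length: int = 50
    n_duplets: int = 5
    orientation_mix: float = 0.5  # fraction of duplets planted acidic-first
    background_composition: Mapping[str, float] | None = None  # default uniform20
    region_position: int | None = None  # None = random placement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_duplets < 1:
            raise ValueError("n_duplets must be >= 1")
        if self.region_length < 2 * self.n_duplets:
            raise ValueError(
                f"region of {self.region_length} aa cannot hold "
                f"{self.n_duplets} non-overlapping duplets"
            )
        if self.region_length > self.protein_length:
            raise ValueError("region_length exceeds protein_length")
        if not 0.0 <= self.orientation_mix <= 1.0:
            raise ValueError("orientation_mix must be in [0, 1]")
        if self.background_composition is not None:
            total = sum(self.background_composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"background composition sums to {total}, not 1")


def _draw_background(
    rng: np.random.Generator, composition: Mapping[str, float], n: int
) -> str:
    alphabet = np.array(list(composition))
    probs = np.array([composition[aa] for aa in alphabet])
    probs = probs / probs.sum()
    return "".join(alphabet[rng.choice(len(alphabet), size=n, p=probs)])


def generate_protein_with_motif(
    spec: PlantedMotifSpec,
    scheme: ChargeScheme = DEFAULT_SCHEME,
    pka: PKaSet | None = None,
    seq_id: str = "synthetic_protein",
) -> tuple[SequenceRecord, MotifRegion]:
    """Generate one protein with a planted duplet-rich region.

    The returned truth is the planted window as a
    :class:`~dupletscan.duplet_motif.MotifRegion` with its composition
    statistics and the exact planted duplets.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_duplets

    duplet_tokens = []
    for _ in range(k):
        acidic = "DE"[rng.integers(2)]
        basic = "KR"[rng.integers(2)]
        acidic_first = rng.random() < spec.orientation_mix
        duplet_tokens.append(acidic + basic if acidic_first else basic + acidic)

    n_spacer = spec.region_length - 2 * k
    spacer_idx = rng.integers(0, len(SPACER_ALPHABET), size=n_spacer)
    spacers = [SPACER_ALPHABET[i] for i in spacer_idx]

    if k >= 2:
        middle = duplet_tokens[1:-1] + spacers
        order = rng.permutation(len(middle))
        tokens = [duplet_tokens[0]] + [middle[i] for i in order] + [duplet_tokens[-1]]
    else:
        tokens = duplet_tokens + spacers
    region_seq = "".join(tokens)

    if spec.region_position is None:
        pos = int(rng.integers(0, spec.protein_length - spec.region_length + 1))
    else:
        pos = spec.region_position
        if not 0 <= pos <= spec.protein_length - spec.region_length:
            raise ValueError(f"region_position {pos} out of range")

    composition = spec.background_composition or uniform_frequencies()
    background = _draw_background(
        rng, composition, spec.protein_length - spec.region_length
    )
    protein = background[:pos] + region_seq + background[pos:]

    hits: list[DupletHit] = []
    offset = pos
    for token in tokens:
        if len(token) == 2:
            hits.append(_hit(protein, offset))
        offset += len(token)

    record = SequenceRecord(id=seq_id, residues=protein)
    truth = build_region(
        protein, seq_id, pos, pos + spec.region_length, hits, scheme, pka
    )
    return record, truth
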