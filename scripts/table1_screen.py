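#!/usr/bin/env python
"""Screen a user-provided biomineralization-protein FASTA for duplet-rich
regions (optional helper; requires external data).

The published screen of this kind ran over the BioMine-DB
"biominproteins" file (biomine.net) and individual database accessions
such as tr|Q288C6 (Atrina rigida chitin synthase, E22 pI 9 domain),
CBK19535 (Haliotis laevigata perlucin) and sp|P35384 (Bos taurus
extracellular Ca-sensing receptor).  Those sequences are not bundled —
download them yourself and pass the FASTA here.  The script reports,
per passing protein, the minimal window holding five R/K-E/D duplets
with its length, K/R/D/E counts, pI and mol% charged, alongside the
full-sequence statistics — the usual column set for such tables.

Note: published region lengths for this kind of screen (e.g. 46 aa for
the chitin synthase domain, 42 aa for perlucin) may reflect manually
chosen rather than minimal windows; this script always reports the
minimal window, so lengths can come out shorter.

Usage:
    python scripts/table1_screen.py proteins.fasta out.tsv [--pka-set grimsley]
"""

from __future__ import annotations

import argparse

from dupletscan.cli import PROTEIN_SCHEMA
from dupletscan.duplet_motif import screen_protein
from dupletscan.physchem import get_pka_set
from dupletscan.seqio import read_fasta, write_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("fasta")
    parser.add_argument("out")
    parser.add_argument("--k", type=int, default=5)
    parser.add_argument("--max-window", type=int, default=50)
    parser.add_argument("--min-charged-frac", type=float, default=0.20)
    parser.add_argument("--pka-set", default="emboss")
    args = parser.parse_args()

    pka = get_pka_set(args.pka_set)
    rows = []
    for rec in read_fasta(args.fasta):
        hit = screen_protein(
            rec,
            k=args.k,
            max_window=args.max_window,
            min_charged_frac=args.min_charged_frac,
            pka=pka,
        )
        if hit is None:
            continue
        m = hit.motif
        rows.append(
            {
                "id": hit.seq_id,
                "motif_aa": m.length_aa,
                "motif_pI": m.pI_region,
                "K": m.counts["K"],
                "R": m.counts["R"],
                "D": m.counts["D"],
                "E": m.counts["E"],
                "motif_mol_percent_charged": m.mol_percent_charged,
                "full_aa": hit.full_length_aa,
                "full_pI": hit.full_pI,
                "full_mol_percent_charged": hit.full_mol_percent_charged,
                "motif_start": m.start + 1,
                "motif_end": m.end,
            }
        )
    write_table(rows, PROTEIN_SCHEMA, args.out)
    print(f"{len(rows)} proteins pass the {args.k}-duplet criterion")


if __name__ == "__main__":
    main()
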