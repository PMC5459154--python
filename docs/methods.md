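# Methods

## The duplet motif and its counting convention

A *duplet* is an adjacent pair of oppositely charged residues: one of the
basic residues {K, R} next to one of the acidic residues {D, E}, in either
order, giving eight admissible pairs (KD, DK, KE, EK, RD, DR, RE, ER).
Histidine is excluded from the duplet alphabet, as are the ambiguity codes
B (Asx), Z (Glx) and X: their charge identity at neutral pH is either weak
or unknown. This single either-order rule reproduces the published duplet
Yes/No flags of both bundled peptide tables exactly (e.g. `AIMGPRTVDRLP`
has a duplet through DR, while `YSLRADSRWMPS` — R and D separated by an A —
does not).

Duplets are counted under a **non-overlap rule**: residues are consumed by
at most one duplet. Counting uses a greedy left-to-right scan (when
positions i, i+1 form a duplet, emit it and jump to i+2, else advance by
one). For intervals of unit length two, greedy earliest-end selection is
provably maximal; the test suite verifies this against a dynamic-programming
maximum and exhaustive subset enumeration over reduced alphabets. The
convention matters: the heptamer `LGFREKE` counts two duplets (RE, KE)
under the non-overlap rule, whereas an overlap-allowing count would give
three (RE, EK, KE).

## Minimal windows and the protein screen

The protein screening criterion is: at least k = 5 duplets within a window
of at most 50 residues, the window itself at least 20% charged, where the
20% filter uses the criterion set {K, R, D, E} (the same residues that form
duplets; the peptide analogue "25% in a 12-mer" also counts only these
four). The reported mol% charged columns, by contrast, use the extended set
{R, K, E, D, B, H, Z} — histidine and the amide-ambiguous Asx/Glx included —
matching how composition statistics are conventionally tabulated for such
regions. Both definitions are explicit `ChargeScheme` fields.

`minimal_duplet_window` finds the exact shortest window containing k
non-overlapping duplets: anchor on each duplet start, greedily chain the
nearest non-overlapping successors, take the span from the anchor to the end
of the k-th chained duplet, and minimize over anchors (ties to the smallest
start, for determinism). Since every minimal window must begin and end on a
duplet, and greedy chaining minimizes the k-th end for a fixed start, the
scan is exact; an O(n²) all-substrings oracle confirms this on random
sequences in the tests. If the minimal window exceeds the 50-residue cap,
no admissible window exists and the protein fails the screen.

Published region lengths for screens of this kind may derive from manually
chosen rather than provably minimal windows; this package always reports
the minimal window and can therefore report shorter regions than a manual
analysis of the same protein. Internal coordinates are 0-based half-open;
emitted tables are 1-based inclusive; BED export is 0-based half-open.

## Net charge: counting rule vs. titration

Two net-charge models coexist deliberately:

* The **counting rule** `#{K,R} − #{D,E}` (termini and His excluded)
  reproduces the integer "net charge at pH 7" column of the published
  peptide tables for all 20 rows. Henderson–Hasselbalch at pH 7 yields
  non-integers and would not reproduce that column, so the printed values
  are evidently counts; the package treats the counting rule as the
  canonical pH-7 column and keeps the titration model separate.
* The **titration model** sums, over the N-terminus, C-terminus and the
  side chains D, E, C, Y, H, K, R:
  `Z(pH) = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic 1/(1+10^(pKa−pH))`.
  Cys and Tyr titrate as acidic groups by default (standard practice);
  `include_cys_tyr=False` disables them. B, Z and X never titrate.

`Z(pH)` is strictly decreasing and the free termini force a sign change in
(0, 14), so the isoelectric point is the unique root. It is bracketed on
(0.001, 13.999) and refined with Brent's method to `tol` (default 10⁻⁴ pH
units); a dense-grid oracle in the tests confirms agreement to 2·tol. Both
pI and titration charge depend only on composition, not residue order.

### pKa sets

pKa constants are program-specific, and the constants behind the published
peptide pI columns (commercial/legacy calculators) are unpublished. The
package therefore treats the pKa table as a named, swappable `PKaSet`;
three published sets are bundled:

| set | N-term | C-term | D | E | C | Y | H | K | R |
|---|---|---|---|---|---|---|---|---|---|
| `emboss` (default) | 8.6 | 3.6 | 3.9 | 4.1 | 8.5 | 10.1 | 6.5 | 10.8 | 12.5 |
| `lehninger` | 9.69 | 2.34 | 3.86 | 4.25 | 8.33 | 10.07 | 6.0 | 10.53 | 12.48 |
| `grimsley` | 7.7 | 3.3 | 3.5 | 4.2 | 6.8 | 10.3 | 6.6 | 10.5 | 12.04 |

Against the 20 published peptide pI values the maximal absolute deviations
are 0.95 (`emboss`), 1.36 (`lehninger`) and 0.50 (`grimsley`): the
`grimsley` set (protein-average constants with a low N-terminal pKa) is the
best stand-in for the reference software and keeps every row within the
±0.6 pH-unit band the package tests against. Published pI values can only
ever be matched to tolerance, not bit-exactly. Custom sets load from JSON.

## Peptide-set re-evaluation

`screen_peptides` collapses the input to its technical diversity (exact
string deduplication — distinct sequences, not clusters; two peptides
differing in one residue stay separate), applies the ≥ 25% charged-fraction
filter (i.e. ≥ 3 of {K,R,D,E} in a 12-mer; the comparison is `≥`, so a
peptide exactly at 3/12 passes), computes each row, and sorts by pI
ascending — the order such tables are published in — with sequence as a
deterministic tiebreak, so output is invariant to input shuffling. The
zirconia and zinc-oxide fixtures are treated as independent per-substrate
sets: the peptide `HYPTAKFHAERL` appears in both and is intentionally not
cross-deduplicated.

The pI histogram uses half-open bins with open outer ends; default edges
(7.0, 8.0, 8.5) are the decision thresholds usually quoted for such
distributions, and are configurable because published binnings are rarely
recoverable exactly. One published tally for this data ("six of nine duplet
peptides above pI 8.5") does not match any single-substrate denominator —
the zirconia table has seven duplet-flagged rows, of which four have
printed pI ≥ 8.5 — so the package reports only its own recomputed tallies.
Likewise, published percentage distributions over *all* selected peptides
(e.g. 14.3% with pI ≥ 8.0) imply the full ~91-sequence selection pool,
which is not printed anywhere; only the highly charged subsets ship, so
those percentages are out of reach by construction.

## Synthetic data

The generators produce inputs with the statistical structure the screens
assume — and ground truth to score against.

**NNK libraries.** Phage-display 12-mer libraries are encoded by NNK
codons (N = any base, K = G/T): 32 codons, one stop (TAG), hence 31 coding
codons with amino-acid multiplicities 3 (L, R, S), 2 (A, G, P, T, V) and 1
(the remaining twelve). Frequencies are derived by enumerating and
translating the 32 codons, conditioned on non-stop (amber suppression is
not modeled — the simplest defensible model of a displayed peptide).
Peptides are drawn i.i.d. per position; real libraries' clone-abundance
skew and sequencing error are *not* emulated, so passing tests validate
composition statistics, not selection dynamics. The optional
**amplification bias** models the reported propagation penalty for clones
with counting net charge ≥ +2 or ≥ 2 arginines as a single per-clone
Bernoulli retention probability (`penalty_factor`, default 0.1). The
penalty magnitude is a package choice: the effect is only described
qualitatively in the literature, so one documented knob covers it. With a
bias configured, the generator returns the surviving clones and a truth
table over *all* generated clones (`biased`, `retained` flags plus
per-clone net charge, arginine and duplet counts).

**Planted motifs.** A background protein (default 300 aa, drawn from a
uniform or user-supplied composition) receives one region of configurable
length (default 50) containing an exact number of non-overlapping duplets
(default 5). Spacer residues inside the region come from the 16-letter
charge-free alphabet (no K/R/D/E), so the planted duplet count is exact by
construction; for ≥ 2 duplets the region starts and ends on a duplet, so
on a charge-free background the minimal k-duplet window coincides with the
planted window exactly. On a uniform background, extra duplets can arise by
chance and the screen is scored by *overlap* with the truth instead. All
randomness flows from a single integer seed; identical spec + seed gives
byte-identical FASTA.

The recovery benchmark (500 planted proteins, charge-free background,
default screen parameters) and the composition benchmark (50,000 clones,
per-residue tolerance ±0.005, ~13 binomial standard errors) are sized to
run in seconds while leaving the Monte-Carlo error far below the asserted
tolerances.

## Degenerate inputs and numerical choices

* Empty sequences are rejected at `SequenceRecord` construction; the
  counting net charge of an empty string is defined as 0, but fractions,
  titration and pI require non-empty input.
* Lowercase input is uppercased silently (FASTA case carries no meaning
  here); X is accepted on input and ignored by every charge computation.
* TSV output prints pI to 2 decimals and percentages to 1 decimal with
  half-up rounding (so 4.365 → 4.37, not banker's 4.36).
* Window ties (equally short minimal windows) resolve to the leftmost;
  peptide-table ties in pI resolve alphabetically.

## Known limitations

* No post-translational modifications (notably no Ser-phosphate chemistry
  of silaffin-like peptides) and no electrostatics beyond per-residue
  titration.
* No alignment, homology or structure analysis: the screen is purely
  composition/adjacency-based, and duplet-rich windows in real proteins
  may be buried or split by structure.
* The database-scale protein screen is provided as a helper script
  (`scripts/table1_screen.py`) requiring externally downloaded sequences;
  it is plumbing, not covered by the test suite, and its minimal-window
  lengths may undercut manually curated region lengths.
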