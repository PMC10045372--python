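# Methods

This note documents the models, algorithms and numerical choices behind
`tecurate`, and what its synthetic benchmarks do and do not demonstrate.

## Coordinates and sequence handling

All coordinates are 0-based, half-open; 1-based inclusive numbers appear
only in human-readable reports.  FASTA input is uppercased on read (U→T in
nucleotide mode); lowercase soft-masking is preserved as a per-position
flag but ignored by every computation (repeat curation is itself the
masking step, so upstream masks carry no extra information here).  Only
the standard genetic code is used.  Runs of ≥10 N disqualify a TSD window;
shorter N stretches count as universal mismatches.

## Homology search

The search is a transparent seed-and-extend design so results are exactly
reproducible from the recorded `SearchConfig`:

- **Protein seeds** against the six-frame translation of each contig:
  exact 4-mer seeding, ungapped X-drop extension (BLOSUM62, X-drop 20),
  hits kept at score ≥ 50 and mapped back to forward-strand nucleotide
  coordinates through the codon map of their frame.
- **Nucleotide queries** on both strands: exact 11-mer seeding, ungapped
  X-drop extension (+1/−1, X-drop 16), then gapped refinement: the full
  query is aligned into a bounded window around the ungapped core with
  edlib (infix mode), and the alignment is reduced to its
  maximum-scoring contiguous segment (Kadane's algorithm over cigar runs,
  match +1, mismatch −1, gap open 5, extend 1).  The local reduction is
  what makes truncated element copies visible: forcing the whole query to
  align would push a half-length copy below the score threshold by
  charging the missing half as one huge gap.
- Hits below 90 bp or score 30 (nucleotide) are dropped; same-strand hits
  overlapping ≥ 50% of the shorter are merged best-score-wins, ties to the
  smaller start.  Identity is measured over aligned columns, gaps
  excluded.  Seed positions inside an already-explored diagonal span are
  skipped, which keeps the scan linear in practice.

## Family building

Copies are clustered by **single linkage**: two sequences link when an
end-gap-free global alignment (match +1, mismatch −1, gap open −4, extend
−1) reaches 75% identity over aligned columns *and* spans 75% of the
shorter sequence — the classic BLASTCLUST-style criterion with coverage on
the shorter member.  The representative is the longest member.

The **consensus** is built on a center-star alignment onto the
representative ("once a gap, always a gap" when merging pairwise
alignments).  The 50%-majority rule is applied per column over the rows
covering it (leading/trailing overhang excluded): a character reaching half
the covering rows is emitted, a winning gap deletes the column, and a
column without a majority becomes N; exact ties are broken by the fixed
order `-` > A > C > G > T.

**Elongation** alternates re-searching the genome with the current
consensus, extracting up to 10 top-scoring copies with 5000 bp flanks,
regenerating the consensus body per-position from the copy pileup, and
extending both ends column by column through the stacked flanks.  An
extension column requires at least 2 covering copies and a **two-thirds
supermajority** on one base.  The supermajority (rather than a simple
plurality) is deliberate: at the default AT-rich composition (GC = 0.33)
the most common base among ~10 unrelated flank columns reaches 50% by
chance in roughly a quarter of columns, which would creep the consensus
past the true terminus round after round; at 2/3 the chance rate is ~2%
per column and extension halts within a column or two of the boundary,
while genuinely shared sequence (≥95% column agreement at the 5%
substitution rate studied) passes almost always.  "Almost" matters: with
10 copies at 5% substitutions, roughly one element column in a thousand
has four simultaneous mutations and fails the supermajority, which would
stall the walk mid-element.  A failing column is therefore skipped (its
plurality base emitted) when at least 5 of the next 6 columns pass;
unrelated flanks pass a column at only ~2%, so a true boundary still
halts immediately.  Rounds stop at convergence or after 10 rounds.  A consensus that no longer finds hits raises "family
lost"; a single-copy family simply refuses to extend (no 2-copy support)
and keeps unresolved termini.

Insertions private to single copies are not given consensus columns
during elongation-time regeneration (the initial center-star consensus
does represent shared insertions); with the per-copy indel rates studied
(≤0.2%) this loses nothing, and a systematically shared insertion is
recovered on the next search round.

**Autonomy**: a family is autonomous iff its longest ATG-initiated
stop-free ORF reaches 300 codons (configurable; an intact DDD/E
transposase is far above, a disrupted one far below this bound).

## Termini, TIRs, TSDs

**TSD calling.** Flanks are taken in element orientation, the left flank
ending immediately 5' of the element.  For L from 35 down to 1 the
length-L suffix of the left flank is compared with the length-L prefix of
the right flank (Hamming distance; N is always a mismatch).  The call is
the largest L within the mismatch budget: 0 mismatches below 10 bp,
⌊L/8⌋ at or above — so degenerate 24/25 bp duplications with up to 3
mismatches remain callable while short spurious matches stay excluded.
The false-positive rate for calls ≥ 10 bp on unrelated flanks is ~10⁻⁴
(measured on 10,000 random pairs).

**Length classes.** Calls are binned per copy: ~4 (2–6 bp), ~15
(14–17 bp), ~25 (24–29 bp); other lengths report "other", absent
duplications "none".  Bins are configurable; a 2–3 bp call is treated as
class ~4 by default but is statistically indistinguishable from noise,
which is why terminus *support* (below) requires ≥ 3 bp.

**Terminus determination.** Candidate 5'/3' positions are signature-motif
matches (degenerate TNT / AYA) within ±30 bp of anchor points taken from
the outer quartiles of the copies' aligned spans — quartiles, not medians,
so a family in which most copies are truncated cannot drag the anchor into
the element interior.  Each candidate pair is scored as the number of
copies whose implied flanks yield a TSD of ≥ 3 bp, plus 1 if the strict
TGT..ACA motif matches, plus 0.5 if a TIR is detectable between the
candidates.  Ties fall to the larger summed *mismatch-penalized* TSD
length Σ max(0, L − 2·mismatches), then the smaller 5' position.  The
penalty matters: shifting a terminus k bases into the element lengthens
every copy's apparent duplication by k at the cost of k budget mismatches,
so raw summed length would systematically prefer shifted boundaries.
When no candidate matches the motif, the raw anchor points are reported
with `signature_matched=False`.

After the termini are fixed, every copy is **re-aligned to the trimmed
consensus** and TSDs are called at its exact ends.  This re-anchoring
removes the end-placement ambiguity that elongation overshoot bases
introduce into the copy alignments (an unmatched consensus base can be
absorbed as either a terminal mismatch or an indel at identical edit
cost, shifting the apparent junction by a base or two).  A copy "retains
both termini" when its maximum-scoring alignment segment reaches within
5 bp of both consensus ends; only such copies enter the census.

**TIR detection** aligns the first 100 bases against the reverse
complement of the last 100 with an affine-gap DP anchored at position 0 of
both (match +1, mismatch −2, gap open 4, extend 1); the TIR length is the
5'-side span of the maximum-scoring prefix pair and identity is measured
over its aligned columns.  A TIR is reported present at length ≥ 8 and
identity ≥ 0.8.  The −2 mismatch penalty keeps a repeat at the 0.8
identity floor scoring positive while making chance extension past the
true repeat end (one match per four random columns) unprofitable.  This
DP is hand-rolled because the anchored-local shape cannot be expressed
with the installed pairwise aligners (free-end global alignment cannot
emulate it: adjacent insertion/deletion columns are disallowed).

## Synthetic genomes

The simulator generates the statistical structure the analysis assumes,
with defaults chosen as the study conditions:

| parameter | default | meaning |
|---|---|---|
| `gc_fraction` | 0.33 | AT-rich, protist-like background |
| `element_length` | 1000–1500 bp | template length (drawn per family) |
| `tir_length` | 25 bp | perfect TIR engineered into the template |
| `terminal_signature` | TGT..ACA | strict signature; alternatives configurable |
| `orf_codons` | 350 | embedded ATG-initiated stop-free ORF |
| `tsd_regime` | (4, 0.7, {4,5}), (15, 0.2, {14,15,16}), (25, 0.1, {24,25}) | discrete class, weight, length jitter |
| `sub_rate`, `indel_rate` | 0 | per-base per-copy noise (tests use up to 5% / 0.2%) |
| `tsd_degeneracy_rate` | 0 | per-base mutation of the right TSD copy |
| `truncation_prob` | 0 | per-copy 5'/3' truncation (10–90% removed) |

Copies are implanted at uniform sites with ≥150 bp separation from edges,
other insertions and previously placed families (no nesting), on a random
strand, duplicating the target site on both flanks.  Two details make the
ground truth exact rather than approximate.  First, a proposed junction is
**resampled until the implanted duplication is the maximal within-budget
duplication there** (checked by an independent brute-force scan):
otherwise chance host repeats adjacent to the site make "the" TSD length
ill-defined and no caller could be scored against it.  Second, when later
families are implanted, the coordinates of earlier truth records are
shifted through the insertion breakpoints, so every record stays exact in
the final genome.  Truncated copies keep their intended TSD length in the
truth table even though one flank is lost — the evaluator uses this to
measure the pipeline's correct refusal to call them.

The evaluator matches recovered families to templates by seed identity and
called copies to truth by ≥50% interval overlap, and reports signed
terminus offsets (template vs termini-trimmed consensus, via end-gap-free
alignment), consensus identity, exact and ±1 bp TSD accuracy, class-census
L1 distance, and both-termini counts against the untruncated truth.

**What the simulations do not emulate:** real repeat landscapes (nested or
fragmented insertions, satellite arrays, segmental duplications), genome
composition heterogeneity, assembly gaps and collapsed repeats, ancient
highly diverged copies, and families without a recognizable ORF seed.
Passing the benchmarks therefore demonstrates the correctness of the
algorithms under the stated generative model, not performance parity with
manual curation on real assemblies.

## Problem sizes of the standard benchmarks

Noise-free closure: 10 families × 10 copies in a ~250 kb background
(final genome ~380 kb).  Noise recovery: 10 families × 30 copies at 5%
substitutions, 5 seeded replicates.  Mixed-census family: 11 full-length
copies with a 4/5/15/24 bp TSD mixture plus 20 truncated copies.  These
sizes exercise every code path at desk scale; all statistics scale with
the per-copy and per-column error rates, not with genome size, so larger
genomes change runtimes rather than conclusions.

## Known limitations

- Families are seeded one per protein query; two seeds recovering the
  same genomic family are not deduplicated.
- Non-autonomous families are named as orphans (`IS481EU-N{j}`); pairing a
  deletion derivative with its autonomous partner family is not attempted.
- Elongation assumes flank columns stack without indels; an indel-rich
  flank halts extension early (conservatively) rather than realigning.
- Clustering is a single pass; families are not re-clustered after
  elongation.
- With more than ~75% of copies truncated at the same end, the terminus
  anchor quartile can leave the true boundary outside the candidate
  window.
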