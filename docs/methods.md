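# Methods

This note records the models implemented in `mitoarch`, the parameter
defaults and why they were chosen, the numerical conventions, and what
the synthetic-data generator does and does not emulate.

## Coordinate model

All interfaces use 1-based inclusive coordinates on the major strand,
the GenBank and feature-table convention. A feature on a circular
genome may wrap the origin (`end < start`), covering
`start..genome_length` then `1..end`; at most one revolution is
allowed. Any half-open representation used internally is invisible at
the API. The major strand is the strand carrying the majority of genes
(for the bundled earwig genome, the strand on which *trnM*, *nad2* and
*cox1* are read); position 1 is the first base of *trnM* there.

## Spacer and overlap accounting

The signed gap between consecutive features is
`start(downstream) − end(upstream) − 1` under circular arithmetic:
positive values are intergenic spacers, negative values overlaps, zero
means abutting genes. Two rules keep the inventory consistent with how
genome descriptions count non-coding DNA:

* repeat regions (a tandem repeat unit annotated inside a spacer) are
  excluded from the adjacency chain — the spacer that hosts them is one
  non-coding region, not two;
* the control region stays in the chain as a non-gene anchor, and gaps
  flanking it are excluded from the positive-spacer summary. Dropping
  it instead would re-surface the whole A+T-rich region as a spurious
  wrap-around "spacer" between its flanking genes.

On the bundled genome this yields 24 positive spacers totalling
3,783 bp. (The source description prints a total of 3,784 bp; the
brute-force sum over the table's own coordinates is 3,783, and the
computed value is reported.)

Validation is deliberately non-fatal: published tables contain errors
(the bundled one carries an anticodon coordinate inconsistent with its
tRNA's span), and a parser that dies on them is useless. Checks cover
anticodon position and sequence, start codons
(ATA/ATT/ATC/ATG/TTG/GTG), stops (TAA/TAG and the incomplete TA/T
completed by polyadenylation), and feature-length sanity; each produces
a finding with a severity, never an exception.

## Skew statistics

AT-skew = (A − T)/(A + T), GC-skew = (G − C)/(G + C), computed from
exact counts; `N` is excluded everywhere, lowercase accepted, zero
denominators give an explicit undefined value (never NaN). The
whole-genome value is measured on the major strand over all positions
(including repeat and control regions — the statistic describes the
strand, so no positions are exempted). PCG partitions are measured on
concatenated coding-strand (sense) sequences: a minor-strand gene
contributes its own reading, which is what makes "minor strand A- and
C-skewed" a statement about the genes rather than a mirror image of the
major strand. The sign-pattern classifier maps the two skew signs onto
the survey vocabulary (`A_and_C`, `T_and_G`, `T_and_C`, `A_and_G`, the
`*_gc_zero` degenerates, `undefined` when AT-skew is zero or
undefined). Printed values round half-away-from-zero to 3 decimals,
matching the usual printing convention; the rounding convention of the
original reports is not stated, so half-away-from-zero is assumed.

Codon-position composition concatenates in-frame codons of all PCGs on
the coding strand, anchored at the annotated start; a trailing
incomplete codon is excluded.

## Tandem repeat detection

A repeat run is `c ≥ 2` full copies of an ℓ-mer plus a partial copy of
the unit's beginning, span = c·ℓ + p. Detection is a self-alignment
period scan:

1. for each candidate period ℓ, mark positions where the sequence
   matches itself at lag ℓ;
2. trim the match profile to its high-density bursts by a
   max-scoring-subarray pass (matches +1, mismatches −m with
   `m = min(3, 0.8·t/(1−t))` for identity threshold t — harsh enough
   that background density (~0.25) drifts down and a mismatch cannot be
   repaid by two or three chance matches, gentle enough that runs at
   the threshold keep a positive drift);
3. anchor the phase at the burst start and chain copies by pairwise
   identity (`matches/ℓ ≥ min_identity` on ungapped columns), so a
   single noisy position at a boundary cannot shave off a whole copy;
4. build the consensus by column-wise majority (ties to the smaller
   base), drop boundary copies below the identity threshold, and
   measure the partial copy as the longest exact match against the
   consensus prefix (trailing) or suffix (leading), capped below one
   unit;
5. reduce to the primitive period: if the consensus matches itself at a
   divisor period at or above the identity threshold, the run is
   re-described at that smaller period. (One heavily mutated copy can
   break the chain at the true period yet survive at a multiple, where
   its mismatches are diluted across a longer unit.)

Overlapping candidates are resolved deterministically: longest span,
then smallest unit, then leftmost start. Defaults
(`min_unit=10, max_unit=600, min_copies=2, min_identity=0.85`) span the
unit lengths reported for insect control regions and large spacers
(135, 189, 202, 297, 554 bp) while suppressing homopolymer noise.
Identity is counted on ungapped columns only — indel-containing repeats
are out of scope, as are alignment-score significance models.

A brute-force enumeration of all maximal (start, ℓ, copies) runs is
shipped alongside (`brute_force_runs`) and the scan is tested equal to
it on exhaustive small binary instances and sampled longer ones. An
exhaustive sweep over *all* sequences up to length 60 is not
computable (2^60 instances); the tests sweep all short instances
exhaustively and sample the rest with fixed seeds.

## Motif scanning

**Cloverleaves.** The tRNA model is purely structural: acceptor stem
7 bp; DHU stem 3–4 bp with a 4–12-nt loop, or — when `dhu_optional` —
no stem and a 7–14-nt loop (the trnS(AGN) configuration); anticodon
stem 5 bp with a loop of exactly 7 nt, the anticodon read at loop
positions 3–5 on the coding strand; variable loop 3–21 nt (the upper
default accommodates the unusually long 20/19-nt loops seen in some
earwig tRNAs); TψC stem 3–5 bp with a 4–9-nt loop. Pairing is
Watson–Crick plus G-U wobble, at most one mismatch per stem by default
(published secondary structures show imperfect acceptor stems). Arms
are contiguous — no inter-arm linkers — which makes the grammar a
well-defined combinatorial object: the synthetic generator builds
motifs from exactly this grammar, guaranteeing detectability, and the
scanner enumerates exactly its foldings on both strands. The grammar is
ambiguous (one span can fold several ways), so candidates are
deduplicated per (start, end, strand) and ranked by total mismatches,
then paired bases; a greedy non-overlap pass (`select_nonoverlapping`)
reduces the list to one candidate per locus, which is how a repeat
region with one planted motif per copy yields one hit per copy.
Isotypes come from the invertebrate mitochondrial genetic code.
Thermodynamic folding is deliberately replaced by these combinatorial
constraints; no free energies are computed, and covariance-model tRNA
scoring is out of scope.

**Stem-loops.** Exhaustive inverted-repeat enumeration (every
qualifying (start, stem, loop) triple is reported, so the output equals
the brute-force definition by construction), with the conserved
control-region flanks annotated: `TATA` within 10 nt upstream, `G(A)nT`
(n ≥ 2) starting within 10 nt downstream. Note that G-U wobble is
strand-asymmetric (G·U pairs, C·A does not), so the strand-mirror
property holds exactly only under pure Watson–Crick pairing
(`allow_gu=False`).

**Poly-T runs.** Maximal runs beginning and ending with T containing at
most `max_interruptions` other bases, length counted inclusive of
interruptions (a 10-bp stretch with one A insertion is length 10).

**ORFs.** Per frame and strand, from the first start codon after the
previous stop to the next stop; starts default to the mitochondrial
initiation set, stops are TAA/TAG only (TGA codes tryptophan in the
invertebrate code). The start codon counts as residue 1. A frame
ending at the sequence boundary on a trailing T or TA qualifies as an
incomplete stop when allowed — so a 131-nt spacer of TTG + 42 codons
+ TA encodes 43 residues.

**Similarity.** `percent_identity` is global alignment identity
(match +1, mismatch 0, linear gap −1; matches / alignment columns) via
Biopython's PairwiseAligner, first optimal alignment (deterministic).
The parameters are fixed for determinism; published homology
percentages for tRNA-like sequences were produced by an unspecified
method, so they are treated as reference points, not exact targets.

## Gene-order rearrangement

A gene order is a circular sequence of signed elements; equality and
all comparisons are rotation-invariant, and no canonical origin is
assumed — "position" always means adjacency context. The ancestral
insect arrangement (identical to *Drosophila*) is built in.

Classification against the ancestral order proceeds in three steps:

1. **Forced flags.** Genes whose orientation differs must have moved.
2. **Exact minimum-backbone search.** The observed circle is cut at
   every adjacency absent from the ancestral adjacency set, yielding
   conserved segments; any rearrangement moves whole segments, so the
   candidate flag sets are unions of segments. All subsets are scored
   and every minimum-cardinality gene set whose removal makes the two
   circular signed orders identical is retained. A gene is classified
   as rearranged when it appears in **any** minimum set (the union
   rule). For a two-gene block swap either member's removal alone
   reconciles the orders — the minimum is not unique precisely because
   both genes moved relative to each other — so the union rule flags
   both, while event grouping (below) still reports one event. This
   also reproduces the full published inventory for the bundled genome
   (three translocated tRNAs from two duplication/random-loss events,
   not two), which a single arbitrarily-chosen minimum set would not.
   A tie-break that *chooses* among minimum sets is therefore
   unnecessary and not implemented.
3. **Per-gene classes.** Flagged genes with unchanged orientation are
   `translocated`; flipped genes whose inter-backbone interval (the
   pair of nearest backbone genes on either side) is unchanged are
   `local_inversion`, otherwise `shuffle_with_remote_inversion`.

Flagged genes contiguous in the observed order with equal class are
grouped into one event, with ancestral and observed neighbor context
attached. The control region participates as an order element but is
never flagged. Because independent events cannot be ordered in time
from a single genome, the report contains event classes, not an event
sequence. The breakpoint count — signed circular adjacencies of one
order absent from the other — is provided as a supporting statistic.
General rearrangement-distance algorithms (DCJ, sorting by reversals)
are out of scope.

The scripted operators (`apply_inversion`, `apply_translocation`,
`apply_dup_loss`) implement the standard mechanisms; dup-loss
tandem-duplicates a block and deletes copies such that each gene
survives exactly once.

## Synthetic data

`generate_genome` emulates the architecture of a large earwig-like
mitogenome: 37 genes with the published lengths and codon/anticodon
metadata, laid out along a configurable gene order (ancestral by
default) with short spacers; background sequence sampled i.i.d. from
per-strand base probabilities (default mirrors the earwig major-strand
composition A/C/G/T = 0.282/0.139/0.176/0.403, so the planted skew
class is T- and G-skewed); a tandem repeat (default 21 × 135 bp +
21 bp partial, matching the annotated giant repeat) planted into the
spacer downstream of a host gene; optional cloverleaf motifs embedded
per repeat copy; an AT-rich control region (default 1,816 bp at 90%
A+T). All randomness flows from one seeded generator, so outputs are
byte-reproducible. Background for every gene is drawn on the major
strand — the planted bias is a property of the strand, not of reading
direction — and only planted codons/anticodons are written through the
sense strand.

Planted repeat boundaries are guarded: the flanking base adjacent to
the run is resampled whenever it would continue the repeat pattern, so
the planted (ℓ, c, p) is the unambiguous ground truth rather than a
quantity blurred by chance flank matches.

`generate_order` applies an event script to the ancestral order and
emits per-gene ground-truth classes. Scripts must be non-interacting
(disjoint touched-gene neighborhoods), and translocations must jump
over more genes than they move — otherwise the minimal explanation is
not unique (moving block B over gap D is indistinguishable from moving
D over B) and the generator refuses with "ambiguous ground truth"
rather than emitting a truth the classifier could legitimately disagree
with. Dup-loss ground truth is derived by an independent local
enumeration over the block.

What the generator does **not** emulate: substitution processes over
trees (no phylogenetic signal), indels, heteroplasmy, realistic codon
usage or amino-acid content, thermodynamically stable tRNA structures
(only the combinatorial grammar), or sequencing artifacts. Passing
tests on synthetic genomes therefore demonstrate correctness of the
algorithms under the structural model, not performance on raw reads or
on annotation transferred across distant taxa.

## Problem sizes used in the test battery

The shipped suites verify: exact recovery of the full published
architecture and rearrangement inventory from the bundled table
(deterministic); repeat-detector equivalence with brute force on all
binary sequences up to length 10–12 and sampled longer ones; planted
repeat-unit recovery in ≥ 95/100 random constructions (ℓ ∈ [20, 300],
c ∈ [3, 25], 0–5% per-copy divergence); skew recovery within 3
binomial standard errors on 100-kb i.i.d. sequence and on a ≥ 50-kb
uniform-background synthetic genome; and exact per-gene class recovery
for 200 random 1–3-event scripts. All seeds are fixed.

## Known limitations

* The feature-table parser targets the two dialects described above; it
  is not a general GFF/feature-table reader.
* Repeat detection assumes length-pure (indel-free) repeats; partial
  copies are measured by exact consensus match, so a mutation inside a
  partial copy truncates its measured length.
* The cloverleaf grammar has no inter-arm linkers; real tRNAs with
  spacer nucleotides between arms may be missed or detected with
  slightly shifted boundaries.
* The backbone search is exact but exponential in the number of
  conserved segments; it is intended for single-genome comparisons
  (≤ ~16 broken segments), not for deeply scrambled genomes.
* Sequence-level published values (whole-genome skews, codon-position
  A+T) require the GenBank record, which is not bundled; the package
  computes them when given the sequence.
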