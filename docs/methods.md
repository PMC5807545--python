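# Methods

`mitochar` packages, as tested library operations, the computations used to
characterize an annotated vertebrate mitochondrial genome and compare it
against a panel of relatives: gene-map accounting, composition and skew
statistics, codon usage, repeat and palindrome scanning, tRNA stem pair
typing, a counting-based dN/dS estimator, and supermatrix preparation.  This
note records the models and conventions behind each stage, the defaults and
why, what the synthetic generators do and do not emulate, and the known
limitations.

## Coordinates and gene-map accounting

All coordinates are 1-based inclusive (the GenBank convention).  Features
spanning the circular origin are rejected at load: published mammalian
mitogenome annotations are conventionally rotated to start at *trnF*, so
such features do not arise in practice, and excluding them keeps the
accounting identity below exact.

For consecutive features in start order, the signed intergenic count is
`start(downstream) − end(upstream) − 1`: positive = spacer, negative =
overlap, zero = abutting.  On a circular genome one closure record runs from
the last feature's end through the origin.  A feature nested wholly inside
its predecessor is excluded from the adjacency chain and reported separately
(none occur in the bundled annotation).  With no nested features,

    Σ feature lengths − total overlap + total spacer + closure gap = genome length

holds exactly; it is property-tested on 200 randomized synthetic genomes.

Per-class genome coverage is reported two ways: the plain sum of feature
lengths over the genome length (the convention in comparative mitogenomics
tables, where overlapping bases count once per feature) and a
union-of-intervals version.  Published per-class coverage percentages are
not always reconstructible from the same paper's own coordinate table; this
package reports what the coordinates imply and nothing else.

Ties for "longest overlap/spacer" break toward the lowest start coordinate.
Gene-order comparison is a rotation-invariant match on circular (name,
strand) token lists, with breakpoints counted as adjacencies of one genome
absent from the other; no rearrangement distance beyond breakpoints is
attempted.  Duplicate-gene identity is a Needleman–Wunsch global alignment
(match 1, mismatch −1, gap −2) reported as informational only, since
identity percentages are alignment-parameter dependent.

## Composition and skews

AT-skew = (A − T)/(A + T); GC-skew = (G − C)/(G + C).  The (G − C) form is
the standard strand-asymmetry statistic and is the only convention
consistent with published skew values recomputed from their own base
percentages (asserted in the test suite from printed values: T 29.8 / C
26.2 / A 31.4 / G 12.6 gives +0.026 and −0.351).  Zero-denominator skews
return 0 with a flag rather than NaN so reports stay finite.  N bases count
toward length but never toward a denominator.

Multi-feature regions are concatenated on their coding strand (L-strand
features reverse-complemented) before summarizing; whole-genome statistics
are computed on the deposited H strand.  Skew antisymmetry under reverse
complement is property-tested.

## Codon statistics

The vertebrate mitochondrial genetic code is used throughout (AGA/AGG
stops, ATA = Met, TGA = Trp).  For codon-level statistics the trailing stop
— complete, or a 1–2 nt T/TA overhang completed by polyadenylation — is
trimmed; boundary reports retain it.  RSCU for codon *c* in a family of
size *k* is `count(c) · k / Σ family counts`, so every observed family has
mean RSCU exactly 1 (asserted).  Amino-acid frequencies are over sense
codons.  Start codons matching AT* are classed canonical (ATN); stops are
TAN-complete (TAA/TAG), the mitochondria-specific AGA/AGG, or incomplete.

## Repeat and palindrome scanning

Tandem repeats: a shift-match scan (position *i* matches at period *p* when
`s[i] == s[i+p]`); a maximal run of *L* matches spans *L + p* bases, i.e.
*(L+p)/p* copies.  Defaults — period 10–200, ≥ 2 copies, ≤ 20% mismatches —
are set to the regime of control-region repeat units reported for
artiodactyl mitogenomes (tens of bp, two or a few copies).  The mismatch
tolerance is a greedy run-merging heuristic; recall is exact (and tested)
for mismatch-free arrays, which is what the generator plants.  Arrays
re-detected at a multiple of their true period are suppressed.

Palindromes follow EMBOSS semantics: inverted repeats (arms reverse
complements around an optional loop of ≤ `max_loop` unpaired bases; default
loop 0) and literal mirror repeats.  Hits are center-maximal; the scanner is
verified against an exhaustive O(n²) oracle on random sequences.  Mirror
mode exists because some published "palindromic" motifs are not
reverse-complement palindromes: the conserved 11-mer CTTCTCCCGCC, for
example, equals neither its reverse nor its reverse complement, so this
package treats it as a conserved motif (`count_motif`) and deliberately does
not force a palindrome classification.

Motif occurrence counting is shift-by-one (overlapping occurrences counted)
with an optional Hamming mismatch budget.

## tRNA stem pair typing

Ab initio folding is out of scope; structures arrive as dot-bracket strings
from standard annotators.  The four helices of a cloverleaf are labelled
AA (acceptor), D, AC (anticodon), TPC in 5′→3′ order of their opening
strands.  Pairs are canonical (A-U/U-A, G-C/C-G), wobble (G-U/U-G — its own
class, never a mismatch, since wobble pairing is conventional), or mismatch
reported as the ordered 5′base-3′base.  T and U are interchangeable on
input.  A published mismatch profile ships as a table; synthetic cloverleafs
embedding it make the whole reporting path testable offline.  A stated
frequency of 2 for one pair type is interpreted as two distinct positions.

## Counting dN/dS (SLAC-style)

Sites: each sense codon's positions contribute one site each, split by the
fraction of non-stop single-base changes preserving the amino acid, so
n + s = 3 exactly per codon.  The split can be transition/transversion
weighted (weight κ on transitions — modified Nei–Gojobori counting); by
default κ is estimated from pairwise differences at fourfold-degenerate
third positions (doubled to correct for the 1:2 transition:transversion
opportunity).  Unweighted counting under realistic transition bias is known
to misallocate sites and biases ω upward by ~10%.

Substitutions between observed codons are averaged over all minimal
mutational pathways, discarding pathways through stop codons when a
stop-free pathway exists (steps into a stop count as nonsynonymous in the
rare all-stop fallback).  The full 60×60 table is verified against an
exhaustive path-enumeration oracle.

`slac_gene` maps substitutions onto a tree: ancestral codons by Fitch
parsimony (deterministic tie-break toward the lowest codon index — an
intentional simplification of likelihood-based ancestral reconstruction
that preserves the counting character of the method), counted per branch.
A mean pairwise Nei–Gojobori estimator is the cross-check.  Multiple-hit
correction is Jukes–Cantor, `d = −3/4 ln(1 − 4p/3)`, applied **per counting
unit** (per branch, or per pair) while proportions are small, then summed
over branches or averaged over pairs.  Applying the correction to tree-total
proportions instead would saturate (summed p ≥ 3/4) on any multi-taxon tree
at realistic divergence; the per-unit form is the numerically usable
reading.  dS = 0 yields an undefined-flagged ratio, never an infinity.
Gapped/ambiguous codons are excluded per unit, not listwise.

The 95% CI is a seeded nonparametric bootstrap over codon columns (default
1000 replicates), percentile method, with ancestral assignments held fixed
across replicates.

Validation: on alignments simulated under κ = 2 with 9 taxa and 500 codons
(see below), the true ω ∈ {0.1, 0.5, 1.0} falls inside the 95% CI in ≥ 90%
of 50 seeded replicates per ω and the median estimate is within 15% of
truth; the median is strictly monotone in the generating ω.  Counting
estimators degrade at high divergence — parsimony undercounts synonymous
multiple hits once branches exceed roughly 0.15 substitutions/codon — so
results on deeply diverged taxa should be treated as conservative bounds,
not point estimates.

Site statistics on nucleotide alignments: a column is variable with ≥ 2
distinct unambiguous bases, parsimony-informative with ≥ 2 bases each in
≥ 2 sequences; gaps/ambiguity ignored.

## Supermatrix and trees

Per-gene alignment is delegated (pre-aligned FASTA in, canonical PCG order
by default); taxa missing a gene are gap-filled with a warning.  Partitions
are 1-based inclusive and tile the matrix exactly; exports are relaxed
PHYLIP and RAxML-style partition files, with a verified round-trip.
Distances are Jukes–Cantor-corrected p-distances (gap/ambiguity sites
excluded pairwise, saturated pairs capped at 5.0 with a warning) fed to
neighbor joining — a sanity tree, deterministic for a fixed input order,
not a substitute for model-based inference.  NJ consistency on additive
matrices is property-tested.  Clade questions are bipartition queries on
the sheared tree, so no rooting convention is imposed.

## Synthetic data

The genome generator writes a circular genome from an explicit blueprint:
gene order/lengths, planted overlaps and spacers (all other adjacencies
abut), a closure gap, composition targets, and optional planted structures.
Defaults emulate a tragulid-like genome: ~16.4 kb, the vertebrate 37-gene
order with typical lengths, A+T 0.614, AT-skew +0.05, GC-skew −0.30, a
*trnF* duplication immediately after the control region, and a 26 bp motif
planted twice in tandem mid-CR.  PCGs get an ATG start, TAA stop and a
stop-free random-codon body on their coding strand; overlapping features
overwrite shared bases (as real overlapping genes do), and the ledger
records boundary codons as actually present.  The A+T target (±0.01) is met
by resampling free non-coding positions only, so planted motifs are never
corrupted.  Everything planted is recorded in a ledger and recovered
exactly by the corresponding analysis — the core end-to-end test.

The generator does **not** emulate: biological codon usage or amino-acid
composition (PCG bodies are near-uniform over sense codons), realistic
rRNA/tRNA sequence structure, heteroplasmy, or sequencing error.  Passing
tests therefore demonstrate the correctness of the accounting and scanning
logic, not robustness to annotation error in real records.

The codon simulator is event-based (exact stochastic simulation along each
branch) rather than matrix-exponential: single-nucleotide moves at rate κ
for transitions and 1 for transversions, multiplied by ω when the amino
acid changes, stop codons forbidden; root codons uniform over sense codons.
Rates are normalized so the mean total leaving-rate over sense codons is 1,
making branch lengths ≈ expected substitutions per codon site.  No indels
and no among-site rate variation are simulated.

Study conditions for the ω-recovery experiment: a 9-taxon caterpillar tree
with 0.05 expected substitutions per codon per branch (total tree length
0.8/codon ≈ 0.27/nt — comparable to within-family mitogenome divergence)
and 500 codons, chosen as the regime where counting estimators are valid;
the known high-divergence degradation above is documented rather than
designed around.

## Determinism

Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); simulations use integer RNG streams with no
float-order dependence in event selection.  Report writers render floats at
fixed precision (3 decimals for skews, 4 for dN/dS) in fixed column order,
and the `characterize` bundle writes a manifest of SHA-256 content hashes;
re-running with the same inputs and seed is byte-identical (tested).
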