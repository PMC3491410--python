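# Methods

## Model and assumptions

Bisulfite sequencing converts unmethylated cytosines to thymines (via
uracil and PCR).  The mapper's objective is to place each read at the
genomic location minimizing its count of **non-bisulfite** mismatches:
read T over reference C (plus strand) or read A over reference G (minus
strand, after plus-coordinate normalization) is biological signal and
costs nothing; every other mismatch is a SNP or sequencing error and is
minimized.  A hit is *unique* when it is the only location achieving the
strictly lowest non-bisulfite mismatch count.

The mismatch model is Hamming-only (no indels), matching the alignment
model of the mapping strategy this package implements; reads with indels
relative to the reference will not be recovered.

### Converted references

Because the two strands are not complementary after C→T conversion, every
conversion is built per strand: reverse-complement first, then conversion,
then (color space) di-base encoding.  Base space uses the two *fully
converted* references (no C remains).  Color space additionally uses two
*non-CpG converted* references in which C is retained exactly when
followed by G — a model of CpG-methylated DNA that keeps methylated CpG
sites alignable.  The non-CpG rule is applied to the strand being
converted (symmetric rule); a trailing C with no following base is
converted.  Non-A/C/G/T symbols are replaced by A in references and base
reads, and by color 0 in color reads, before any processing; originally
ambiguous reference positions are excluded from methylation calling.

### Search engine

Hit counting needs *all* occurrences of a query within Hamming distance k,
grouped by mismatch count.  This is implemented as pigeonhole
seed-and-extend: the query is split into k+1 parts, so any hit with ≤ k
mismatches contains at least one exact part; a sorted q-gram index (q = 12
for base space, 8 for color space) yields candidate positions from each
part's leading q-gram, and a vectorized Hamming comparison verifies them.
Queries too short to seed (part length < q) fall back to a full scan.  The
contract — the exact hit set — is checked against a definitionally correct
pure-Python sliding-window oracle on randomized instances.  Hits are
reported sorted by (chromosome, position); hits never span chromosomes.

### Base-space pipeline

1. **Entropy filter.**  Read complexity is the Shannon entropy of the
   A/C/G/T histogram (ambiguity codes excluded), normalized by log2(4) to
   [0, 1]; reads with H < 0.25 are discarded.  The normalization makes the
   0.25 cutoff scale-meaningful: unnormalized log2 entropy would discard
   almost nothing at that threshold.
2. **Counting.**  The C→T-converted read and the C→T-converted reverse
   complement (reverse complement taken on the raw read first) are each
   counted on both converted references: four orientation lists.
3. **List filtering.**  A list is discarded when any of its mismatch-level
   groups holds ≥ 40 hits (color space: strictly more than 10); the
   surviving candidates are the union of retained lists.
4. **Verification and resolution.**  Candidates are mapped back to
   plus-strand coordinates (RC-reference position p ↦ L − p − m) and
   recounted against the original genome with the bisulfite rule above.
   Uniqueness is evaluated jointly across orientations over genomic
   *locations*: an unconverted (fully methylated) read matches the same
   locus under both strand interpretations — Count 1 + Count 4, or
   Count 2 + Count 3 — because without bisulfite asymmetry the duplex is
   readable both ways; that is one unique location, and the tie resolves
   to the earlier table orientation, which preserves the natural strand of
   real reads.  Ties across *distinct* locations are ambiguous and the
   read is dropped.  Resolved hits are additionally capped at non-BS
   mismatches ≤ k.

The default budget k is 3 for reads longer than 51 bp and 2 otherwise,
overridable.

### Color-space pipeline

SOLiD reads are a primer base plus color digits; the first color (the
primer transition) is excluded from genome search queries, since it is not
a genomic di-base.  A directional library sequences only the original
bisulfite-treated strands, so only two orientations are valid: the color
string forward against the plus reference, and forward against the
reverse-complement reference (conversion per strand before encoding makes
minus-strand reads match the RC reference directly).  Matches of the
*reversed* color string correspond to reverse-complement reads, which the
protocol cannot produce; they are probed only by the noise estimator.

The primary scan uses budget 4 because one bisulfite conversion appears as
two adjacent color mismatches against the fully converted reference.
After list filtering, candidates from both orientations are bucket-sorted
by color mismatch count and examined in ascending groups.  Each examined
hit is decoded by a dynamic program over the four bases per position:
transition cost 1 when a color disagrees with the di-base code of its
adjacent base pair, emission cost 1 unless the base equals the reference
base or the reference is C and the base is T (bisulfite, free); the primer
anchors the first transition.  Cost ties break toward reference-matching
bases, so an isolated mismatching color — including one at the final
position, where no second flanking color exists to disambiguate — is
resolved as a sequencing error rather than a substitution.  L colors
decode to L bases; the contract-level decoded read B[1..L−1] drops the
final, single-flank base, while the full decoding is used for the
alignment span and methylation calls.

The non-bisulfite mismatch count of a decoded hit charges 1 per base whose
*both* flanking colors mismatch the reference colors and which itself
mismatches non-bisulfitically (the first and last bases are charged on
their single available flank).  Runs of ≥ 3 consecutive color mismatches
are charged per this literal pairwise rule.  The first group-wise unique
strict-minimum hit is reported, capped at 3 non-BS mismatches (base
mismatches, not color mismatches, also in sensitive mode).

**Dual-index order.**  Reads are scanned on the fully converted references
(budget M1) first; "no mapping" — meaning no *unique resolved* hit, so
ambiguous reads get a second chance — falls through to the non-CpG
converted references (budget M2).  Results carry the reference label
(FULL/NONCPG).  Modes: fast = [M1 0, M2 3] then [M1 3, M2 0];
default = (4, 4); sensitive = (5, 5); M1, M2 ≤ 5.

**Noise estimation.**  err = reverse-complement mappings / mappings.  Each
read is mapped in the valid orientations; the invalid orientations are
probed in the same FULL-then-NONCPG order, and the read is marked as noise
when a strictly lower color-mismatch hit exists there, or when it maps
uniquely *only* in the invalid orientations (such reads are counted in the
denominator as mappings — otherwise deliberately reverse-complemented
contamination could never raise the estimate).  err is undefined when
nothing maps.

### Methylation calling

For every covered strandwise reference cytosine (plus-strand C under a
plus alignment, plus-strand G under a minus alignment), read C/G counts as
methylated and read T/A as unmethylated; any other base is ignored as
error/SNP.  Color reads contribute their decoded bases.  Context is
classified from the original genome reading strandwise: CG when the next
base is G, CHG when the base after next is G, else CHH; a cytosine too
close to the strandwise end to complete the trinucleotide is classified
from its available bases (CG if next is G, else CHH).  The per-context
level is 100 · Σ methylated / Σ (methylated + unmethylated), undefined for
an uncovered context.

## The simulator: what it does and does not emulate

`simulate_genome` draws i.i.d. bases at a target GC fraction (default
0.4, a realistic mammalian-like composition).  Reads are drawn uniformly
over positions and strands; each read cytosine is retained with
probability `meth_prob` **independently of context** — the identity-line
design in which the detected level of every context should equal the
simulated level.  The retention probability is deliberately named
methylation, not conversion: a 100 % "bisulfite rate" corresponds to
`meth_prob = 0`.  Base-read substitutions are drawn uniformly over
{0..max_snps} per read (color default {0, 1, 2}), never ref-C→T (which
would be conversion, not error); color reads are encoded after conversion
and substitutions, then per-color errors are injected at a uniform rate
(default 5 %), so a conversion flips two adjacent colors and an error one.
Directional color reads are produced only in the two valid orientations.

Not emulated: quality-score structure, indels, coverage or amplification
bias, CpG-island composition, context-dependent methylation, repeats
beyond what an i.i.d. genome contains.  Passing tests therefore
demonstrate correctness of the algorithms under the stated read model, not
performance on repeat-rich real genomes.

All randomness flows through `numpy.random.default_rng` with explicit
integer seeds; outputs are byte-identical across runs and platforms.

## Problem sizes and numerical choices

The end-to-end methylation-recovery checks use a 200 kb genome with
20,000 × 75 bp reads per methylation level (≈ 7.5× coverage, tens of
thousands of calls per context, binomial standard error ≈ 0.15 pp —
comfortably inside the ±1 pp acceptance band); the color-space noise and
mode-ordering checks use a 100 kb genome with 10,000 × 50-color reads
under the 97 % conversion / ≤ 2 SNP / 5 % color-error protocol.  A full
run of the acceptance script takes under a minute on one CPU.

Determinism and tie-breaking: hits sort by (chromosome, position); DP
traceback prefers reference-matching bases, then the smaller base index;
orientation ties at one location prefer the earlier table orientation.
Degenerate inputs: an empty genome is rejected; chromosomes shorter than
the query (or than 2 bases in color space) simply contribute no hits;
`k ≥ |query|` reports every window; a zero denominator (no mapped reads,
no covered context) reports an undefined value rather than 0.

## Known limitations

* Hamming-only alignment; no indel handling, no quality-aware scoring.
* Paired-end mates are mapped independently; no concordance rescue.
* A substitution at the final read base of a color read is
  information-theoretically indistinguishable from a color error and is
  resolved as an error (charged 0).
* The serialized index stores the genome and build parameters and rebuilds
  the converted texts on load; for the genome sizes this package targets
  that is cheap and keeps the on-disk format trivially versionable.
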