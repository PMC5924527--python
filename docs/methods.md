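# Methods

This note documents the models, parameter choices and numerical conventions
behind each module, what the synthetic generators do and do not emulate, and
the known limitations.

## Coordinate and rounding conventions

All intervals and positions are 0-based half-open internally; VCF positions
(1-based) and GFF3 output are converted at the I/O boundary. Phred offset is
fixed at 33 (offset-64 data is out of scope). All reported percentages and
densities round half-up at the printed precision (2 decimals for
percentages, 4 for per-kbp densities, 1 where a report conventionally uses
one decimal); half-up is used because it reproduces the conventional
renderings of QC reports, where banker's rounding would not (e.g.
1422/1440 → 98.8).

## Linker matching (CreClip rule)

The matcher scans every ungapped offset of the linker, and of its reverse
complement, against the read — including partial overhangs at both read
ends, down to an aligned span of `min_core` bases. A candidate qualifies iff

* `matches / aligned_length ≥ min_identity` (default 0.8), and
* it contains a run of ≥ `min_core` (default 9) consecutive exact matches,
  lying fully inside the read.

Among qualifying candidates the winner has the most matching bases; ties
break to the leftmost read start, then the plus strand, making the result
deterministic. The identity threshold is not fixed by the clipping rule
itself — the continuous-core requirement supplies the specificity — so 0.8
is a configurable default in line with NextClip-era practice. `N` bases
never match. Gapped alignment is deliberately not attempted: junction
read-throughs are substitution-dominated, and an ungapped scan is what the
base-matching heuristic being hardened actually does.

Requiring the exact core *fully inside* the read (not abutting an overhang)
is a design choice: a core truncated by the read end carries less evidence,
and the symmetric rule keeps the scan's behaviour identical at both ends.

Why 9 bp matters: for a 38-bp linker at 80 % identity, a random placement
passing the identity test alone is rare, but short overhang alignments
(span ≥ 9) would otherwise qualify on identity easily; demanding a 9-bp
exact run caps the per-read false-positive probability near
4⁻⁹ ≈ 3.8 × 10⁻⁶ per candidate placement, which the planted-truth
simulations confirm (precision ≥ 0.99 at 30 % linker incidence).

Clipping truncates a read to `[0, match_start)`. A truncated member shorter
than 25 bp (configurable; the original pipeline does not state a value) is
flagged and the pair demoted to single-end output, because paired-input
assemblers need files of equal cardinality. Clipped pairs are passed
through without reorientation. Clipping is idempotent: no qualifying match
survives its own truncation.

## 454 splitting

A read with a qualifying internal linker is split into
forward = `[0, start)` and reverse = `[end, len)`. The reverse segment's 3′
bases with quality below the threshold (default Q20) are dropped *before*
reverse-complementing (the quality array is reversed alongside), mimicking
the trim-then-flip order of the original processing, so the emitted pair
has mate-pair geometry.

## Adapter dropping

Stage 1 drops a read containing any exact adapter k-mer (k = 11 by default,
both strands) — the screen a k-mer-index contamination filter applies.
Stage 2 drops a read whose 3′ end equals an adapter prefix, or whose 5′ end
equals an adapter suffix, of ≥ 8 bp (both strands) — terminal fragments too
short for stage 1. Reads are never modified: downstream assemblers that
model full-length reads want contaminated reads gone, not trimmed. Chance
11-mer hits in clean reads occur at ≈ 10⁻³ per 100-bp read with one adapter;
this is the intended behaviour of an exact-k-mer screen, not a defect.

## k-mer spectrum and genome size

Counting is canonical: each window maps to min(k-mer, reverse complement),
making the histogram invariant to read strand. Windows containing non-ACGT
characters are skipped; reads are joined with an `N` sentinel so windows
never span read boundaries. Multiplicities above the cap (default 10⁴) bin
at the cap. The default backend encodes bases 2 bits each and counts 64-bit
codes vectorially; a dictionary backend defines the reference semantics,
and both are held to an independent dictionary oracle in the tests. k = 23
is the default word size, large enough that a ~10²–10³ Mb genome's k-mers
are mostly unique, small enough that per-k-mer coverage stays high.

Spectrum analysis is deliberately descriptive (smoothed local extrema), not
a mixture-model fit: the histogram f(m) for m ≥ 1 is smoothed with a
centred moving average (window 5 bins, edges truncated — the nonexistent
m = 0 bin is never treated as an observed zero, which would manufacture a
minimum at the origin). The error cutoff is the first local minimum after
m = 1 (first strict rise of the smoothed curve); a spectrum with no rise is
rejected with advice that coverage is too shallow. The main peak λ is the
smoothed argmax beyond the cutoff. Secondary peaks are local maxima beyond
the cutoff whose position lies within a relative tolerance (default 0.12)
of 0.5λ, 2λ or 3λ, classified HET/DUP/TRIP; the 0.12 tolerance
accommodates the off-ratio secondary peaks real spectra show. A noise floor
(default 0.5 % of the main-peak height) keeps counting-noise wiggles in the
deep tail from registering as peaks.

Genome size is `Σ_{m > cutoff} m·f(m) / λ`, i.e. total non-error k-mer mass
over per-copy depth; repeats contribute in proportion to copy number, as
they must. Because λ is an integer multiplicity, the estimate carries a
granularity bias of order 1/λ (≈ ±2 % at λ ≈ 47) — visible in the
simulations, and the reason the recovery tolerance is 2 % on error-free
data. With substitution errors at rate e the effective per-copy depth
scales by (1−e)^k and the error mass concentrates below the cutoff; the
estimator stays within 5 % at e = 0.005 in the simulations.

## Insert size

The insert is the outer distance, leftmost start to rightmost end of the
pair — the convention distance-based scaffolders consume. A pair is used
only if both mates map to one contig of length ≥ 3× the nominal insert
(shorter contigs cannot host the long tail of the distribution, biasing the
mean down), in the expected orientation (FR by default, since processed MP
reads mimic FR geometry; TANDEM is always rejected), with both MAPQ ≥ 20.
Inserts farther than 10×MAD from the median are removed in one pass before
mean/sd — a deliberately loose robust gate that only discards gross
chimeras (e.g. residual junction artifacts) without touching the
distribution's genuine tails. PCR duplicates are not collapsed here;
duplicate marking belongs to the alignment pipeline. Every rejection class
is counted and reported; zero usable pairs is an error carrying those
counts.

## Assembly statistics

Nx/Lx follow the cumulative definition: sort descending, Nx is the length
at which the running sum first reaches x % of the total, Lx the number of
scaffolds up to and including it. The final filter keeps scaffolds
≥ 250 bp by default (fragments shorter than the read length of the library
that built the contigs are likely assembly artifacts); the boundary is
inclusive. Cutoff tables recompute every metric on the ≥-cutoff subset, so
the cutoff-0 row equals the whole-set statistics. The N metric counts
literal N/n bases only.

## Variant hard filter

The rule battery is applied exactly as printed, with *strict* inequalities:
a SNP with MQ = 40.0 fails the `MQ > 40.0` keep condition. Two points are
noteworthy and intentional: `FS < 20.0` is considerably stricter than the
customary FS > 60 fail threshold, and the indel rule set omits MQ and
MQRankSum entirely. A rule whose annotation is absent passes by default
(rank-sum statistics are undefined at many sites; this matches caller
convention), configurably. Mask subtraction tests the variant's start
coordinate only against the merged intervals — indel spans are not
intersected, keeping the rule simple and reproducible. Zygosity
percentages report HOM_ALT over total per type; a type with no observed
variants is absent from the report rather than 0 %. Heterozygous densities
divide het counts by an *explicitly supplied* non-masked length: which
masker defines "non-masked" is a pipeline decision, so the denominator is
never derived silently. Note that a denominator quoted to three significant
figures (e.g. 138 Mbp) leaves a 4-decimal density uncertain by about one
unit in the last digit.

## Hint construction

Hits are ranked per query by score, ties broken by longer summed segment
length, then leftmost target start, then contig id (the tie-break is this
package's, chosen for determinism). The best hit is TOP; up to two more are
SECONDARY; the rest are dropped ("three hits per query" is read as three
total). Truncation removes `cut` bp from *each side* of every CDS segment —
3/9 bp for protein top/secondary evidence, 0/3 bp for transcript — applied
literally in target bp; a switch rounds protein cuts up to codon multiples
for users who prefer frame-preserving cuts. Segments left shorter than 1 bp
are dropped and counted. Clustering is single-linkage over *strictly*
overlapping segments within one contig/strand/evidence class (half-open
abutment is not overlap; evidence classes are never merged across). Gene
retention keeps exactly the models with both hint support and a protein
database hit — the conjunction that removes purely de novo predictions.

## Synthetic data

The generators define the study conditions used throughout the tests and
the acceptance script, chosen once:

* genomes: i.i.d. bases at GC 0.36 (typical Brassicaceae); duplication is a
  single contiguous segment appended as a second copy (total length is
  preserved), which is the minimal structure that produces a 2λ spectrum
  peak;
* reads: 100 bp at 60× over 200 kb for spectrum work (k-mer coverage
  ≈ 46.8), uniform starts, fair strands, i.i.d. substitutions (0 or 0.5 %);
  qualities encode the error model; adapter contamination is 3′
  read-through into tiled adapter copies;
* mate pairs: 150 bp reads, inserts N(5000, 300²) truncated to
  [2·read length, genome]; linkers are planted as read-throughs at the
  junction — the real Cre-Lox failure mode — at recorded offsets chosen so
  the 38-bp linker lies fully inside the read, with a truth table per read;
  the default linker is a fixed non-palindromic 38-bp placeholder (the real
  Cre-Lox linker sequence is a user input in production);
* pair alignments: same insert law on a 30 kb contig (1000 pairs) for
  recovery, a 12 kb contig (200 pairs) for the gate check;
* variants: 500 records whose annotations are drawn from ranges sitting
  clear of each threshold on the designed side, so pass/fail truth is
  unambiguous; ~10 % of passing annotations are omitted to exercise the
  missing-annotation convention; a ~20 % mask with recorded membership.

What the generators do *not* emulate: position- and cycle-dependent quality
profiles, indel sequencing errors, GC-coverage bias, PCR duplicates,
heterozygous genomes (diploid variation enters only through the variant
table, not the read simulator), and real repeat families. Passing tests
therefore demonstrate algorithmic correctness against controlled truth, not
robustness to every artifact of real libraries.

All generators draw from a seeded integer-based RNG and are deterministic
under their seed; no result depends on floating-point summation order.

## Problem sizes

The simulations run at desk scale by design: 200 kb genomes at 60× for
spectrum work, 2000 pairs for clipping sensitivity, 1000 alignments for
insert recovery, 500-instance randomised suites for the oracle-equivalence
checks. These sizes give sampling noise comfortably inside every stated
tolerance while keeping the whole suite fast. Data-dependent headline
numbers of a full-scale genome project (assembly N50, gene counts, a
227 Mb genome size) require the raw reads and are not reproduced;
recovery *properties* of the same estimators are verified instead.

## Known limitations

* The linker scan is ungapped; a linker copy containing an indel is found
  only if one flank still qualifies on its own.
* Spectrum analysis assumes a unimodal non-error coverage distribution per
  copy class; heavily contaminated or very low-coverage read sets can fail
  the valley search (reported as an error, with advice).
* The integer peak position bounds genome-size accuracy at ~1/λ.
* The minimal VCF subset preserves unknown INFO keys as opaque text but
  does not parse multi-sample files or symbolic alleles.
* `parse_sam_pairs` holds unmatched mates in memory; name-sorted input
  keeps that footprint at one record.
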