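# Methods

This note records the models, conventions and parameter choices behind each
pipeline stage, what the synthetic-data generator does and does not emulate,
and the numerical details a maintainer would need.

## Read QC

A read's *B-tail* is the maximal 3' suffix in which **every** base has
quality below `min_q` (default Q15). The name comes from Illumina 1.5-era
Phred-64 data, where such tails are runs of the character 'B' (Q2); the
definition used here is the quality threshold, not the literal character, so
it behaves identically on Phred-33 input. Trimming scans from the 3' end to
the first base at or above the threshold; interior low-quality bases and
low-quality *prefixes* are untouched. Trimming is idempotent and the final
base of any non-empty trimmed read has quality ≥ `min_q`.

Filtering is pair-level: a pair is dropped unless **both** trimmed mates are
at least `min_len` (default 50 bp). Repeat detection and cross-mate primer
design need usable sequence on both mates, so keeping half a pair has no
value downstream. The dataset cap (`max_pairs`, default 5,000,000) keeps the
first N QC-passed pairs in input order — deterministic, and equivalent to
truncating the file rather than random subsampling. 'N' bases receive no
special handling at QC; quality governs trimming, and later stages exclude
N from repeats and primers.

## Perfect-repeat detection

A reported locus satisfies three properties:

- **perfect** — the spanned sequence is the unit repeated a whole number of
  times, no interruptions ('N' never matches, so it breaks any run);
- **primitive** — the unit is not a repetition of a shorter string; this
  excludes homopolymers (unit length ≥ 2) and prevents an AC run from being
  re-reported as an ACAC run;
- **maximal** — the run cannot be extended by one full unit on either side.

Runs are found per unit length u by scanning the self-match array
`seq[i] == seq[i+u]`: a maximal match run of length k spans k+u bases of
tandem structure and contains ⌊(k+u)/u⌋ whole units. A run with a partial
trailing unit is anchored at its leftmost whole-unit start, so rotated
re-anchorings of the same tandem region are reported once. The test suite
checks the implementation against an independently formulated brute-force
enumerator on random and repeat-planted strings.

Minimum repeat counts per unit length default to 6 (dinucleotide) and 4
(tri- through hexanucleotide) — common practice for 100 bp read mining,
where a dinucleotide needs more copies to be a useful marker — and are fully
configurable; no published value exists for this knob, so every quantitative
claim in the tests is parameter-explicit.

Motif classes use the canonical representative: the lexicographically
smallest string among all cyclic rotations of the unit and of its reverse
complement (GT → AC, GAT → ATC). A positive pair gets exactly **one**
unit-length class — that of its longest run in bp, ties to the larger unit,
then the earlier locus on mate 1 before mate 2 — so per-class counts
partition the positive-pair total the way development-table rows sum. The
longest-run rule is this package's choice; any fixed deterministic rule
would preserve the partition property.

## Primer design

The designer is self-contained and deterministic, with Primer3-style
constraints (defaults): length 18–27 (optimum 20), Tm 57–63 °C (optimum 60),
GC 20–80%, homopolymer runs ≤ 4, no N, and no overlap with any detected
repeat on the primer's own mate. The reverse primer is taken verbatim from
mate 2 as sequenced: under the FR layout it already faces the forward primer
across the unsequenced insert, which is also why the amplicon length is
unknowable at design time (the simulator reports true amplicon sizes for
validation).

Melting temperatures use unified nearest-neighbor thermodynamics
(SantaLucia 1998): ΔH/ΔS sums over dimer steps plus terminal-initiation
terms, an entropic salt correction of 0.368·(L−1)·ln[Na⁺] (50 mM monovalent
default), and Tm = 1000·ΔH/(ΔS + R·ln(C_T/4)) − 273.15 at C_T = 50 nM total
strand concentration. For the rare self-complementary oligo the symmetry
term (−1.4 cal mol⁻¹K⁻¹) is added and the divisor becomes ln(C_T/1);
reference implementations differ on the concentration convention in this
case, which only matters for palindromic candidates. Values are
deterministic to 0.01 °C and agree with an independent hand-summed table
check to 0.1 °C.

3'-end complementarity is a simplified hairpin/dimer model: a candidate is
rejected if the reverse complement of its last `max_3prime_self_comp`
(default 3) bases occurs as a contiguous substring of itself, and a
candidate *pair* is rejected if either primer's 3'-tail reverse complement
occurs in the partner. ("Any subsequence" is implemented as contiguous
substring — the physically meaningful reading for duplex nucleation.)

Among all surviving (forward, reverse) combinations the pair minimizing

    |Tm_f − 60| + |Tm_r − 60| + |len_f − 20| + |len_r − 20| + |Tm_f − Tm_r|

wins; ties go to the leftmost forward window, then the leftmost reverse
window, making the choice unique and reproducible. This absolute-deviation
penalty is deliberately simpler than Primer3's full weighted objective; it
orders candidates sensibly and is easy to recompute in tests. The search is
exact (the penalty matrix over all candidate combinations is evaluated, with
clash masking), not heuristic.

The optional `require_ssr_one_mate_only` flag refuses to design for pairs
with repeats in both mates. A repeat visible in both mates signals an insert
so short the amplicon is likely too small to size — the short-insert guard
used when ordering primers.

## Uniqueness counting and pPALs

A primer's copy number is the number of (read, offset) positions at which
the primer **or its reverse complement** occurs as an exact substring of
either mate, across all pairs, overlapping occurrences included. This is
the strictest reading of "found only once", and the right one: any second
occurrence, on either strand, is evidence the primer site is not unique in
the sampled genome. A primer identical to its own reverse complement is
counted once per position (the pattern set is deduplicated).

Counting is a single streaming pass with a hand-built Aho–Corasick automaton
(dense transitions after failure-link folding), so memory scales with the
number of patterns times pattern length — never with dataset size — and the
result is independent of read order. A quadratic substring-scan oracle
verifies it exactly on toy sets.

A PAL is a pPAL iff both its primers have copy number exactly 1 (the design
read itself). Copy number 0 is impossible by construction and raises an
internal-consistency error. Copy-number histograms use the fixed bins
{1, 2–10, 11–100, 101–1,000, 1,001–10,000, 10,001–100,000, >100,000}.

## Summaries

Cross-dataset ratio statistics are **means of per-species proportions**, not
pooled ratios; on the packaged 32-species tables the two differ materially
(mean PAL/SSR ≈ 17% vs pooled ≈ 15%; mean pPAL/PAL ≈ 25% vs pooled ≈ 29%)
and only the ratio-mean convention reconciles with the headline percentages
quoted for such panels — a test enforces the distinction. Threshold counts
("over 500 pPALs") use strict inequality. Reported means round to the
nearest integer (128,484.94 → 128,485). The arcsin-square-root transform
asin(√p) is provided as a utility for downstream variance-stabilised
analysis of proportions; no cross-taxon hypothesis testing is performed
here. The packaged table fixture is checksummed at load.

## The simulator

The generator reproduces the *data regime* that makes the uniqueness filter
meaningful: sparse shotgun coverage of a large genome, where a single-copy
site appears in about one read and a k-copy site in about k. Concretely:

- A uniform-ACGT background genome (GC-content knob available) receives
  `n_loci` planted contexts — repeat plus private flanks, 560 bp by default —
  each copied to `copy_number` well-separated positions (≥ 2 read lengths of
  guard space). Flank bases adjacent to the repeat are forced to break the
  repeat period, so the planted run is maximal exactly as recorded.
- Each context is **certified amplifiable** at generation time: flanks are
  redrawn until the context contains exactly the planted repeat and no
  chance SSR, the 30 bp immediately 5' of the repeat admit at least one
  constraint-satisfying forward primer, and reverse-primer windows are dense
  enough downstream that *every* admissible mate-2 placement contains one.
  This is what "clean, amplifiable flanks" means as ground truth: a planted
  locus is guaranteed recoverable when sequenced without artifacts, so
  recovery shortfalls measure pipeline defects, not generator luck.
- Each context copy is covered by `coverage_per_locus` (default 1) anchored
  pairs. Fragment layouts are drawn per locus and replayed identically at
  every genomic copy, so a k-copy locus yields exactly k occurrences of each
  primer-sized subsequence — the repetitive-element signature the filter
  must catch. Anchored fragments keep the two mates disjoint (insert ≥
  2·read_len + 10); overlapping mates would double-count any primer in the
  overlap. Remaining pairs are background, drawn uniformly *outside* all
  contexts so that primer copy numbers reflect genomic copy number rather
  than Poisson coverage noise.
- Reads follow the FR layout with Gaussian insert sizes (default
  300 ± 30 bp, clamped to the context); qualities are two-state — Q38 bases
  with optional Q2 B-tails of random length ≤ `btail_maxlen` appended at
  probability `btail_prob` per read — and substitutions are applied at
  `base_error_rate`, always changing the base. Output is deterministic given
  the seed, byte-for-byte.

What the simulator does **not** emulate: realistic position-dependent error
profiles, indels, adapter read-through, PCR duplicates, library-prep
chemistry differences (TruSeq vs Nextera is carried only as a metadata
label), or biologically realistic SSR densities and GC landscapes. Passing
recovery tests therefore demonstrate the pipeline's correctness under its
own contracts — detection, design, counting, filtering — not discovery
yields on real genomes, which the packaged 32-species tables represent
instead.

`score_recovery` compares pipeline output with the manifest: over covered
single-copy loci it reports the fraction recovered as SSR-positive, as PALs
and as pPALs; multi-copy loci are scored separately for specificity (a
pPAL call on one is a defect). On clean data all recalls are 1.0 and
multi-copy pPAL calls are 0; with substitution errors or B-tails recall
degrades monotonically, which the tests exercise.

## Problem sizes and determinism

The test suite and the acceptance script run the end-to-end check at 50,000
pairs over a 2 Mb genome with 40 planted loci (three multi-copy) — large
enough that background coverage makes chance repeats non-unique and the
locus sample is meaningful, small enough to run in seconds. The shared unit
fixture uses 5,000 pairs. Table aggregation is instantaneous.

All randomness flows through a single seed (NumPy `default_rng`; the read
stage derives seed+1). Reruns with identical parameters produce
byte-identical FASTQ, TSV and JSON artifacts; output files carry the package
version and a config hash but never timestamps.

## Known limitations

- The repeat detector reports compound/interrupted repeats as separate
  perfect runs; there is no imperfect-repeat mode.
- The primer designer's penalty and 3'-complementarity model are simplified
  relative to Primer3's full thermodynamic alignment; an external-designer
  adapter could be added behind the same interface, but the internal model
  defines the contract.
- Occurrence counting is exact-match only; a mismatch-tolerant mode (to
  catch near-identical repetitive elements) is out of scope.
- Amplicon sizes are unknowable from read pairs by construction; only the
  simulator can report them, for validation.
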