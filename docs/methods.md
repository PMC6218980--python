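# Methods

## Model of the artifact

During whole-genome amplification the polymerase may switch template and
re-elongate along an already synthesized product. The resulting molecule
is a prefix followed by the reverse complement of that prefix; if the
event recurs on the product, the palindromes nest, and *k* full-length
events yield 2^k copies of the original fragment. Sequenced as a single
long read, the molecule carries false adjacencies. The corrective model
is purely structural: a palindromic read is one whose self-vs-reverse-
complement local alignment is unexpectedly strong, and the correct
action is to cut at the palindrome center and re-examine both halves.
No base is ever changed: correction is a partition of the read.

## Detection

Each read *R* (length *n*) is aligned against rc(*R*) with exact
Smith-Waterman under a linear gap model. Scoring defaults are match +3,
mismatch −4, gap −3 per gap column — a mismatch-averse, indel-tolerant
scheme suited to reads with 11–38% error dominated by indels. The
expected per-pair score of random sequence is 0.25·3 − 0.75·4 = −2.25,
so chance local hits grow only logarithmically with *n* (Karlin–Altschul
regime) while a genuine palindrome of arm length *a* scores close to
3*a* even through two error-laden copies.

A hit must clear five ratios: filter factor (score ≥ 0.01 × match × n),
query coverage (aligned fraction of the read ≥ 0.01), query identity
(identical fraction of aligned columns ≥ 0.01), relative score (score
per column ≥ 0.01), and base score (score per read base ≥ 1.0). The
five names follow the established hit-filter vocabulary for local
alignment; their precise ratio definitions here are this package's own
reconstruction, chosen so that with the printed defaults the base score
is the operative criterion — the only reading under which random
non-palindromic reads are not flagged while heavily eroded palindromes
still are. Empty alignments (score 0) always fail; no division by zero
can occur because an empty hit has zero columns and is rejected first.

The aligner is a numba-jitted full-matrix DP with Python traceback. It
is exact: the test suite checks score equality against a naive
pure-Python full-matrix oracle on hundreds of random pairs, and the
traceback re-scores column by column to the reported score. Among
equal-scoring optima the hit with the smallest query start, then target
start, is chosen (candidate end cells are examined in row-major order,
capped at 256 cells — the cap can only matter on adversarial degenerate
input such as long homopolymers, where any optimal hit is equally
acceptable). Ties inside a traceback prefer diagonal, then query-gap,
then target-gap steps. N never matches anything, including another N,
and rc(N) = N: conservative, so N-runs cannot fabricate palindromes.
Memory is quadratic in read length; reads longer than a configurable
cap (default 100 kb, ≈ 40 GB of int32 matrix at the cap) are passed
through uncorrected with a warning rather than risking the host.

## Splitting and recursion

For an accepted hit, target coordinates are mirrored into read space
(position *j* on rc(*R*) is position *n*−1−*j* on *R*), giving arm 2 =
[n−t₁, n−t₀). The split point is the floor midpoint of the union of
arm 1 = [q₀, q₁) and arm 2. For a perfect palindrome both arms are the
whole read and the midpoint is *n*/2; for an embedded palindrome
B + X + rc(X) + C the union is the palindromic region and the midpoint
is its center, the arm junction. When random flanks happen to extend
the local alignment a few bases past the true arm boundary, the
midpoint shifts by at most half the extension — observed offsets on
simulated 12%-error reads stay near 1% of read length. An alternative
rule (midpoint of the query interval alone) coincides with the union
midpoint in the dominant adjacent-arm case but is not mirror-symmetric;
the union midpoint is invariant under exchanging the hit with its
mirrored twin, which makes detection strand-symmetric in practice. A
computed position of 0 or *n* is treated as "no split" to guarantee
strict progress.

Recursion is depth-first, left child first, so emitted fragments are
ordered left-to-right in input coordinates. Only the single best hit is
used per iteration — nested or multiple palindromes are found by the
recursion itself. Every split produces two strictly shorter fragments,
so termination is guaranteed; a safety cap of 64 split events per read
(real WGA read sets show up to ~15) additionally bounds adversarial
input, with remaining fragments emitted unsplit under a warning.
Fragments shorter than `min_len` (default 50 b) are discarded — counted
and reported, not silently dropped — and the rule applies equally to
never-split short input reads. Fragments of length ≥ 2 are always
re-tested for further palindromes until emitted or discarded.

Fragment identifiers are `{parent}:{start}-{end}` with 0-based
half-open coordinates always in the frame of the original input read;
nested splits therefore compose flatly, and the emitted + discarded
intervals provably tile the input, which the conservation tests assert
byte for byte.

## Simulator

The simulator generates the study conditions for all tests. Templates
are i.i.d. random DNA with adjustable GC. The fold operator returns
`seq[:b] + rc(seq[:b])` (default breakpoint: full length), mirroring
the re-elongation mechanism without modeling polymerase kinetics;
repeated full-length folds create nested palindromes with 2^k copies.
Errors are applied per base: deletion and substitution are exclusive
events decided by one uniform draw (substitution always changes the
base), and an insertion of a random base may follow each template base
independently. Defaults — substitution 0.01, insertion 0.08, deletion
0.03, ≈ 12% total, indel-dominated — emulate early-chemistry PacBio
reads; all rates are configurable up to 1.0 (forced substitution is a
useful degenerate test case). A monotone coordinate map from pre- to
post-error positions projects true fold points into read coordinates,
so split accuracy can be scored exactly. For *k* nested folds the
ground truth records all 2^k − 1 internal arm boundaries as true split
targets; for a single fold this is just the projected fold point.

What the simulator does not emulate: MDA branching and coverage bias,
chimeras joining distant genomic loci, position- or context-dependent
error rates, and realistic quality values (FASTQ output uses a constant
quality). Passing tests therefore demonstrate correctness of the
detection/splitting machinery under an idealized error process, not
performance on any particular instrument's error profile; on real data
the operative score threshold behaves the same way, but detection power
at extreme error rates (towards 38%) will be lower than the simulated
12% figures suggest.

## Statistics

A read counts as "with palindromes" iff at least one split was
performed. Mean output length averages emitted fragments only,
excluding discarded ones, matching the usual before/after read-length
tables. The GC profile is a per-read histogram over [0,1] normalized to
unit mass, with N excluded from numerator and denominator and all-N
reads excluded with a warning; since correction only cuts, aggregate
base-level GC is conserved whenever nothing is discarded, which the
tests verify.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale read sets: 1,000 mixed reads at
template 400 b for conservation, 100 + 100 reads at template 500 b for
detection/false-positive recovery, 200 random pairs up to 300 b for
oracle equivalence — sizes at which the whole suite completes in tens
of seconds while exercising every code path. All randomness is
seeded; identical seeds give byte-identical read sets and outputs.
Detection on the simulated 12%-error single-fold sets is complete
(100%), false positives are absent, and predicted splits land within
~1% of read length of the projected true fold point — comfortably
inside the package's own acceptance thresholds (≥ 95% detection,
≤ 1% false positives, ≤ 2% split offset), all recomputed at run time
by `scripts/acceptance.py` and the test suite.

## Known limitations

* Quadratic time and memory in read length; ultra-long reads (beyond
  the 100 kb cap) are passed through unexamined.
* Linear gap model only; no affine gaps, no quality-aware scoring.
* Palindromes whose center lies within `min_len` of a read end can
  leave a sub-threshold fragment that is discarded rather than emitted.
* Chimeras that join distant loci without inverted orientation are out
  of scope — they produce no self-vs-rc signal.
* Biological (genuine) palindromes and inverted repeats long enough to
  clear the score threshold are indistinguishable from artifacts and
  will be split; on real genomes this mainly affects reads spanning
  long inverted repeats.
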