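# Methods

This note records the models implemented in `smsmap`, the parameter
defaults and why they were chosen, the numerical conventions, and the
limitations of the synthetic data used to validate the pipeline.

## Error model and anchor combinatorics

Sequencing is modeled as a scan across a template in which every step errs
independently with probability ρ. Error-free words therefore have geometric
length: Pr{W ≥ K} = (1−ρ)^K, with mean word length 1/ρ − 1 (≈ 5.67 at
ρ = 0.15). The *waiting length* — the expected number of sequenced bases
until a word of length ≥ K appears with probability 1 − ε — is

    t = log ε / log(1 − (1−ρ)^K),   bases = t · (1/ρ − K(1−ρ)^K / (1−(1−ρ)^K)).

For exact finite-length statements the model is conditioned on the error
*count*: a read of length L with M errors at uniformly random positions is
cut into M+1 parts forming a strict composition of L+1; parts of size
λ > K are anchors (λ − 1 ≥ K error-free bases plus the trailing error).
`c_{M,N,K}(L)`, the number of arrangements with exactly N anchors, is
computed two ways:

* **Polynomial route** — coefficient of `t^(L+1)` in
  `C(M+1,N) · A(t)^N · S(t)^(M+1−N)` with `S(t) = t + … + t^K` and
  `A(t) = t^(K+1) + t^(K+2) + …`, truncating every intermediate product at
  degree L+1. All intermediates are nonnegative integers bounded by the
  final total, so any integer width that can hold the answer can hold the
  computation.
* **Closed form** — `C(M+1,N) Σ_i (−1)^i C(M+1−N, i) C(M+D−iK, M)` with
  `D = L − NK − M` and `i ≤ min(⌈D/K⌉, M+1−N)`. The alternating terms can
  exceed the result by hundreds of bits (at M=75, N=1, K=15, L=1000 the 61
  nonzero terms span 93–401 bits around a 294-bit result), so the sum is
  evaluated in Python's unbounded integers; the term diagnostics are
  exposed. For K = 0 the statement follows the constructive derivation:
  every part is an anchor, so the count is C(L, M) concentrated at
  N = M+1.

Both routes are cross-checked against each other and against brute-force
enumeration of all C(L, M) error placements for every (L ≤ 14, M ≤ 5,
K ≤ 4). Moments of N are exact rationals:
μ = (M+1)·C(L−K,M)/C(L,M) and σ² = M(M+1)·C(L−2K,M)/C(L,M) + μ − μ². For
large M the pmf is approximated by a normal density,
`c ≈ C(L,M)·φ((N−μ)/σ)/σ`, and the survival function by
`C(L,M)·(1 − Φ((N−½−μ)/σ))` with a continuity correction. The 1/σ density
scaling is required for the coefficients to total C(L, M); without it the
approximation is off by a factor of σ. At L = 1000, M = 150, K = 15 the
approximation is within 0.01 of the exact pmf (relative to C(L, M)).

A consequence worth recording: the exact probability of ≥ 10 anchors of
length ≥ 15 in a 1000-base read with 150 errors is
`NumConfigurations(150,10,15,1000)/C(1000,150) ≈ 0.9388` — high, but
noticeably below the ≈ 97% sometimes quoted for these parameters; we report
the exact value computed at run time rather than hard-coding either number.

## Mapping pipeline

**Index.** A plain suffix array (numpy prefix doubling, O(n log² n)) over
the concatenated reference with a non-nucleotide separator byte between
records, so matches never span records. Only the query contract matters:
`COUNTLCP` finds the longest prefix of a query present in the text, its
count, and (under a count cap) its positions, via binary search in 64-byte
windows so long queries never force long comparisons. A BWT-FM index would
support the same queries; nothing downstream depends on the choice.

**Anchoring.** For each read position the LCP is shortened by
`lcp_shorten = 1` base (an LCP tends to end *in* a sequencing error), with
floor K = 12. Positions with more than `MaxCount = 10000` occurrences are
skipped. Anchors containing N are rejected to avoid poly-N artifacts. The
reverse complement of the read is scanned independently; strands never mix
within a cluster.

**Clustering.** Every anchor seeds a window of genome span R; anchors in a
window are chained by O(n²) dynamic programming maximizing total anchor
bases, with non-overlap in both coordinates. Duplicate chains and chains
whose genome span lies inside a better chain's span (the suffix chains the
sliding windows inevitably produce) are dropped. Clusters are ranked by
Σ log(1/freq(a)) with freq(a) = Freq(a)/G the anchor sequence's *relative*
genomic frequency — equivalently Σ log(G/Freq(a)), the negative log chance
that this particular combination of matches lands together by accident.
Reading the frequency as relative is essential: with raw counts the score
is maximized by tiny clusters and a kilobase read's true cluster (which at
1 Mb scale almost always contains at least one multi-copy anchor) would be
outranked by dozens of one-anchor accidents, capping end-to-end accuracy
far below what the method demonstrably achieves. Ties break by anchor
bases, then leftmost genome position. The top `MaxCandidates = 10` proceed;
the full list is kept for significance counting.

**Refinement and banded alignment.** The candidate interval extends the
chained anchors by the unanchored read prefix/suffix scaled by (1+δ),
δ = 0.15 being the assumed maximum insertion rate, rounded outward
(floor/ceil) and clamped to the containing record. Inside it, all exact
matches of fixed length K^SDP = 11 (the upper end of the typical 8–11
range, keeping match multiplicity low) are chained by sparse dynamic
programming — maximum cardinality, strictly increasing in both coordinates,
O(n log n) patience chaining; for the modest match sets that arise in
practice an exact pass additionally breaks ties toward the chain with the
smallest total diagonal drift, which yields the tightest guide band. The
guide band gives rows covered by a chain match a half-width `b_SDP = 15`
about the match diagonal — wide enough to absorb the indel drift expected
across one K^SDP gap at δ = 0.15 — and rows between matches
`b_drift = |Δdiagonal| + b_SDP`; rows outside the chain extend the nearest
diagonal, and the band is widened minimally until both endpoints are
monotone with consecutive rows overlapping or adjacent (which also
guarantees at least one complete path always exists). The alignment is
global in the read and free at the interval ends, since the interval
already carries the (1+δ) flanks.

Scoring follows the phred-cost recurrence with per-base quality tracks
(insertion I, substitution S, deletion D, and alternative calls Ŝ, D̂);
without tracks, flat penalties 20/15/15 apply. Two indexing conventions
deserve note. The deletion discount applies when D̂_i matches the genome
base *consumed* by the deletion: conditioning on the preceding base instead
would break the invariance of the optimal cost under jointly
reverse-complementing read and interval, which the implementation
maintains (exactly so when the deletion track is position-uniform — a
deletion consumes no read base, so its quality is indexed by the adjacent
read row and is inherently read-direction-asymmetric when it varies per
position). All costs are small integers, so the float dynamic programming
is exact and traceback re-derives moves by equality, preferring diagonal,
then deletion, then insertion. Each row is computed as a vectorized
minimum over diagonal/vertical candidates followed by a prefix-scan for
within-row deletion chains.

**Mapping quality.** `Pr(r | g interval)` uses the phred-scaled Viterbi
cost, `10^(−cost/10)` — a deliberate approximation to the Pair-HMM forward
probability that reuses the quantity the aligner already minimizes. The
posterior over the top `MaxCandidates` candidates gives
`Q = round(−10 log10(1 − posterior))`, capped at 254 (255 is reserved in
SAM). When the number of *significant* clusters n_sig exceeds
`MaxCandidates`, the denominator is multiplied by ν = n_sig/MaxCandidates
to account for plausible locations never aligned. A cluster is significant
when its anchor bases exceed μ − 2σ of the anchor-bases distribution
expected at the true locus — genome-independent, depending only on read
length, accuracy and K. The mean is exact
((M+1) Σ_{v>K} (v−1) C(L−v, M−1)/C(L, M)); the variance comes from 10⁴
seeded Monte Carlo compositions. Moments are cached per (length bin,
accuracy bin, K) with quarter-octave log-spaced length bins (~8–185 kb) and
a 0.60–1.00 accuracy grid in steps of 0.01; each bin's seed derives
deterministically from its key, so results are independent of query order.
The best alignment's matches-per-column accuracy proxies the read's true
accuracy. Out-of-grid queries clamp to the nearest bin with a logged
warning.

## Anchor similarity

The similarity S of two sequences is the length of the longest chain of
shared exact K-mers, ordered and non-overlapping in both sequences, in
which every consecutive pair at starts (a, b) and (a′, b′) satisfies
1−δ ≤ (b−a)/(b′−a′) ≤ 1+δ. Gaps are at least K > 0, so the ratio is always
defined. The chain is computed by O(n²) dynamic programming over the match
set; for a repeat-free sequence S(x, x) = ⌊|x|/K⌋. The pairwise-chain
formulation is the normative definition here; genome-scale censuses are
supported only as loops over user-supplied interval samples.

## Read simulator

The simulator emulates indel-dominated SMS error behavior parametrically:
each scan step errs with probability ρ; error types are drawn i.i.d. from a
(substitution, insertion, deletion) mix of (0.10, 0.62, 0.28); insertions
emit a uniformly random base without consuming template, deletions consume
silently, substitutions emit a random different base. Validation contract:
error-free run lengths are geometric with parameter 1−ρ (log-frequency
falls linearly with slope log10(1−ρ)), the realized type mix is within
binomial noise of the configuration, and at ρ = 0 every read is an exact
genomic substring. Quality tracks carry the marginal per-base phred of each
error type (e.g. at ρ = 0.15: I = 10, S = 18, D = 14) with uniformly random
alternative calls.

What the simulator does *not* model: homopolymer-biased insertions,
position-dependent error rates, multi-base indel events, chimeric reads,
and the long-tailed read-length distribution of real instruments — so
passing tests demonstrate correctness of the pipeline under the stated
error process, not instrument-level realism. Mapping a simulated read is
also somewhat easier than mapping a real one on a real genome: an i.i.d.
random genome has no repeat families beyond chance k-mer collisions.

## Problem sizes and determinism

The test suite validates alignment against full-matrix oracles on 500
random pairs of up to 80 bases, SDP against a quadratic chain oracle on 500
match sets, and the combinatorics against exhaustive enumeration up to
L = 14. The end-to-end study uses a seeded 1 Mb random genome with 500
simulated 1000-base reads at ρ = 0.15 — sizes chosen so a single-core run
of the whole suite stays comfortable while leaving the per-read anchor
statistics at full kilobase scale; accuracy is insensitive to the genome
draw (fixed seeds make every run byte-reproducible). Observed on those
conditions: ≥ 95% of reads map within 50 bases of truth on the correct
strand, the mapping-quality distribution is strongly bimodal with the bulk
of reads at the Q = 254 cap, and reads with Q ≥ 30 are mismapped at a rate
below 10⁻².

## Known limitations

* The suffix array is uncompressed (≈ 8 bytes/base); genomes beyond a few
  hundred Mb would need a compressed index.
* Chaining and SDP are exact but quadratic in their (small) inputs; deeply
  repetitive references could inflate window sizes.
* Mapping quality trusts the Viterbi approximation; a forward-algorithm
  Pair-HMM would be better calibrated in the low-Q regime.
* Alignments are single, contiguous, and read-global: no split/chimeric
  alignment, no soft clipping.
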