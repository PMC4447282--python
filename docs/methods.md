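# Methods

This note records the models, conventions and numerical choices behind
`cisconserve`, and what the synthetic-data experiments do and do not
establish about real data.

## Sequence model and coordinates

Sequences are uppercase DNA over {A,C,G,T,N}. All internal coordinates
are 0-based, half-open; reports additionally emit ATG-relative positions
(position − atg_offset, negative upstream of the translation start),
because functional sites in regulatory elements are conventionally
located relative to the start codon. N is legal input but inert: any
k-mer containing N is excluded from matching, and N never equals N when
extending blocks — chance identity through ambiguity codes would
otherwise inflate every statistic.

## Similarity statistics

All similarity is exact-match, alignment-free. A *reverse* match at
(i, j) means `ref[i:i+k] == revcomp(query[j:j+k])`; plain reversal
without complementation has no biological reading and is not offered.

* `dotplot_matches` enumerates every matching (i, j) window pair via a
  reference k-mer index, O(n + m + matches).
* `count_shared_kmers` defaults to the number of *distinct* reference
  k-mer strings occurring in the query in any requested orientation
  (union over strands). Distinct-string counting is robust to internal
  repeats, which AT-rich non-coding DNA has in abundance; the
  match-pair count (number of dotplot dots) is selectable where a
  dot-count is wanted. Both conventions are exposed because the choice
  materially changes the statistic on repetitive sequence.
* `coverage_fraction` marks every query position lying under at least
  one shared k-window; the profile over k is non-increasing by
  construction, and k = 1 gives full coverage whenever the reference
  contains all four bases.
* `maximal_shared_blocks` seed-and-extends from min_length-mers: every
  maximal block of length ≥ min_length contains such a seed on its
  diagonal, so extending all seeds and deduplicating yields exactly the
  maximal set (checked against an exhaustive diagonal-run oracle in the
  tests). Overlapping and nested blocks are all reported; deduplication
  is a reporting decision, not an algorithmic one.
* Low-complexity flag: a block is flagged when its longest
  single-nucleotide run covers ≥ 60% of it, or it contains ≤ 3 distinct
  dinucleotides. This is a deliberately simple, deterministic proxy for
  "homopolymer or short tandem repeat"; it is not a DUST replacement and
  is only used to annotate blocks, never to filter them silently.

## Composition-preserving shuffles

The null hypothesis is "this much similarity arises from nucleotide
composition alone", with composition preserved at order 1
(mononucleotides), 2 (dinucleotides) or 3 (trinucleotides).

The default `exact_klet` method preserves the *exact multiset* of
order-lets: for order ≥ 2 it is the random-Eulerian-path construction on
the de Bruijn multigraph of (order−1)-mers — a uniform spanning
arborescence toward the terminal vertex is drawn with Wilson's
loop-erased random walk, the remaining out-edges of each vertex are
uniformly permuted with the arborescence edge exiting last, and the walk
consuming all edges is the replicate. Exact preservation gives sharp,
testable invariants: every k-let table for k ≤ order is identical, and
the first and last (order−1)-mers are fixed points. Degenerate graphs in
which every vertex has a single forced exit admit only the input
ordering; the input is returned with a warning. Sequences containing N
are shuffled within their N-free segments with N positions fixed.

The alternative `markov` method resamples from the fitted
order-(order−1) transition counts and preserves k-let counts only in
expectation; the test suite demonstrates the difference. Both are kept
because "shuffling" is used in both senses in the literature and the two
nulls are not identical.

Empirical p-value: p = #{replicates with count strictly greater than
observed} / n. Ties count as non-exceedances — the formula is applied
verbatim rather than replaced by the more conventional (x+1)/(n+1)
estimator, which is available but not default. p = 0 is reported as 0.0
annotated "< 1/n". n defaults to 1000, resolving p to 0.001.

## Motif scanning and mutagenesis

Consensus matching uses plain Hamming distance on the core with IUPAC
degeneracy counting as match and N in the scanned sequence counting as
mismatch. No position weighting: the inputs are consensus strings, not
frequency matrices, and pretending otherwise would manufacture
precision. Default strand mode is both strands — functional instances
are routinely found on the minus strand — and the strand mode is
recorded with every result because occurrence probabilities depend on
it. Overlapping hits are all reported; a palindromic even-width
consensus yields coincident +/− pairs, and the palindromic CACGCGTG
double site yields two overlapping hits, one per strand, by design.

Flank extension is greedy base-by-base identity outward from the
aligned core start in each direction, stopping at the first mismatch or
context end; minus-strand query hits are compared motif-forward.

`motif_null_probability` is the fraction of composition-preserving
reshuffles containing ≥ 1 exact hit on the requested strands. On an
i.i.d. background this converges to 1 − (1−q₊)^N (1−q₋)^N with
N = L − w + 1 window starts per strand and q± the products of per-base
frequencies over the consensus and its reverse complement. The two
per-strand probabilities are kept separate: collapsing them to
1 − (1−q)^(2N) is only valid for strand-symmetric composition
(f_A = f_T, f_C = f_G), and on realised i.i.d. sequence the symmetric
form is measurably wrong (several Monte-Carlo standard errors at
L = 1500).

Site mutagenesis is substitution-only (intervals keep their length, as
in reporter-construct engineering). Verification rescans the edited
interval extended by one motif width on each side, both strands, for
exact consensus matches; a valid design has zero survivors. The two
canonical designs — the UNC-30 core context aTAATCCcc → aTAGGCGac and
the palindromic AHR-1-like site CACGCGTG → CACAAGTG (destroying CACGC on
both strands) — are carried as package constants and verified in the
acceptance experiments.

## Reporter statistics

Expression per animal is the ratio of mCherry-positive (control) cells
that also express GFP; animals with zero mCherry cells are excluded with
a logged reason. Proportions carry Wilson score intervals (Wald is
available for comparison; Wilson has far better coverage at the small
per-cell-class counts involved). Fisher's exact test is two-sided by
probability ordering. Kruskal–Wallis uses tie-corrected H against the
chi-square reference by default — appropriate at the >100 animals per
construct these experiments use — with an exact permutation option
(total n ≤ 12) used by the tests to validate the approximation; fully
tied data return H = 0, p = 1 by convention rather than an error. The
rank-sum test is exact by full enumeration over rank assignments
(midranks, hence valid under ties) whenever C(n+m, n) ≤ 50 000, and the
tie-corrected normal approximation beyond that.

## Synthetic data: what it emulates, and what it does not

Backgrounds default to i.i.d. AT-rich composition (A = T = 0.32,
C = G = 0.18), the regime in which biased composition inflates chance
matches. Two scenarios bracket the regimes of interest:

* **congeneric** (defaults: 1.5 kb pair; four collinear conserved blocks
  of 23, 18, 15 and 20 nt with conserved spacing, plus a shared TAATCC
  site) — genuine sequence conservation; the k = 10 shuffle null should
  reject.
* **deep** (defaults: 2 kb pair; three TAATCC instances at shuffled
  positions, two on the minus strand, no conserved blocks) — motif
  content without conservation; the null should not reject, and maximal
  block lengths should sit inside the fully-random envelope.

Every generator is deterministic given its seed, and a truth record of
all planted coordinates accompanies each pair. Reporter tables draw GFP
and mCherry counts binomially over the cell-class maximum with the test
and control construct probabilities respectively.

What passing these experiments does *not* show: real upstream regions
are not i.i.d. (they contain repeats, poly-A/T runs and regional
composition gradients that an order-3 shuffle only partially captures),
real conserved blocks are not copied verbatim but decay by substitution
and indel, and real reporter counts are over-dispersed across transgenic
lines. The synthetic experiments validate the machinery — exactness of
the combinatorics, calibration of the empirical p, recovery of planted
signal — not the biology of any particular locus.

## Experiment sizes and numerical choices

The packaged experiments (`cisconserve.experiments`, driven by
`scripts/acceptance.py` and the end-to-end tests) use these problem
sizes, chosen so the whole battery runs in about a minute on one core:

* Calibration: 400 null queries × 200 replicates, 1 kb sequences,
  order 2, k = 8. k = 8 rather than 10: on 1 kb sequences the shared
  10-mer count is nearly Poisson with mean ~1, and a strictly-greater
  empirical p on so few distinct values is too discretised to sit at a
  5% level; at k = 8 the count distribution is rich enough (mean ≈ 50)
  for the rejection rate to land within binomial 99% bounds of the
  nominal level. The residual discreteness still biases the rate
  slightly above 5% — an inherent property of the strict-inequality
  formula, visible in the reported calibration number.
* Planted-signal detection: default congeneric scenario, k = 10,
  500 order-3 replicates.
* Chance-block envelope: 200 independent random pairs at the deep
  scenario's length and composition; block search seeded at 6 nt.
* Closed-form check: L = 1500 uniform i.i.d. background, consensus
  ACGTGA (non-self-overlapping, so clumping corrections are
  negligible), 1000 order-1 replicates, agreement required within
  3 Monte-Carlo standard errors.
* Reporter power: 0.9 vs 0.5 per-animal expression probability in a
  single-cell class, 100 animals per construct, 200 trials, α = 0.05.

Floating-point conventions: Wilson bounds are snapped to exactly 0/1 at
the empirical boundaries; exact-test comparisons use a 1e-12 slack when
comparing enumerated statistics to the observed one; permutation
enumeration limits (rank-sum C(n+m,n) ≤ 50 000, Kruskal–Wallis total
n ≤ 12) are hard caps, with the documented approximations beyond.

## Known limitations

* No gapped alignment, substitution matrices or indel evolution — out
  of scope by design; the method is exact-match only.
* The shuffle null conditions on composition of the *reference* only;
  GC-stratified or windowed shuffling is not implemented.
* Consensus scanning has no position weighting and therefore no notion
  of binding affinity.
* The low-complexity rule is a proxy, not a calibrated repeat detector.
* Empirical p-values are bounded below by 1/n; claims beyond that
  resolution require more replicates, not a different formula.
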