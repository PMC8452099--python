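# Methods

## The SCC decision rule

Let 𝒜 be the atomic class set (|𝒜| ≥ 2) and p(·) a posterior probability
vector over 𝒜 for one item.  For a certainty threshold β ∈ (0, 1], sort the
posterior descending (ties broken by the fixed class-set order, stably) and
take the shortest prefix whose cumulative mass reaches β.  The returned
*achieved certainty* is that cumulative mass, ≥ β by construction; the
decision's cardinality is its *precision*.  Properties the implementation
guarantees and the suite verifies:

* **Minimality.**  The sorted prefix of length K is a minimum-cardinality
  subset of 𝒜 with mass ≥ β (verified against brute-force subset
  enumeration).  Among subsets of equal cardinality it is the one with
  maximal mass.
* **MAP as a special case.**  β = 1/|𝒜| always yields the singleton
  containing the MAP class, because the maximum posterior entry can never be
  below 1/|𝒜|.
* **Monotone nesting.**  Decisions at β ≤ β′ are nested prefixes of the same
  permutation, so precision, correctness counts (truth ∈ decision) and
  collective certainty are all non-decreasing in β.
* **Numerical tie handling.**  The threshold comparison is `cum ≥ β − 1e-12`
  so that β = 1.0 terminates at the last nonzero entry despite
  floating-point cumulative sums like 0.9999999999999998.  Classes with
  posterior exactly 0 are never included: they add no certainty, and
  excluding them keeps a degenerate (1, 0, 0) posterior at precision 1 even
  at β = 1.

Transition points: the cumulative sorted posteriors c₁ ≤ … ≤ c₍|𝒜|−1₎ of an
item are the thresholds at which its decision loses precision; c₁ is the MAP
certainty.  For |𝒜| = 2 the single transition point is the maximum
responsibility, reported as a percentage rounded half-up to two decimals in
human-facing tables (internal values stay at full precision).

Collective certainty multiplies per-item *achieved* certainties (reported
with its logarithm to survive large datasets).  Independence of decisions is
a heuristic, not a theorem — the product is a rough joint-certainty gauge,
and achieved certainty (rather than the nominal β) is used because it is the
stronger per-item guarantee.

## Triplet genome models

A genome is summarised by the empirical distribution P3 of its 64 ordered
3-mers over {A, C, G, T}, counted over every length-3 window; windows
containing N are skipped (N carries no base information, and exclusion
avoids inventing an imputation).  The read likelihood factorises as

```
L(r₁…r_L) = P2(r₁r₂) · ∏ₖ T3(r₍ₖ₋₂₎, r₍ₖ₋₁₎ → rₖ)
```

where P2 is the pair marginal of the (pseudocounted) triplet counts and T3
the row-normalised transition table.  Because P2 marginalises the *same*
pseudocounted counts, the factorisation P3 = P2 · T3 is exact at any
pseudocount, and length-3 reads reproduce P3 to machine precision.  Summed
over all 4^L strings of fixed length L the likelihood is exactly 1: the
model is a proper distribution over fixed-length reads (verified by
enumeration to L = 6).

Parameters:

* **pseudocount** (default 0.5, Jeffreys-style; 0 allowed for exact toy
  calculations).  A ~30 kb genome can miss some of the 64 triplets entirely;
  without smoothing a single unseen triplet would zero a read's likelihood
  and destroy its posterior.
* **N handling in reads** — two modes.  `skip` (default) drops every factor
  whose 2- or 3-base window touches an N; log-likelihoods then remain
  comparable across models because every model drops the same factors.
  `marginalize` computes the exact likelihood summed over all {A,C,G,T}
  substitutions of the Ns by a forward pass over the 16 previous-two-base
  states with per-step rescaling; it is the principled choice when N density
  is high, at the cost of mild length-incomparability with N-free reads.
  The two modes agree on N-free reads exactly.
* **Strand.**  Likelihoods are forward-strand only; the simulator never
  reverse-complements, keeping the pipeline self-consistent.  A
  reverse-strand-aware mode (max of both orientations) would be a
  straightforward extension but is deliberately out of scope.

All likelihood arithmetic is in log space; posteriors use a max-shifted
normalisation, so 101-base reads (log-likelihoods near −140) and far-tail
mixture observations never underflow.

## Bayes layer

Posteriors are prior × likelihood, normalised in log space.  Priors may be
uniform (default), a shared vector, or per-item.  MAP ties break to the
first class in class-set order — determinism over elegance; ties are
measure-zero for continuous likelihoods.  Entropy summaries use natural
logarithm: a clean two-way split then scores ln 2 ≈ 0.693 and the
three-class maximum is ln 3 ≈ 1.099.  ECDF tables and a two-sample
Kolmogorov–Smirnov wrapper (scipy) support group comparisons of certainty
and entropy by read source.

## Gaussian-mixture front-end

EM for a 2-component (generally k-component) univariate normal mixture:

* **Initialisation** is quantile-based — observations are rank-split into k
  equal blocks, each moment-matched.  This makes the fit deterministic (no
  seed, no label switching), which is why `fit_mixture_em` takes no RNG;
  component order is normalised post hoc by ascending mean, so "component 1"
  is always the lower-mean component.
* **Convergence**: absolute log-likelihood change < 1e-8 or 1000 iterations
  (warning on non-convergence; observed-data log-likelihood is asserted
  non-decreasing).  Degenerate fits (a component's variance collapsing, or
  fewer distinct values than 2k) raise rather than returning garbage.
* **Responsibilities** are computed in log space and are invariant to a
  common shift of the log densities, so observations far in both tails
  still get well-defined posteriors.

A parametric-bootstrap goodness-of-fit harness draws replicate samples from
the fitted mixture and KS-tests each against the mixture CDF; its rejection
count at α = 0.05 is a stochastic calibration diagnostic, not a sharp
statistic.

## Synthetic data generator

The simulator emulates a short-read classification experiment end to end:

* **Random genomes**: i.i.d. bases with adjustable GC content.
  `reference_genome_trio` produces three genomes whose lengths
  (34,125 / 29,926 / 29,751) and GC contents (0.55 / 0.38 / 0.41) mirror a
  real adenovirus and two coronavirus reference genomes.  The compositions
  matter: i.i.d. genomes at *equal* GC are statistically exchangeable, so
  triplet models can separate their reads only through estimation noise
  (MAP rates near 0.46 in three-way classification) — whereas real reference
  genomes differ compositionally, which is precisely the signal a triplet
  classifier uses.  With the trio's realistic GC spread, scaled-down runs
  (20 kb genomes, 500 reads each) reach MAP rates of ~0.72–0.76; the two
  coronavirus-like genomes (GC 0.38 vs 0.41) remain the hardest pair to
  separate, as one would expect.
* **Reads**: length 101 at 6X coverage by default, so a genome of length G
  yields round(6·G/101) reads with uniform start positions.  Per-base
  i.i.d. errors: substitution 0.004 (to a uniformly random different base),
  insertion 5e-4, deletion 5e-4, N 0.001 — plausible Illumina-like
  magnitudes, all configurable.  Indels shift the window and the read is
  refilled from the genome downstream so corrupted reads keep exactly the
  configured length; each read carries its error-free twin and truth label.
  No quality model, no paired ends, no reverse strand.
* **Genome degradation**: each iteration applies per-base SNPs at 2.5e-5
  and single-base indels at 2.5e-6, so 1000–2000 iterations accumulate
  heavy but unsaturated divergence (the original-vs-degraded triplet KL
  grows monotonically with iterations).
* **Mixture draws**: component by weight, value from that component's
  normal, hidden component identity returned as truth.

Everything is reproducible under `numpy.random.default_rng(seed)`.

What passing tests on this synthetic data do and do not show: they verify
the estimators, the decision rule and the pipeline plumbing under a known
generative process.  They do not certify performance on real reads — real
genomes share homologous sequence far beyond composition, real error
profiles are position- and context-dependent, and real priors are rarely
uniform.  Correct-rates measured here are therefore properties of the
simulator's conditions, not predictions for any particular organism pair.

## Problem sizes used in the checks

The automated checks run the mixture example on its two printed anchor
observations; the certainty bound on 10⁵ random 3-class posteriors; oracle
equivalence on 10⁴ posteriors × 50 thresholds for each of |𝒜| = 2, 3, 4;
likelihood-mass enumeration to read length 6; the read experiment at 20 kb
genomes × 500 reads × 3 classes; and EM recovery on 12 independent datasets
of 5,000 draws.  These sizes were chosen so the whole suite completes in
well under a minute on one core while keeping every Monte-Carlo check
statistically meaningful.

## Known limitations

* k-mer order is fixed at 3; no general-order Markov extension.
* The decision lattice is the full power set of 𝒜; partially ordered
  restricted decision sets are not supported.
* Collective certainty's independence product is heuristic; no
  multiple-testing correction (Bonferroni/FDR) is implemented.
* FASTQ quality scores are ignored.
* Mixture fitting is univariate and primarily aimed at k = 2.
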