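# Methods

## Genome model

A genome on n signed genes is represented purely combinatorially as a perfect
matching of the 2n gene extremities: gene g contributes a tail (encoded as the
integer 2g−2) and a head (2g−1), and an adjacency is an unordered pair of
distinct extremities. Together with the implicit edge joining the two ends of
each gene, the n adjacencies decompose into disjoint cycles — circular
chromosomes. An adjacency joining the two ends of one gene is legal and forms
a one-gene circle. The model is deliberately **circular-only**: the analysis
is insensitive to the circular/linear and uni-/multichromosomal distinction up
to O(1) boundary terms, so we implement exactly the model the closed forms
describe and reject linear chromosome terminators (`$`, `|`) at parse time
rather than silently coercing them.

Chromosome decomposition is canonicalized — each cycle starts at its smallest
gene identifier in positive orientation — so that text round-trips and set
comparisons are deterministic.

## Distances and overlap structure

Breakpoint distance is d = n − a with a the shared-adjacency count; the score
of a candidate x against a trio is s(x) = (1/n)Σ d(x, gᵢ), an exact multiple
of 1/n since it is an integer sum divided by n. Trio overlap structure is
reported as ψ (three-way proportion) and ω₁₂, ω₁₃, ω₂₃, where each ω counts
adjacencies in *exactly* that pair: the three-way core is excluded so that ψ
and the ω's are additive, which is the convention the expected-score formula
s = 3 − (θ₁ + θ₂ + max θ₃ + Σω + ψ) requires. (The additive convention also
resolves a dimensional slip in informal statements like d(g₁,g₃) = n − ψ −
nω₁₃: the consistent form, and the one implemented, is n − nψ − nω₁₃.)

## Trio generator

`random_genome` draws a uniform random perfect matching of the 2n ends
(shuffle the ends, pair consecutively). Uniform matchings differ from uniform
signed circular permutations only in the chromosome-count distribution, which
none of the quantities studied here depend on; matchings are the distribution
the free-end arguments are cleanest under, so that is the one we fix.

`random_trio` produces genomes whose measured overlap profile equals the
request **exactly as counts**, not in expectation: a single random partial
matching supplies the four shared blocks (sizes round(nψ), round(nω₁₂), …),
each genome receives its blocks, and each genome's remaining free ends are
paired by a uniform matching. A completion that accidentally reproduces an
adjacency present in another genome would inflate a shared count, so
completions are drawn sequentially and any colliding matching is redrawn
whole (the accepted matching is therefore uniform over collision-free
matchings). Collisions are O(1) per pair of genomes, so a handful of redraws
suffices at any realistic n; a budget of 1000 redraws guards degenerate tiny-n
specs, which fail loudly. Exact counts were chosen because the asymptotic
theory treats ψ and the ω's as fixed proportions — binomial noise in the
inputs would only blur the comparison between simulation and closed form.

The generator emulates the overlap *structure* of a trio, not its
evolutionary history: real trios arise from rearrangement processes along a
tree, which induce correlations (common intervals, clustered breakpoints)
that uniform matchings lack. Agreement of simulation with the closed forms
therefore validates the sampling theory, not any claim about real genomes.

## The construction

`construct_antimedian` seeds a partial assembly with every adjacency of the
two-way and three-way overlaps, then samples in fixed order g₁ → g₂ → g₃ (the
CLI's `--order` flag permutes roles for symmetry experiments). A stage's
candidates are the source's adjacencies with both ends free; an explicit θ
takes a uniform random subset of round(nθ) of them (θ is interpreted relative
to n throughout, not relative to the exclusive block), failing loudly with the
achievable maximum if too few exist. The MAXIMAL third stage adds *all*
candidates: since candidates come from a single matching they are mutually
compatible, and compatibility with the assembly is per-adjacency, so greedy
inclusion is exactly maximal — no search is involved. Random completion pairs
the leftover free ends uniformly; it adds only O(1) adjacencies to any shared
count, so realized proportions determine the score to O(1/n).

## Closed forms and the general-overlap question

At zero overlaps, after sampling θ₁ and θ₂ the fraction of third-genome
adjacencies with two free ends is (1 − θ₁ − θ₂)², which is therefore the
maximal θ₃; the expected score 3 − (θ₁ + θ₂ + max θ₃) is concave with its
maximum on the ridge θ₁ + θ₂ = 0.5, and imposing the analogous stationarity
condition on all three genome pairs yields the unique symmetric anti-median
θᵢ = 0.25 (θᵢ = 0.25 − 0.5(ψ + Σω) with overlaps, requiring ψ + Σω ≤ 0.5).

With general overlaps two candidate closed forms exist for the maximal θ₃:

- **stationary** (the default): (1 − ψ − Σω − θ₁ − θ₂)², the form the
  symmetric stationarity system and its solution require;
- **conditional**: the same numerator divided by 1 − ψ − ω₁₃ − ω₂₃,
  obtained by conditioning on the third genome's own shared ends — of its
  n(1 − ψ − ω₁₃ − ω₂₃) exclusive adjacencies, each end is free with
  probability (1 − ψ − Σω − θ₁ − θ₂)/(1 − ψ − ω₁₃ − ω₂₃).

The two coincide whenever the third genome shares nothing beyond the
three-way core with either partner (and in particular at zero overlaps).
Both are exposed (`model="stationary" | "conditional"`), and
`empirical_max_theta3` reports realized values that simulations can compare
against either; the test suite records that on an asymmetric profile the
simulation lands on the conditional form. The stationary form remains the
default analytic model because the symmetric solution and the score-surface
maximization are stated in its terms.

An overlap-proportional allocation of the θ's (weight ½(ωᵢⱼ + ωᵢₖ) + ψ/3 per
genome, normalized) is implemented for comparison only; it fails the
stationarity equations except in symmetric cases and is not a maximizer.

## Numerical choices and problem sizes

- Proportion-to-count conversion always rounds to the nearest integer;
  O(1) rounding effects are below every tolerance used.
- Analytic values are computed in double precision; comparisons against the
  published 25-cell grid (θ ∈ {0.15, …, 0.35} at step 0.05) are made at 4
  decimal places after rounding.
- Simulation checks run at n = 10⁴ with 3 replicates and a 0.02 tolerance on
  realized θ₃ and score — at that size the sampling standard error is about
  10⁻², so the tolerance is a ~2σ band. The random-genome baseline (score ≈ 3)
  uses a 0.01 tolerance; shared counts there are O(1), i.e. O(10⁻⁴) on the
  score. Structural property tests (metric axioms, generator contract,
  monotonicity) use n between 25 and 2000, where they are already exact or
  deterministic.
- Stage sampling sorts the candidate list before drawing so results depend
  only on the seeded generator, not on set iteration order; all CLI commands
  with randomness require an explicit `--seed` and echo the resolved
  parameters into a provenance header, making outputs byte-reproducible.

## Limitations

- Equal gene content, no duplicates, circular chromosomes only; no DCJ or
  inversion distances.
- The maximum-matching completion variants that squeeze extra shared
  adjacencies out of individual instances are intentionally not implemented:
  the object of study is the purely statistical behaviour of random
  completion.
- The score surface is emitted as grid data (TSV); no rendering.
- The small-phylogeny iteration that would embed anti-medians in a tree
  search is out of scope.
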