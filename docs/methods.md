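# Methods

## Extinction theory

One round of settling selection is modelled as drawing `round(f·N)` of `N`
groups without replacement (minimum one draw; the theory requires `f·N ≥ 1`
for selection to be meaningful). A lineage present in `k` groups goes
extinct iff none of those groups is drawn, the zero-success term of a
hypergeometric distribution. `extinction_prob_exact` evaluates the product
`∏ (N−k−i)/(N−i)` as a sum of logs, so populations of 10⁵⁺ groups do not
underflow; agreement with exact rational counting (`C(N−k,d)/C(N,d)`) is
maintained to 10⁻¹² across all `N ≤ 30`.

As `N → ∞` at fixed `f` the exact probability converges to `(1−f)^k`. The
exponential form `exp(−k·f/(1−f))` additionally approximates
`ln(1−f) ≈ −f/(1−f)`, so it carries an N-independent error of order `k·f²`:
negligible at the 1% bottlenecks studied here (< 10⁻⁴ at `f = 0.01`), and
worth knowing about at `f ≳ 0.1`. Tests therefore check monotone convergence
of the exact form to `(1−f)^k` and bound the exponential form's residual gap
separately, rather than pretending the gap vanishes.

The bottleneck count `k` for a lineage of `m` cells uses a ceiling for
clonal development (`⌈m/mean size⌉`; a partially filled group still carries
the lineage — the worked example `100/50 = 2` does not discriminate ceiling
from floor) and `k = m` for aggregative development, an idealization valid
while mutants are rare relative to the number of groups.

## Lineage simulator

Each round applies three operators.

**Growth.** Ancestral and mutant subpopulations grow exponentially at rates
`λ` and `λ(1+s_c)` until the total has increased `growth_fold`-fold. The
stopping time solves `(I−m)e^{λt} + m e^{λ(1+s_c)t} = growth_fold·I`
(Brent's method on a bracketed interval; closed form when `s_c = 0`). `λ`
only sets the time scale and cancels from the final composition. Fractional
mutant counts are rounded stochastically (floor + Bernoulli on the
remainder) so integer bookkeeping adds no systematic bias.

**Development.** Group sizes are redrawn from the size distribution each
round until they hold the grown population, the last group trimmed to fit;
only the surviving totals carry over between rounds. Clonal allocation picks
groups uniformly at random and fills each entirely before the next — a
consequence of the branching growth form, which guarantees at most one mixed
group. Aggregative allocation marks `m` of the cells uniformly at random
(multivariate hypergeometric over groups), so larger groups receive
proportionally more mutants while capacities are respected.

**Settling selection.** Groups are sampled without replacement with
probability proportional to `n + (1+s_g)·m` until the sampled groups hold at
least `survival_fraction` of all cells. The sequential renormalized-weight
draw is implemented by sorting exponential keys `Exp(1)/weight` (successive
sampling — identical in distribution, vectorizable, and reproducible from
the seed). The overshoot beyond the exact cell target is removed by
discarding uniformly chosen cells from the selected groups: proportional in
expectation, total exact. An earlier implementation that rescaled every
selected group by a common factor and rounded by largest remainder was
rejected because small per-group mutant counts have systematically large
fractional parts under a ~0.99 factor, which spared mutants from the trim
and inflated their frequency by ≈1.5% per neutral round.

With `s_c = s_g = 0` each operator preserves the expected mutant frequency,
so a full round is a martingale; this is verified by Monte Carlo (10⁴
replicates, 3-SE band) and the single-round extinction fraction of a
two-group clonal lineage matches the hypergeometric prediction.

**Parameters and defaults.** `growth_fold = 100` and
`survival_fraction = 1/100` mirror a daily 100-fold batch growth followed by
transfer of 1% of biomass, keeping the population stationary across rounds;
`rounds = 5`; one initial mutant. `s_c` is dimensionless growth advantage;
`s_g ≥ 0` adds `s_g` per mutant cell to a group's survival weight.

**Desk-scale study conditions.** Simulation tests and examples use lognormal
group sizes (mean 50 cells — the worked example's value — log-SD 0.5) and an
initial population of 50 groups (≈2500 cells), i.e. ≈50 groups surviving
each bottleneck. The deterministic selection recursion
`f' = (1+s_g)f/(1 + s_g f)` shows why the bottleneck size matters for
*literal* fixation: at `s_g = 10` the post-selection frequency reaches only
≈0.99 by round five, so hitting the absorbing state within five rounds is a
finite-sample event that requires a bottleneck of at most ~10² groups. The
chosen scale places the simulations in this drift-dominated regime, which is
the regime of interest; at much larger population sizes the same parameters
give near-deterministic frequency trajectories that approach, but do not
touch, fixation within five rounds. For the same reason aggregative
lineages, though essentially never lost when growth-beneficial, can show a
*lower* five-round fixation fraction than surviving clonal lineages (which
fix at the group level); the meaningful contrast is extinction probability
and final mutant frequency, and tests assert exactly those.

## Phenotype statistics

**Settling rate** is the least-squares slope of the intensity-weighted
vertical centroid of biomass against time, in pixels/s (or length/s when a
pixel scale is supplied). Static illumination structure is removed by
subtracting each column's minimum over the whole stack. Because valid video
intensities are non-negative, symmetric sensor noise gets clipped at zero
and leaves a half-normal background of mean ≈ σ/√(2π) per pixel, which
drags the centroid toward the frame middle and biases the slope by 5–10% at
σ = 0.05; the estimator therefore isolates the foreground with an Otsu
threshold before the regression (`foreground="none"` restores the plain
centroid for clean data). The statistic is invariant to uniform intensity
scaling. Recovery of programmed front speeds is within 5% at σ ≤ 0.05.

**Flocculation efficiency** is the coefficient of variation of pixel
intensity in a single well-mixed frame — scale-free, 0 for a uniform frame,
higher when biomass is concentrated in flocs. The raw pixel variance is
exposed as an option for users who prefer an absolute measure; CV is the
primary statistic because it is invariant to illumination scale.

**Biomass-weighted mean size** bins a per-group size sample (e.g.
forward-scatter values) into 100 equal-width bins spanning [min, max],
weights each bin by the fraction of total biomass (sum of member values) it
holds, and averages the bin centers under those weights. It is a binned
size-biased mean: it always dominates the arithmetic mean, with equality
only for a degenerate sample, and moves by < 1% between 50 and 200 bins on
lognormal samples of 10⁴ values. Bin centers (not edges) represent each bin;
a degenerate sample short-circuits to its common value.

## Fitness and assortment

Relative fitness is `w = ln(E_f/E_0) / ln(A_f/A_0)` on endpoint counts taken
at the same two time points; counts may be whole clusters or deflocculated
cells as long as the unit is consistent (it is carried as metadata). The
optional normalizer divides by a reference fitness (e.g. an
ancestor-vs-ancestor control competition) rather than hard-coding any
normalization convention. Assortment `(f_set − f_pop)/(1 − f_pop)` is 0 when
settling leaves the focal frequency unchanged, 1 when the settled fraction
is pure focal strain, and bounded below by `−f_pop/(1−f_pop)`.

## Mutation-spectrum null

`simulate_snps` places SNPs uniformly over the genome with the alternate
base uniform over the three non-reference bases, then classifies each by
translating the affected codon before and after the change
(reverse-complemented for minus-strand genes): same residue → synonymous,
stop gained → nonsense, any other change (including stop loss) → missense.
Non-coding positions within a strand-aware window upstream of a gene start
(default 1000 bp, configurable) are labelled upstream; the remainder
intergenic; the two are reported jointly as the fourth class. The classifier
is validated by exhaustive agreement with an independent full-gene
translation oracle over every possible SNP of a 10 kb two-strand genome.

The bootstrap draws, with replacement, null subsamples of the pooled
observed size and tallies classes — realized as one multinomial draw over
the null class proportions per replicate, which is the identical
distribution at a fraction of the cost. Tails are reported with ties counted
in both tails (`P(sim ≥ obs)` and `P(sim ≤ obs)`, summing to ≥ 1). Because
class counts are discrete, the raw tail proportion is conservative
(super-uniform) under the null by construction; the tie-corrected mid-P
(`P(sim ≥ obs) − P(sim = obs)/2`), derivable from the two reported tails, is
the quantity that is uniform under the null, and calibration tests check
exactly that (KS at α = 0.01 over 500 synthetic experiments at the pooled
subsample sizes 69 and 104, 1000 resamples each) alongside the
conservativeness of the raw tails.

## Synthetic data: what it emulates, and what it does not

The generators provide distributionally controlled stand-ins, not replicas:
lognormal group sizes capture the right-skewed, strictly positive shape of
real cluster-size distributions but no real population's measured histogram
(empirical lists can be supplied verbatim); the settling video encodes
biomass as a unit-intensity band on a dark background with Gaussian sensor
noise, with none of the optics of a real cuvette (no scattering, no
refraction, no depth structure); the toy genome has uniform base composition
at a yeast-like GC fraction and single-CDS intron-free genes, far simpler
than a real genome; competition counts grow deterministically with optional
Poisson counting noise, with no shared-environment covariance between
strains. Passing tests therefore demonstrate correctness of the estimators
under known ground truth — unbiasedness, parameter recovery, calibration —
not robustness to every artifact of real instruments.

## Known limitations

- Single mutant lineage versus ancestor only; no interference among
  mutations, no within-group birth–death dynamics, no spatial structure.
- The clonal allocator applies the at-most-one-mixed-group rule every round;
  after round one, descendants of a part-mutant group could in reality seed
  several part-mutant propagules.
- The exponential extinction formula inherits an `O(k·f²)` bias relative to
  the exact hypergeometric limit; use `extinction_prob_exact` when `f` is
  not small.
- The settling-rate contract is displacement of the biomass centroid; front
  tracking or per-band velocimetry are out of scope.
- The drift-null covers SNPs only (no indels) and a four-class effect
  partition; finer effect categories (splice, frameshift, UTR) do not exist
  in the toy gene models.
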