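# groupsel

Group selection on clonal versus aggregative multicellular life cycles.

Nascent multicellular organisms can build groups in two fundamentally
different ways: clonally (daughter cells stay attached, as in "snowflake"
yeast, so every group is genetically uniform) or by aggregation (free cells
stick together into genetically mixed "flocs"). Under a life cycle that
alternates exponential growth with settling selection — only groups that
sediment fast enough survive each transfer — these two developmental modes
impose very different genetic bottlenecks on a new mutation, and therefore
very different prospects for multicellular adaptation. `groupsel` packages
the quantitative core of that comparison for people studying evolutionary
transitions in individuality, experimental evolution of multicellularity, or
levels-of-selection questions more broadly.

## What is inside

- **`lifecycle_theory`** — the extinction probability of a rare mutant
  lineage in one round of selection. If `k` of `N` groups carry the mutant
  and a fraction `f` of groups survives, survival of the lineage is a
  without-replacement sampling problem and

  p_e = ∏_{i=0}^{fN−1} (N−k−i)/(N−i) ≈ exp(−k·f/(1−f)) for large N.

  Clonal development concentrates `m` mutant cells into
  `k = ⌈m / mean group size⌉` groups; aggregative development scatters them
  (`k = m` when mutants are rare). That difference is the bottleneck.
- **`lifecycle_simulator`** — a stochastic simulator of a mutant lineage
  through repeated rounds of two-exponential growth
  `(I−m)e^{λt} + m e^{λ(1+s_c)t}`, life-cycle-specific packing of cells into
  groups, and settling selection of groups weighted by `n + (1+s_g)·m`,
  without replacement, until 1/100th of cells survive.
- **`group_phenotypes`** — settling rate from a video stack (biomass-centroid
  displacement regression), flocculation efficiency (pixel-intensity
  coefficient of variation of a well-mixed frame), and the biomass-weighted
  mean group size of a forward-scatter sample (100-bin size-biased mean).
- **`fitness_stats`** — relative fitness as the ratio of Malthusian growth
  parameters, and the assortment statistic
  `(f_set − f_pop)/(1 − f_pop)` of genotypic enrichment after settling.
- **`mutation_spectrum`** — a drift-null for mutation spectra: scatter random
  SNPs over an annotated genome, classify them (missense, nonsense,
  synonymous, upstream/intergenic) by codon lookup, and bootstrap-compare
  observed class counts to the null.
- **`synthetic_data`** — generators for every input above (group-size
  distributions, annotated toy genomes, settling videos, competition count
  tables) with known ground truth, so the whole pipeline is testable without
  laboratory data.

## Worked example

One mutant arises at the start of a growth phase and the population grows
100-fold, leaving 100 mutant cells. Groups average 50 cells and 1% of groups
survive settling:

```python
from groupsel import (LineageContext, SelectionRegime, extinction_prob_approx,
                      extinction_prob_exact, mutant_group_count)

k_c = mutant_group_count(LineageContext(100, 50, "clonal"))       # -> 2
k_a = mutant_group_count(LineageContext(100, 50, "aggregative"))  # -> 100
extinction_prob_approx(k_c, 0.01)                                 # -> 0.9800
extinction_prob_approx(k_a, 0.01)                                 # -> 0.3642
extinction_prob_exact(SelectionRegime(10000, 0.01, k_c))          # -> 0.9801
```

A clonally developing population loses this lineage 98% of the time, an
aggregative one only 36.4% of the time: clonal development pays a heavy
drift cost at the group bottleneck. The multi-round simulator shows the flip
side — group-beneficial mutations (here `s_g = 10`) are usually lost by
clonal lineages, but when they survive the first bottlenecks they sweep:

```python
from groupsel import SimParams, SizeDistributionSpec, run_ensemble

sizes = SizeDistributionSpec(family="lognormal", mean_size=50, dispersion=0.5,
                             n_groups=50)
summary = run_ensemble(SimParams(mode="clonal", s_g=10.0, seed=42), sizes, 1000)
summary.extinction_fraction   # -> 0.857
summary.fixation_fraction     # -> 0.117
```

Of the lineages that escape extinction, 82% reach fixation within the five
simulated rounds.

A `groupsel` command-line tool exposes the same operations
(`groupsel theory`, `simulate`, `synth`, `phenotype`, `fitness`, `mutspec`);
see `groupsel --help`.

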