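# Methods

## Model

`abosim` simulates a single autosomal locus with three alleles A, B, O in
a randomly mating, non-overlapping-generations population. The state
variable is the allele-frequency triple `(p, q, r)`; genotype frequencies
are always taken as Hardy–Weinberg proportions of the current allele
frequencies, never tracked as counts.

Selection is negative frequency-dependent at the phenotype level:
pathogens that infected hosts of a given antigen phenotype in the previous
generation are assumed better at infecting hosts expressing the same
antigens now, so each genotype's fitness is one minus `z` times the summed
frequency of genotypes sharing its phenotype. Dominance of A and B over O
makes the scheme asymmetric: AA and AO share one fitness, BB and BO
another, the co-dominant AB phenotype is penalised by both classes plus
itself, and OO only by its own frequency. The dial `z ∈ [0, 1]` scales all
penalties; `z = 0` is exact neutrality (the selection step is the identity
map).

Per-generation event order, fixed throughout the package:

1. alleles → Hardy–Weinberg zygotes;
2. zygote fitnesses from current genotype frequencies;
3. selection recursions → post-selection gamete expectations `(p', q', r')`,
   renormalised onto the simplex;
4. drift: one multinomial draw of the gamete pool;
5. next generation.

Mutation is ignored (a specific exon-6 deletion is not regenerated on
100-generation timescales), so zero frequencies and monomorphic states are
absorbing; the replicate loop exploits this with an early exit that cannot
change any outcome.

## Drift convention

The drift step samples **`ne` gene copies** per generation; `ne` is the
package's unit of effective size everywhere (grids, CLI, tables). A
diploid census of `N` individuals corresponds to `ne = 2N`. This is the
calibration under which the package's summary tables take their standard
values (e.g. neutral populations of `ne = 500` copies show ~1% complete
fixation within 100 generations); readers used to diploid `Ne` should
halve before comparing. Sampling gametes one at a time with replacement is
distributionally identical to the single multinomial draw used.

Seeding: each replicate owns a `numpy` `SeedSequence` spawned from the
master seed with key `(round(z·10⁴), ne, replicate)`. Streams therefore do
not depend on grid composition: a cell re-run alone bit-reproduces its
replicates from a full grid run.

## Loss statistics

Per cell the summary reports three related quantities:

* `prop_any_loss` — fraction of replicates with ≥ 1 allele at frequency
  exactly 0 after the final generation;
* `prop_lost_2` — fraction ending monomorphic (both A-class losses);
* `prop_lost_1` — the *allele-loss index*: total allele-loss events
  divided by the maximum possible (two per replicate), i.e.
  `(n_{≥1} + n_{2}) / (2·replicates)`. This is the "losing 1 allele"
  convention of the classic summary-table layout the grid mirrors, and
  always lies between the other two.

`frac_fix_O` is the fraction of fixation events (replicates ending
monomorphic) that fixed O; it is undefined (empty/`null`) when no
fixation occurred. Mean final frequencies average over *all* replicates,
fixed ones included. `he_var` uses the unbiased (n−1) estimator.

## Equilibrium and the selection-coefficient scale

Iterating the deterministic recursion from any interior start converges to
the unique interior fixed point `(0.19154, 0.19154, 0.61691)`. Because
every fitness is `1 − z·(genotype-frequency sum)`, `z` factors out of the
marginal-fitness equality and the fixed point is `z`-independent; only the
convergence rate varies (39 iterations at `z = 1`, 271 at `z = 0.25` for
tol 1e-10 from the uniform start). Default solver settings: tolerance
1e-10 on the maximum per-component change, 100 000 iteration cap,
non-convergence raises with the last iterate attached.

`z` is not a classical selection coefficient. To place it on that scale,
`selection_coefficient(z)` holds the deterministic model at the fixed
point and averages `|w_OO − w_AA|` over a 100-generation horizon. At the
fixed point the statistic is constant, hence exactly linear in `z`:
`s(z) = z·|r² − p² − 2pr| ≈ 0.1076·z`, i.e. "strong" selection `z = 1`
corresponds to `s` of roughly one tenth. (Note the value rounds to 0.11,
not 0.10, at two decimals; the one-tenth description is approximate.)

## Reference experiment and problem sizes

The default grid is `z ∈ {1, 0.75, 0.5, 0.25, 0}` × `ne ∈ {1000, 500,
250, 100, 50, 25, 10}`, 1000 replicates of 100 generations from
`(0.19, 0.19, 0.62)` (the rounded equilibrium; 100 generations ≈ 3000
years of human history, long enough that most loss events — typically
before generation 30 — are captured). The full grid takes a few seconds
on one core. The test suite runs the grid at 4000 replicates to tighten
its own Monte-Carlo error and compares stochastic quantities with
three-standard-error bands that include the Monte-Carlo variance of both
the reference values (1000 replicates) and its own estimates;
`scripts/acceptance.py` keeps the plain 1000-replicate protocol, except
that the rarely fixing `z = 0.5, ne = 50` cell uses 10 000 replicates so
its fixation fraction has a denominator worth reporting.

## Empirical utilities

**Allele estimation.** Published blood-group surveys report phenotype
frequencies (A, B, AB, O). The package uses the classical Bernstein
square-root estimator — `r = √O`, `p = 1 − √(B+O)`, `q = 1 − √(A+O)` —
followed by clipping at zero and renormalisation to an exact unit sum.
For Hardy–Weinberg-consistent input the estimator is exact
(`B + O = (q+r)²`); renormalisation absorbs sampling noise. No EM
refinement is attempted; for the aggregate uses here (regional averages,
He) the classical estimator is adequate, and an EM pass would be the
natural extension. He is always recomputed from the allele estimates, so
records carrying phenotypes and records carrying alleles are treated
identically.

**Isolation by distance.** `ibd_regression` is ordinary least squares of
He on distance-from-East-Africa (km, consumed as published — the
waypointed great-circle computation is out of scope), with the standard
two-sided t-test on the slope. Degenerate inputs are contracts, not
crashes: < 3 usable records raises, constant distances raise, a flat
response returns slope 0 with p-value 1.

**Model fit.** `least_squares_ss` is the raw sum of squared differences
over the three allele frequencies; no likelihoods or information criteria.
`regime_fit` lets each observed unit pick its best-fitting `ne` within a
regime and sums the minima. The grouping of observations is deliberately
caller-supplied: regional averages give a coarse comparison, while
supplying populations individually (the package's acceptance usage) makes
the statistic sensitive to the *composition* of the compilation — many
nearly O-fixed populations reward the strong-selection regimes, which are
the only ones producing nearly O-fixed small-`ne` cells, and that is what
produces the strongest-fits-best ranking.

## Synthetic population tables

`generate_fixture_populations` emulates the schema and gross structure of
published ABO compilations: seven continental regions whose centers sit
near the global O-rich equilibrium in the Old World and are strongly
O-shifted in the Americas (Central and South America nearly monomorphic
for O), with Dirichlet scatter around each center (concentration
`center / noise`), distances uniform in per-region ranges, Hardy–Weinberg
phenotypes, He and the full column set. An optional `far_center` slides
the mean triple across a region's distance range, injecting an
He-vs-distance gradient of known sign for parameter-recovery tests.

What the generator does *not* emulate: sampling error from finite blood
samples (phenotype counts are exact expectations of the drawn alleles),
non-Hardy-Weinberg structure within populations, shared ancestry between
nearby populations (records are independent draws), or the waypointed
distance geometry. Tests passing on fixtures therefore demonstrate
correctness of the estimators and regressions, not anything about real
compilations; with a real table supplied in the same schema the identical
code paths apply.

## Numerical choices and limitations

* Frequencies are double-precision floats, renormalised after every
  selection step; drift outputs are exact lattice fractions `k/ne`, so
  loss is tested by exact equality with zero.
* `w̄ > 0` is guaranteed for any polymorphic state; monomorphic states
  bypass selection (absorbing) and are the only way `w̄` could vanish.
* Exactly three alleles; no A1/A2 or O-allele subtypes, no mutation, no
  migration, selfing, separate sexes, overlapping generations or
  time-varying `ne`; no alternating pathogen regimes.
* Fitnesses respond to *current* genotype frequencies; a one-generation
  pathogen lag is part of the biological story but is not modelled as an
  explicit delay.
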