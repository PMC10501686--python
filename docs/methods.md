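# Methods

## The model

`expansionload` simulates a species range expansion with a mid-landscape
shift to self-fertilization, using a forward-time, individual-based,
non-Wright-Fisher model, and computes the genetic-load and purging
statistics used to compare such simulations with resequencing data from
natural populations.

### Landscape and demography

The landscape is a one-dimensional line of `n_demes` demes under
stepping-stone migration. Deme 1 (the core, carrying capacity `K_core`) is
initialized at capacity with mutation-free individuals and burned in as a
closed, obligately outcrossing population for `4 * K_core` generations.
The landscape then opens: individuals migrate with probability `m = 0.05`
per generation, direction uniform between the two neighbours, and boundary
demes send all their migrants to their single interior neighbour
(reflecting boundaries). All demes beyond the core have capacity `K_deme`.
The run stops `stop_extra_generations = 100` generations after the last
deme first reaches its carrying capacity; the expansion time is the number
of generations from opening the landscape to that crossing.

Generations are discrete and non-overlapping. Each generation, in order:

1. **Regulation.** The expected total offspring of a deme of census `N` is
   Beverton–Holt, `N' = R N / (1 + N/M)` with `M = K / (R - 1)` and growth
   rate `R = 1.2`, so `N = K` is the fixed point.
2. **Reproduction with fecundity selection.** Parent `i` leaves
   `Poisson(w_i / sum_j w_j * N')` offspring, so less fit parents leave
   fewer offspring and regulation and selection act through one draw. In
   demes at or beyond `shift_deme`, each parent is independently designated
   a selfer with probability `sigma` each generation; a selfed parent
   contributes both gametes of each of its offspring. Outcrossing parents
   draw, per offspring, a uniform mate among the *other* individuals of the
   deme — incidental selfing is disabled, so a lone outcrosser in a newly
   reached deme leaves no offspring. This mate limitation is the only Allee
   effect in the model and is what lets selfers colonize faster.
3. **Death and migration.** Parents die; offspring migrate.
4. **Recording.** Every `record_interval = 5` generations, each occupied
   deme records census, neutral nucleotide diversity, observed
   heterozygosity, mean fitness, per-individual lethal and deleterious
   allele counts, the homozygous-deleterious locus count, and the selfed
   offspring fraction.

### Genomes, mutation, fitness

Each individual carries two haploid genomes of `G` base pairs. Mutations
arise at rate `mu = 7e-8` per bp per generation and fall into four classes
with proportions 0.25 neutral, 0.001 beneficial, 0.649 deleterious and 0.1
lethal. Deleterious selection coefficients are `-Gamma(shape, mean=0.001)`
(shape 1, i.e. exponential, by default; 0.5 and 2 are the sensitivity
settings), beneficial ones `+Exponential(0.01)`, lethals `s = -1` exactly.
Dominance is `h = 0.3` for non-lethal selected mutations (0.5 in the fully
additive sensitivity set) and `h = 0.02` for lethals — partially recessive
lethals are what selfing exposes and purges. Fitness is multiplicative:
`1 + h s` per heterozygous and `1 + s` per homozygous mutation, clamped at
zero, computed once at birth.

Sites are finite with collision redraw: positions are integers in
`[0, G)`, and a new mutation landing on an occupied position is redrawn
(at `mu * G = 0.7` expected new mutations per gamete, collisions are
negligible; the redraw just keeps positions unique so that equal positions
imply the same allele). Gametes recombine with `Poisson(r * G)` crossovers
(`r = 1e-8`/bp) at uniform breakpoints. Globally fixed mutations are *not*
converted to substitutions: they keep contributing a constant factor to
every individual's fitness so that core-versus-edge comparisons within a
replicate share one reference. Consequently absolute fitness values drift
downward over a run as weakly deleterious mutations fix, and all load
comparisons in this package are within-replicate ratios or differences.

Implementation notes: haplotypes are immutable sorted arrays shared
between generations (an unrecombined, unmutated gamete is a reference, not
a copy), the per-haplotype heterozygous-factor product is cached on the
haplotype, and the homozygous correction `(1+s)/(1+hs)^2` is evaluated in
a two-pointer merge over the two position arrays (numba-accelerated when
numba is importable, with an identical numpy path otherwise).

### Scales

* `full-scale` preset: 50 demes, `K_core = 5000`, `K_deme = 200`,
  `G = 1e7`, burn-in 20,000 generations, shift at deme 25 — the full study
  conditions. With 20 replicates per selfing scenario this is an overnight
  computation; it is exposed through the CLI and not run by the test
  suite.
* `desk` preset: 10 demes, `K_core = 500`, `K_deme = 100`, `G = 1e6`,
  shift at deme 5, every per-bp rate and demographic ratio unchanged. One
  replicate takes ~20–25 s; the test suite and the acceptance script run
  replicated experiments at this scale. Expansion-load magnitudes shrink
  with the landscape (the desk core-to-edge fitness loss is ~1–2% for
  outcrossers versus ~29% at full scale) but every ordering and purging
  effect is preserved.
* `neutral-only` preset: one deme, `K = 200`, `G = 1e6`, every mutation
  neutral, burn-in `8N` — the coalescent equilibrium oracle
  (`pi -> 4 N mu`). Because the 1 Mb genome at `r = 1e-8` is a single
  weakly recombining block (`rho = 4 N r G = 8`), single-replicate `pi`
  has a CV around 0.35; equilibrium checks therefore average ~10
  replicates.

## Simulation-side statistics

* Neutral `pi`: per-site pairwise diversity over the whole deme census,
  `sum 2 p (1-p) * 2N/(2N-1) / G` over segregating neutral sites.
* Observed heterozygosity `H`: mean per-individual fraction of sites
  carried on exactly one haplotype.
* Fitness-change rate: `w(t) / w(t - 100)` per deme; 1 means no change.
* Realized DFE bins over segregating negatively selected sites:
  `(-0.0001, 0)`, `(-0.001, -0.0001]`, `(-1, -0.001]`, `{-1}` (right edges
  closed).
* Load proxies per individual over deleterious-class (non-lethal) sites:
  additive = derived allele count (the `h = 0.5` reading), recessive =
  homozygous-derived locus count (the `h = 0` reading). An
  `include_lethals` toggle exists on every counting operation (default off
  for the proxies, on for the fixed-site proportion, matching the
  empirical missense/nonsense-versus-LoF split).
* Purging drop: census-weighted per-individual lethal count over the
  selfing half of the landscape, measured `window = 200` generations after
  the expansion front first enters it, relative to the outcrossing-half
  level at arrival. Aggregating whole landscape halves keeps both sides
  averaged over hundreds of individuals; per-front-deme counts in newly
  founded demes of <10 individuals are dominated by sampling noise and
  produce spurious drops for outcrossers.
* Load-model validation: OLS of per-deme mean fitness on a load proxy.
  Points are taken relative to each replicate's core deme (proxy minus
  core proxy, fitness divided by core fitness), which removes the fixed
  mutational background shared within a replicate but not between
  replicates, and the validation set is the obligate-outcrossing
  replicates: selfing inflates homozygous counts mechanically without a
  matching desk-scale fitness change, so pooling mating systems at this
  scale would compare proxies on a confounded design. On the desk preset
  the recessive model explains substantially more variance than the
  additive one, reproducing the full-scale finding directionally.

## Empirical-side statistics

Inputs are polarized variant tables — VCF with ancestral allele (`INFO/AA`)
and effect class (`INFO/EC`: `neutral`, `deleterious`, `lof`) or an
equivalent per-site TSV — plus a sample-to-population map.

* `Rxy`: with per-site derived frequencies `d^X, d^Y`,
  `L_XnotY = sum_i d_i^X (1 - d_i^Y)` and `Rxy = L_XnotY / L_YnotX`; sites
  unscored in either population are dropped listwise, and a zero
  denominator reports missing, never infinity.
* `Rxy'` divides the category ratio by the same ratio at neutral sites,
  cancelling reference/branch-shortening bias that uniformly thins derived
  calls in one population. `Rxy' > 1` means population X carries an excess
  derived burden in the category.
* Confidence intervals: delete-one block jackknife over 100 contiguous
  genomic blocks (sites in chromosome-then-position order, chromosomes
  concatenated in input order, near-equal site counts per block), the full
  `Rxy'` recomputed per leave-one-out subset; pseudovalues
  `n*theta - (n-1)*theta_(-j)` and a normal-approximation
  `mean ± 1.96 SD/sqrt(n)` interval. Fewer sites than blocks reduces the
  block count with a warning; degenerate pseudovalues are dropped with a
  warning.
* Load counts per individual over deleterious-class sites (additive and
  recessive, missing genotypes skipped), fixation proportion per effect
  class (derived frequency 1 among called genotypes), and windowed
  nucleotide diversity as a ratio of sums (mismatching over comparable
  haplotype pairs, invariant genotyped sites included in the denominator,
  1 Mb windows by default) — missingness shrinks the denominator instead
  of biasing the mean.

## Synthetic cohorts

The generator emulates the structure of an annotated resequencing cohort:
several populations with differing inbreeding levels, polarized derived
alleles, and per-class site counts (defaults 10,000 neutral / 5,000
deleterious / 500 LoF, scaled ~30x down from the size of a typical
annotated resequencing cohort). Per site a base derived frequency is drawn from a `1/q` density
on a configurable interval; per population the frequency is multiplied by
a per-class burden factor (clamped to 1) and genotypes are sampled under
the inbreeding law `P(hom) = q^2 + pqF`, `P(het) = 2pq(1-F)`. A
per-population thinning factor applies binomial thinning to derived allele
calls across all classes alike, emulating reference bias for the
cancellation property. `expected_rxy` integrates the same frequency laws
by seeded Monte-Carlo and serves as the ground truth that `rxy_prime` must
recover.

What the generator deliberately omits: linkage disequilibrium between
sites (sites are independent; LD-aware data comes from the simulator), a
realistic site-frequency spectrum shape beyond the `1/q` family, and
population divergence beyond the burden/thinning factors. Passing tests
on synthetic cohorts therefore demonstrate correctness of the estimators
under known truth, not robustness to every property of real resequencing
data; the block jackknife in particular is validated for coverage on
independent sites, where blocking is conservative.

## Numerical and degenerate-input choices

* Deleterious draws are truncated at `s > -1` by redraw (relevant only for
  the shape-2 sensitivity setting and pathological configurations).
* Fitness factors clamp at zero; a homozygous lethal short-circuits to
  fitness 0.
* `pi`, DFE bins, fixed proportions and load proxies on an empty deme
  report missing rather than raising inside a run.
* A deme whose total fitness is zero, or a lone obligate outcrosser,
  produces no offspring; global extinction ends the run with status
  `extinct`, and a configurable generation cap guards non-completing
  expansions with status `timeout`.
* Per-replicate seeds in the CLI are `base_seed XOR replicate_index`; all
  randomness in a run flows from one `numpy.random.Generator` recorded in
  the manifest.

## Known limitations

* One-dimensional landscapes only; no gradual loss of self-incompatibility
  (the mating shift is a step function in space), no environmental
  heterogeneity or local adaptation.
* Retaining fixed mutations makes absolute mean fitness decline over long
  runs; only relative (within-replicate) fitness comparisons are
  meaningful, and reported fitness levels are sensitive to this choice.
* The mate-choice rule (uniform among others, mates not fitness-weighted)
  and the juvenile-migration event order are one consistent reading of the
  model family this package implements; alternatives (adult migration,
  survival-based regulation) would change colonization-front dynamics
  quantitatively.
* No tree-sequence recording and no linkage-disequilibrium statistics.
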