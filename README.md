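# expansionload

Individual-based simulation of species range expansions with a shift to
self-fertilization, plus the genetic-load and purging statistics used to
compare such simulations with population resequencing data.

## The scientific problem

As a species expands its range, serial founder events at the wavefront let
deleterious variants surf to high frequency — *expansion load* — while
mate scarcity at the front favours self-fertilization. Selfing doubles as
a purging mechanism: by exposing partially recessive deleterious alleles
as homozygotes, it lets selection remove the most severe variants. This
package asks, in a controlled forward simulation, whether purging by
selfing can prevent expansion load, and provides the empirical-side
statistics (Rxy′ burden ratios with block-jackknife intervals,
additive/recessive load counts, per-class fixation proportions, windowed
π) used to look for the same signatures in annotated variant data from
natural populations with contrasting mating systems.

It is written for population geneticists who want to reproduce and extend
the simulation experiment in pure scientific Python, and to run the load
statistics on
their own polarized, effect-annotated VCFs.

## The model in brief

A line of 50 demes under stepping-stone migration (rate *m* = 0.05,
reflecting boundaries). The core deme (*K* = 5000) burns in for 4*N*
generations, then the landscape opens (*K* = 200 per deme, Beverton–Holt
regulation *N′* = *RN*/(1 + *N*/*M*), *M* = *K*/(*R*−1), *R* = 1.2).
Reproduction is fecundity selection — parent *i* leaves
Poisson((*w*<sub>*i*</sub>/Σ*w*) · *N′*) offspring — with probabilistic
selfing (probability σ ∈ {0, 0.5, 0.95, 1}) from deme 25 onward.
Mutations arise at μ = 7×10⁻⁸/bp on a 10 Mb diploid genome
(*r* = 10⁻⁸/bp) in four classes (25% neutral, 0.1% beneficial with
*s* ~ Exp(0.01), 64.9% deleterious with *s* ~ −Exp(0.001), 10% lethal with
*s* = −1), dominance *h* = 0.3 (non-lethal) and 0.02 (lethal); fitness is
multiplicative (1 + *hs* per heterozygous, 1 + *s* per homozygous site).

Rxy′ compares the derived-allele burden of two populations at a site
category (deleterious or loss-of-function), normalized by the same ratio
at neutral sites so reference/branch-shortening bias cancels:
Rxy = Σᵢ d<sup>X</sup>ᵢ(1−d<sup>Y</sup>ᵢ) / Σᵢ d<sup>Y</sup>ᵢ(1−d<sup>X</sup>ᵢ),
Rxy′ = Rxy(category)/Rxy(neutral), with a 100-block contiguous jackknife
for confidence intervals. Rxy′ > 1 means population X carries an excess
derived burden in the category.

See `docs/methods.md` for the full model description, estimator
definitions and design choices.

## Worked example

Simulate a scaled expansion with and without obligate selfing and compare
expansion speed and purging, then recover a constructed burden from a
synthetic cohort:

```python
import numpy as np
from expansionload import make_sim_fixture, run_replicate
from expansionload.simstats import lethal_purging_drop

for sigma in (0.0, 1.0):
    cfg = make_sim_fixture("desk", sigma=sigma, seed=1000)
    traj, state = run_replicate(cfg)
    drop = lethal_purging_drop(traj, cfg.shift_deme)
    print(f"sigma={sigma}: expansion_time={state.expansion_time} "
          f"lethal_drop={100 * drop:.1f}%")
```

```
sigma=0.0: expansion_time=170 lethal_drop=25.0%
sigma=1.0: expansion_time=101 lethal_drop=95.7%
```

The selfing scenario crosses the 10-deme desk landscape in 101 generations
against 170 for obligate outcrossers (reproductive assurance: a lone
selfer can found a deme, a lone outcrosser cannot), and within 200
generations of the mating shift the selfing half of the landscape has lost
~96% of its per-individual lethal alleles, while the outcrossing null
fluctuates near zero drop.

```python
from expansionload import (PopulationSpec, SyntheticCohortConfig,
                           generate_cohort, expected_rxy_prime, rxy_prime)

cfg = SyntheticCohortConfig(
    populations=(PopulationSpec("edge", 12, f_inbreeding=0.3,
                                burden={"deleterious": 1.4}),
                 PopulationSpec("core", 12, f_inbreeding=0.3)),
    sites_per_class={"neutral": 2000, "deleterious": 1000, "lof": 0},
    seed=1)
table = generate_cohort(cfg)
res = rxy_prime(table, "edge", "core", "deleterious")
truth = expected_rxy_prime(cfg, "edge", "core", "deleterious")
print(f"R'={res.R_prime:.3f}  CI=[{res.ci_low:.3f}, {res.ci_high:.3f}]  "
      f"constructed truth={truth:.3f}")
```

```
R'=1.644  CI=[1.509, 1.776]  constructed truth=1.618
```

The cohort was built with a 1.4× deleterious derived-frequency burden in
the "edge" population; the estimator recovers the implied Rxy′ within its
jackknife interval.

## Command line

```bash
expansionload make-config --preset desk --sigma 1 --out desk.yaml
expansionload simulate --config desk.yaml --replicates 10 --seed 7 --out runs/
expansionload stats --trajectory runs/ --out stats.tsv
expansionload figures --trajectory runs/ --out figs/ --shift-deme 5 --k-deme 100
expansionload synth --out cohort/
expansionload rxy --vcf cohort/cohort.vcf --pops cohort/popmap.tsv \
    --category deleterious --blocks 100 --out rxy.tsv
expansionload load-counts --vcf ... ; expansionload fixation --vcf ... ; expansionload pi --vcf ...
```

The `full-scale` preset (`make-config --preset full-scale`) carries the
full-scale study conditions (50 demes, K=5000, 10 Mb genome, 20,000
generation burn-in); 20 replicates per selfing scenario is an overnight
run.

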