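# bridgehead

Invasion-history inference from SNP genotypes: structured-coalescent
simulation of divergence-plus-introduction-wave scenarios and
random-forest approximate Bayesian computation (ABC-RF) for model choice
and parameter estimation.

## The problem

When an invasive population may descend from several genetically
distinct source groups — possibly through repeated introductions — the
question "where did it come from, and in how many waves?" is a
demographic model-choice problem. `bridgehead` was built around the
global invasion of the common monkeyflower (*Mimulus guttatus*) into the
United Kingdom: five native genetic groups (Aleutians **ALE**,
Alaska–British Columbia **AKBC**, **COAST**, **NORTH**, **SOUTH**) with a
fixed divergence history are candidate sources for one or more
introduction waves into a single introduced deme (**UK**). The package
is aimed at population geneticists who want that analysis as a tested,
reusable pipeline, exercisable end-to-end on synthetic data.

## The model and method

All candidate models share the native history (backwards in time:
ALE→AKBC at *t*₁, AKBC→COAST at *t*₂, COAST→ancestral at *t*₃;
SOUTH→NORTH at *t*₅, NORTH→ancestral at *t*₄) and differ only in the UK's
introduction history: a founding origin at *t*₀ₐ plus a set of later
admixture pulses, each with migrant proportion *p*ᵥ ∈ [0.001, 0.999].
Comparison is stepwise: round *k* extends the best (*k*−1)-wave model by
one origin — (6−*k*)·*k* new models per round (5, 8, 9, 8, 5) — while
carrying earlier rounds' best models forward.

For each candidate, unlinked biallelic SNP datasets are simulated under
prior-drawn parameters with a numba-accelerated structured coalescent
(Hardy–Weinberg pairing of haploids into diploids, missing calls injected
at the observed rate), summarised by a fixed statistic vector (per-deme
diversity and heterozygosity, pairwise Weir–Cockerham F_ST and
allele-frequency differences, and the same at regional-group scope), and
fed to a classification random forest. Tree votes select the model; the
posterior probability of the selection follows the abcrf scheme
(regression of the out-of-bag correct-classification indicator);
parameters of the winning scenario are estimated by quantile regression
forests. Upstream, the package provides the genotype side: VCF I/O, the
site/individual/LD filtering cascade, π and F_ST, and PCA + K-means/BIC
genetic-group assignment.

## Worked example

Recover a two-wave introduction history from a synthetic dataset whose
truth is known (UK founded from AKBC 100 generations ago, with a later
30% pulse from NORTH):

```python
import numpy as np
import bridgehead as bh
from bridgehead.coalsim import simulate_dataset
from bridgehead.popgen_stats import summary_vector
from bridgehead.scenarios import Dist

truth = bh.Scenario("TRUTH", "AKBC", ("NORTH",))
params = bh.ScenarioParams(
    ne={"ALE": 2000, "AKBC": 2000, "COAST": 2000, "NORTH": 2000,
        "SOUTH": 2000, "UK": 1000, "ANC": 5000},
    t0a=100.0, wave_times=(50.0,), wave_props=(0.3,),
    splits={"t1": 2000, "t2": 4000, "t3": 8000, "t4": 6000, "t5": 3000},
)
design = bh.SampleConfig(
    haploids={"ALE": 16, "AKBC": 24, "COAST": 12, "NORTH": 22,
              "SOUTH": 16, "UK": 52},
    n_snps=300,
)
gm = simulate_dataset(truth, params, design, 0.1, np.random.default_rng(7))
observed = summary_vector(gm, design.popmap())

prior = bh.PriorSpec(
    ne=Dist("loguniform", 300, 10000),
    t0a=Dist("uniform", 20, 300),
    split=Dist("uniform", 1000, 15000),
)
result = bh.run_search(
    observed, prior, design, sims_per_model=500, max_waves=2,
    n_trees=500, seed=5, missing_profile=0.1,
)
```

which prints (via the loop in `examples`-style code over
`result.rounds`):

```
round 1:
  A1: first=ALE following=-                        votes=86
  A2: first=AKBC following=-                       votes=286 <- promoted
  A3: first=COAST following=-                      votes=66
  A4: first=NORTH following=-                      votes=24
  A5: first=SOUTH following=-                      votes=38
  posterior probability of A2: 1.00
round 2:
  A2: first=AKBC following=-                       votes=3
  B1: first=AKBC following=ALE                     votes=2
  B2: first=AKBC following=COAST                   votes=11
  B3: first=AKBC following=NORTH                   votes=234 <- promoted
  B4: first=AKBC following=SOUTH                   votes=77
  B5: first=ALE following=AKBC                     votes=2
  B6: first=COAST following=AKBC                   votes=4
  B7: first=NORTH following=AKBC                   votes=99
  B8: first=SOUTH following=AKBC                   votes=68
  posterior probability of B3: 0.51
final best: B3: first=AKBC following=NORTH
```

Reading this: of 500 forest trees in round 1, 286 vote for a single
AKBC origin — the true founding source — and the round-2 comparison
(the carried-over single-origin model plus all eight two-wave
extensions) concentrates 234 votes on "AKBC first, then NORTH": the true
history. The single-origin model collapses to 3 votes once two-wave
alternatives exist, and the moderate posterior probability (0.51)
reflects genuine confusability between orderings of the same origin set
(B3 vs B7), a documented property of the design. `bh.export_table1` and
`bh.export_confusion` write these results as CSV tables; the `bridgehead`
command-line tool exposes the same pipeline as subcommands (`filter`,
`stats`, `structure`, `simulate`, `make-synth`, `abc-search`,
`estimate`).

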