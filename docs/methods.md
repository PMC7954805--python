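# Methods

`bridgehead` reconstructs the introduction history of an invasive
population from unlinked biallelic SNP genotypes. It was built around the
global invasion of the common monkeyflower (*Mimulus guttatus*) into the
United Kingdom, where five native genetic groups — Aleutians (ALE),
Alaska–British Columbia (AKBC), Coastal (COAST), North (NORTH) and South
(SOUTH) — are candidate sources for one or more introduction waves into a
single introduced deme (UK). The machinery is generic: any system with a
fixed native divergence history and a single admixed introduced deme fits
the same model space.

## The demographic model

All candidate models share one native divergence history, treated as
known (established from phylogenetic structure, not inferred here).
Backwards in time: ALE lineages join the AKBC lineage at `t1`, AKBC joins
COAST at `t2`, and COAST joins the ancestral population at `t3`; SOUTH
joins NORTH at `t5` and NORTH joins the ancestral population at `t4`.
Validity requires `t1 < t2 < t3` and `t5 < t4`. Each deme *i* has a
constant diploid effective size `Ne_i`.

Candidate models differ only in the introduction history of the UK deme:

* a **founding introduction** from one native group at time `t0a`
  (backwards: all UK lineages relocate to that group at `t0a`);
* optionally up to four **subsequent waves**, each an admixture pulse
  from a further native group at a time `t0w < t0a` with migrant
  proportion `p_w ∈ [0.001, 0.999]` (backwards: each UK lineage moves to
  the wave origin independently with probability `p_w`).

Subsequent waves are unordered among themselves: the model space
distinguishes *which* origin founded the population and *which set*
contributed later pulses, not the order of the pulses. UK `Ne` is
constant after founding (no growth or bottleneck parameters).

## Stepwise model space

With five possible origins, the full space of ordered multi-wave
histories is too large to compare at once, so comparison is stepwise.
Round 1 compares the five single-origin models. Round *k* takes the best
(*k*−1)-wave model's origin set *S* and, for each group *X* ∉ *S*, forms
the candidate set *S* ∪ {*X*} with every choice of first origin — giving
(6−*k*)·*k* new models (5, 8, 9, 8, 5 for *k* = 1…5). Earlier rounds'
best models are carried into each comparison, so the final round holds
nine candidates. The model promoted to seed round *k*+1 is the top-voted
*k*-wave model of its round, even when a carried-over simpler model
out-votes it (both facts are recorded); the final best model is the
overall vote argmax of the last round. Model identifiers follow the
round letter plus enumeration order; in the all-origins round the single
new origin is numbered before the last carried origin (the conventional
numbering for this design).

A caveat the recovery experiments make explicit: with a near-symmetric
admixture history (e.g. a 50/50 two-source mixture), round 1 — which only
contains single-origin models — can prefer an origin *near the root* of
the native topology over either true source, because a deep origin
mimics intermediate affinity to both contributing clades. Greedy stepwise
search then cannot reach the true origin set. Recovery is therefore
demonstrated for an asymmetric, informative history (wave proportion
0.3); symmetric histories are a documented identifiability limit of the
stepwise design itself, not of the implementation.

## Coalescent simulator

Each SNP is an independent genealogy under the continuous-time
approximation of the Wright–Fisher coalescent: within a deme holding *k*
lineages, pairwise coalescence occurs at rate *k*(*k*−1)/(4 `Ne`) per
generation; demographic events (pulses, founding, splits) relocate
lineages at fixed times. The event loop is JIT-compiled with numba; a
study-sized dataset (1435 SNPs × 798 haploids) simulates in ~0.5 s.

**Polymorphism conditioning.** Every simulated site must be segregating.
In the small-mutation-rate limit, conditioning a site on being
polymorphic weights genealogies by total branch length. Placing one
mutation on an *unweighted* genealogy draw instead biases the site
frequency spectrum measurably (≈5% singleton excess at n = 20). The
simulator therefore draws each site's genealogy from the simulated pool
with probability proportional to total branch length and then places one
mutation uniformly along the branches. The resampling has O(1/pool) bias
and negligible between-site dependence; with it, the single-deme SFS
matches the neutral closed form (class *i* frequency ∝ 1/*i*) to
chi-square precision at 20,000 SNPs, and `E[T_MRCA] = 2·Ne` for n = 2.
Tree distributions for a two-deme split model also match msprime
(Kolmogorov–Smirnov) as an independent engine.

Haploid genomes are paired uniformly at random within demes into
diploids (Hardy–Weinberg pairing), and missing calls are injected i.i.d.
per genotype at the observed study's rate (globally, or per deme via a
profile). Sites are unlinked by construction; there is no recombination,
selection, or continuous migration.

## Summary statistics

Observed and simulated datasets are summarised identically by an
explicit, configurable catalogue; what matters for ABC-RF is that both
sides of the comparison use the same vector in the same order, not the
exact membership of any particular legacy statistic set. Per deme:
proportion of polymorphic sites, mean expected heterozygosity 2p(1−p),
mean observed heterozygosity, mean per-site nucleotide diversity
π = 2·c_ref·c_alt/(n(n−1)). Per deme pair: multi-locus Weir–Cockerham
(1984) F_ST (ratio of summed variance components, negative per-locus
components retained; a Hudson estimator is available by flag) and mean
absolute allele-frequency difference. The same statistics are recomputed
at the scope of three regional groups (NORTH+SOUTH; COAST+AKBC+ALE; UK),
giving 72 statistics for the six-deme design. Haploid allele counts
derive from dosages (dosage *d* contributes *d* alternate alleles);
scopes with no data yield NaN sentinels, never silent drops. The
vectorised implementation is verified against a straightforward
scope-by-scope implementation, and the F_ST estimator against an
independently coded nested-ANOVA oracle.

## Genotype filtering

The cascade order is fixed: sites → individuals → LD. Site filters:
non-missing call fraction ≥ 0.75 (boundary inclusive), minor-allele
count ≥ 3 over non-missing haploid calls, biallelic only (multiallelic
records dropped, not split; half-calls are missing). Individual filter:
genotyped fraction ≥ 0.5 over current sites. LD thinning replicates
sliding-window semantics (window 50 SNPs, step 5, r² > 0.5): within each
window pairs are scanned in site order and the later member of an
offending pair is dropped — deterministic, no randomness. r² is the
squared Pearson correlation of dosages over samples non-missing at both
sites; pairs with under two informative samples are skipped. For
genome-wide diversity (π_GENOME), matrices retain invariant sites and
the MAC filter is disabled (`min_mac=0`), so monomorphic loci dilute the
mean as they should.

## Genetic-group assignment

Missing dosages are mean-imputed per site; PCA is a centered (optionally
scaled) eigendecomposition. K-means runs with 100 random-centroid
restarts for each K in 2…15 and the fit is scored with
BIC = n·log(WSS/n) + K·log(n) on the retained component space; the
argmin-K solution is kept. That criterion behaves well on PCA scores
(whose eigenvalue decay makes further splits unprofitable) and on
well-separated high-dimensional clusters; on low-dimensional isotropic
blobs it over-segments, which the tests document. Clusters are named by
majority region label with lexicographic tie-break.

## ABC random forest

Model choice uses a scikit-learn classification forest (1000 trees at
full scale; 500 at desk scale; `sqrt(d)` features per split, unlimited
depth, bootstrap resampling) trained on per-model reference tables.
Votes are per-tree predictions for the observed vector; the selected
model is the vote argmax (lexicographic tie-break, with warning). The
posterior probability of the selected model follows the abcrf scheme: a
regression forest is trained on the out-of-bag indicator "this training
row was classified correctly" and evaluated at the observed vector.
OOB predictions yield the confusion matrix (rows = simulated model,
columns = classified model; row sums conserve per-model counts),
per-model classification error (1 − recall), column-conditional
precision, and the prior error rate.

Parameter estimation trains one regression forest per parameter;
posterior medians and 0.05/0.95 quantiles come from terminal-node
weights (training rows sharing leaves with the observation, weight
1/leaf-occupancy per tree) applied to the weighted empirical
distribution of prior draws. Noiseless identity statistics recover the
truth within 2%; pure-noise statistics return the prior's quantiles —
the behaviour expected when data carry no information about a parameter.

## Priors

The migrant-proportion prior is uniform on [0.001, 0.999]. The remaining
defaults are the package's own choices on invasion timescales, all
overridable: log-uniform `Ne` on [10², 10⁵]; uniform `t0a` on [10, 500]
generations; subsequent wave times uniform on [5, `t0a`]; native split
times uniform on [500, 20000] with orderings imposed by sorting and the
`t0a < min(splits)` constraint enforced by rejection resampling.

## Desk-scale study conditions

Full-scale settings (10,000 simulations per model, 100,000 for parameter
estimation, 1000 trees) are configurable but not the defaults. The
package's own validation runs use:

* **Confusability gradient**: the nine final-round models, 1,000
  simulations per model on a 78-haploid, 120-SNP design with 10%
  missingness, 500 trees. Single-origin OOB error ≈ 5%, rising
  monotonically through the promotion path to ≈ 80–86% for five-wave
  models, with prior error rate ≈ 0.7 — the confusability ordering the
  full-scale analysis reports, compressed by the smaller dataset.
* **Two-wave recovery**: truth = AKBC founding (t0a = 100) + NORTH wave
  (p = 0.3 at t = 50), Ne = 2000 (UK 1000, ancestral 5000), splits
  2000–8000 generations; search over a 142-haploid, 300-SNP design with
  a tight invasion-timescale prior (`Ne` log-uniform [300, 10⁴], `t0a`
  uniform [20, 300], splits uniform [1000, 15000]), 1,000 simulations
  per model, 500 trees, 10% missingness. The acceptance suite requires the true origin
  set to be recovered in at least 80% of 20 replicates.
* **Closed-form checks**: SFS at n = 20 over 20,000 SNPs; T_MRCA over
  5,000 replicates; deep-split F_ST on 5,000 SNPs.

## What the synthetic data do and do not show

The generator emulates the study's shape — six demes with the real group
sizes, 1435 unlinked SNPs, configurable i.i.d. missingness — under a
known truth, so every stage is testable without external data. It does
not emulate GBS read-level error, allele dropout, LD between sites,
population substructure within demes, or non-random missingness.
Passing tests therefore demonstrate the correctness and calibration of
the machinery under the model's own assumptions, not robustness of the
biological conclusions to violations of those assumptions.

## Numerical and degenerate-input choices

Dosages are int8 with −1 as the missing sentinel; positions are 1-based.
F_ST is clipped to [−0.05, 1] for reporting; sites with fewer than two
non-missing haploids are excluded from π and frequency statistics; pair
scopes with no informative site yield NaN. Constant or non-finite
statistic columns are dropped (with warning) before forest training.
Reference-table rows are reproducible in isolation from (seed, row
index); per-scenario simulation seeds derive from the master seed and a
CRC of the scenario id, keeping every derived seed below 2³¹. The
coalescent aborts with an error if no MRCA is reached within 10⁹
generations.

## Known limitations

* Identifiability: near-symmetric admixture defeats greedy stepwise
  search (see above); vote-based promotion can oscillate among origin
  orderings within the correct origin set (B3 vs B7), which is why
  recovery is scored on origin *sets*.
* The statistic catalogue is deliberately compact (72 statistics);
  haplotype-based and LD statistics are out of scope.
* Constant-size demes only; no growth, bottlenecks, or continuous
  migration.
* The BIC clustering criterion inherits the over-segmentation behaviour
  of its family on unstructured low-dimensional data.
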