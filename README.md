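# contactzone

Introgression analysis for contact zones between a self-fertilizing taxon
and its outcrossing sister taxon, built for low-depth reduced-representation
(GBS-style) sequencing data.

When incipient species with divergent mating systems meet, three questions
recur: are early-generation hybrids (F1s, F2s) actually forming, or is the
observed admixture the residue of old backcrossing?  Which taxon do F1s form
on (readable from maternally inherited chloroplast haplotypes)?  And is
admixture within a zone structured by floral phenotypes or by proximity to
the other taxon?  `contactzone` implements the full analysis chain for these
questions as a reusable Python library, plus a mating-system-aware forward
simulator so every stage can be validated on data with known truth.

## What it computes

**Local ancestry from low-depth reads.**  A hidden Markov model along each
individual's SNP map with three diploid ancestry states — homozygous
conspecific (CC), heterozygous (HC), homozygous heterospecific (HH).
Transitions follow a single admixture pulse of proportion *m*, *t*
generations ago: over a map interval of *d* Morgans a haploid copy keeps its
ancestry with probability e^(−t·d) and otherwise redraws from the stationary
distribution (*m*, 1−*m*); the diploid chain is two independent copies
collapsed.  Emissions marginalize the unobserved allele genotype
*g* ∈ {0, 1, 2} over the two reference panels' allele frequencies and a
binomial read-count model with error rate ε:

    P(reads | state) = Σ_g P(g | panels, state) · Binom(alt | depth, (g/2)(1−ε) + (1−g/2)ε)

An outer loop re-feeds the posterior-weighted genome-wide admixture
proportion as *m* until input and output differ by < 0.001, and picks *t*
from a grid by likelihood.

**Admixture summaries.**  Two per-individual estimators: α_all averages the
posterior-weighted score z_i = 0.5·w_HC + w_HH over all sites; α_hc
hard-calls sites whose top posterior exceeds 0.9 and averages x_i ∈
{0, 0.5, 1}.  Triangle-plot coordinates (proportion outcrosser ancestry,
proportion inter-ancestry heterozygous sites) and a configurable hybrid
classification (F1 at (0.5, 1), backcrosses along the edges, parentals in
the corners) come from the high-confidence calls, and chloroplast-capture
tallies from the metadata.

**Modality.**  Gaussian mixtures over K = 1–9 on genomic principal
components and univariate phenotypes, accepting a richer model only when it
lowers BIC (−2·logL + k·log n) by ≥ 10; a one-way ANOVA tests whether the
clusters found differ in admixture.

**Associations.**  Per-zone multiple regressions of percent admixture
(α × 100) on standardized petal size, herkogamy, protandry, flowering time
and binary flower colour, with Type II sums of squares, partial R² (negative
values reported as 0) and VIFs; across zones, a linear mixed model with a
random intercept per contact zone; a reproducible outlier rule
(|studentized residual| > 4 or protandry > Q3 + 3·IQR).

**Spatial structure.**  Nei (1972) standard distance between individuals on
allele dosages and on hard-called ancestry genotypes; seeded Mantel tests
(1000 permutations, one-sided); mean distance to the three nearest
heterospecifics; linear and quadratic admixture-by-distance models compared
by a nested F-test.

**Simulation and I/O.**  A forward simulator (admixture pulse, within-taxon
mating at each taxon's selfing rate, Poisson-crossover recombination,
maternal chloroplasts, ancestry-linked phenotypes, Poisson-depth binomial
reads at 2.7×) plus designed F1/F2/BC/old-admixed cohorts; VCF v4.2 with AD
fields in and out; the standard GBS site/individual filter stack
(missingness, depth quantiles, heterozygosity windows, QUAL/MQ/DP, 200-bp
spacing, panel coverage).

## Worked example

Fit local ancestry for ten simulated individuals with known admixture
(`examples/02_local_ancestry.py`):

```text
 ind   true   fitted   t_hat  iters  converged
   0  0.092   0.096      20      3  True
   1  0.199   0.179      20      3  True
   2  0.086   0.074      20      2  True
   ...
   9  0.000   0.000       5      4  True

correlation fitted vs true alpha: 0.995
```

Each `fitted` value is that genome's posterior-weighted heterospecific
fraction; `t_hat` is the grid-selected pulse age; the EM loop converged in
2–5 iterations for every individual, and fitted admixture tracks truth at
r ≈ 0.995.  The other scripts in `examples/` walk through simulation,
triangle classification (an F1 cohort lands at (0.50, 1.00)), modality
(K = 2 genomically, K = 1 for the fully overlapping trait), the planted
flower-colour association (recovering ≈ 2.2 percent admixture for pink
flowers), spatial statistics, and the end-to-end pipeline with its manifest.

A thin CLI wraps the pipeline: `contactzone simulate|filter|all --config
config.yaml --out outdir`.

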