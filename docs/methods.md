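# Methods

This note documents the models behind `contactzone`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want written down.

## Local-ancestry HMM

### Model

For one individual of a labelled taxon ("conspecific"), the hidden state at
SNP *i* is the diploid ancestry genotype k ∈ {CC, HC, HH}, counting copies
derived from the other taxon ("heterospecific").  The model assumes a
single admixture pulse of proportion *m*, *t* generations before sampling,
followed by free recombination: looking back from the present, the
ancestry of one chromosome copy switches as a Poisson process of rate *t*
per Morgan, and each new tract is heterospecific with probability *m*.
Over a map interval *d* this gives the haploid transition

    P = e^(−t·d) · I + (1 − e^(−t·d)) · 1·(m, 1−m)

which is exactly the t-step product of per-generation matrices with switch
probability 1 − e^(−d) (verified in the test suite).  The diploid chain is
two independent haploid copies with ordered pairs collapsed to unordered
genotypes; the collapse is lumpable, as the two ordered representatives of
HC produce identical rows.  The initial distribution is the stationary one,
((1−m)², 2m(1−m), m²).

Emissions marginalize the unobserved allele genotype g ∈ {0, 1, 2}.  Each
ancestry copy draws its allele from the matching reference panel's alt
frequency (conspecific copies from f_con, heterospecific from f_het); the
read layer is Binomial(alt | depth, (g/2)(1−ε) + (1−g/2)ε) with per-read
error ε.  Sites with zero reads are uninformative but remain in the chain.
Panel frequencies receive a pseudocount of 0.5 per allele class so that no
site is exactly fixed; integrating over panel-count uncertainty is out of
scope.

The forward–backward pass runs in scaled linear space with per-site
emission rescaling, so 10^5-site chains do not underflow; chromosome
boundaries reset the chain to the stationary distribution.  On ≤ 8 sites
the posteriors agree with exhaustive 3^L path enumeration to 1e−8.

### Outer admixture loop

The genome-wide admixture proportion is re-estimated by feeding the
posterior-weighted mean z̄ = mean(0.5·w_HC + w_HH) back in as *m* and
re-running forward–backward until |α_out − α_in| < 0.001 (default
tolerance; `max_iter` 50, group-level α_init 0.05).  The pulse age *t* is
then chosen from the grid {2, 5, 10, 20, 50, 100, 200} by total
log-likelihood at the fitted α, and the α loop re-runs if the grid pick
changed.

This update is a fixed-point iteration, not an exact Baum–Welch M-step:
*m* enters the transition matrices as well as the initial distribution, so
the total log-likelihood is not guaranteed monotone.  In practice the loop
converges in 2–6 iterations and terminal decreases are ≲ 0.03 nats on
log-likelihoods of order 10³; the suite asserts near-monotonicity with a
relative tolerance of 1e−3·|logL|.  Individuals that hit `max_iter` are
flagged, not dropped.

"Conspecific" is always defined by the individual's field taxon label, and
individuals are fitted per taxon/zone group; α is per-individual.

## Admixture summaries

Two estimators per individual: the all-site posterior-weighted mean
(α_all) and the hard-call mean over sites whose top posterior is strictly
greater than 0.9 (α_hc), with x = 0, 0.5, 1 for CC, HC, HH.  At 2.7× depth
with the default panels, ~80–95% of sites clear the 0.9 threshold and the
two estimators correlate at r ≈ 0.99; their absolute gap can still reach
~0.03 for strongly admixed genomes because the sub-threshold remainder
contributes partial weight to α_all only.  Individuals with no confident
site get α_hc = None and are excluded downstream.

Triangle coordinates use only confident sites: x is the mean outcrosser
allele dosage (the state index counts heterospecific copies, so the
mapping flips with the taxon label), y the fraction of sites called HC.
The hybrid classifier is a set of conventional regions: F1 when
|p − 0.5| ≤ 0.1 and H ≥ 0.85; parental corners when the heterospecific
fraction is ≤ 0.05; otherwise recent (backcross/F2-like) versus old
admixture split at H = 0.35 · 2·min(p, 1−p).  The 0.35 factor is chosen
because Hardy–Weinberg-proportioned recent hybrids sit at ~0.5 of the
triangle ceiling, and a boundary at exactly 0.5 would put the F2 centroid
on the boundary; all boundaries are configurable (`HybridBoundaries`) and
echoed in output metadata.  Classification is mirror-symmetric in
p ↔ 1−p.

## Modality

`fit_gmm_path` fits Gaussian mixtures for K = 1…9 (sklearn EM, 20
k-means++ restarts, fixed seed) and walks K upward, accepting K+1 only when
BIC = −2·logL + k·log n falls by at least 10 (lower is better); the walk
stops at the first stall.  Univariate data try equal- and unequal-variance
families, multivariate diagonal and full; the better BIC wins within each
K.  Two stabilizations matter at small n: the covariance regularization is
floored at 1e−3 of the mean feature variance (preventing single-point
collapse), and the genomic pathway reduces the SNP matrix to leading
principal components explaining 90% of variance, capped at 10 components
*and* at one component per ten individuals — without the latter an
unstructured sample hands the mixture enough noise axes to overfit.  The
per-cluster admixture comparison is a one-way fixed-effects ANOVA;
clusters with fewer than two members are excluded with a warning.

## Association models

Per zone and taxon: OLS of α × 100 (percent-of-genome scale) on the four
continuous floral traits, standardized to mean 0 / SD 1 within the model's
data subset, plus flower colour (pink = 1, white = 0) where polymorphic.
Each predictor's Type II F comes from dropping only that predictor:
F = ((SSE_r − SSE_f)/q)/(SSE_f/df_resid); partial R² = (SSE_r − SSE_f)/SSE_r
with negatives reported as 0; VIF_j = 1/(1 − R²_j).  Zero-variance
predictors are dropped with a warning; rank deficiency raises an error
naming the most collinear pair.

The outlier rule — |externally studentized residual| > 4 OR protandry
above Q3 + 3·IQR — is a reproducible surrogate for a visual call; it
refuses to act when more than 10% of observations are flagged, and removed
ids are recorded.  Like any residual rule it can be masked by grouped
outliers; the refusal guard is the backstop.

Across zones, a linear mixed model (REML) with a random intercept per
contact zone; per-predictor Wald χ² on the fixed effects.  Partial R² for
the mixed model is a marginal variance-explained contrast:
R² = Var(Xβ)/(Var(Xβ) + σ²_zone + σ²_resid) computed for the full and the
drop-one refit, difference clipped at 0 (the part-R² convention; stated in
the report metadata).  A singular random-intercept fit falls back to fixed
zone intercepts with a warning.

## Spatial statistics

Nei (1972) standard distance treats each individual as a two-allele
frequency vector per locus (dosages 0/0.5/1):
D = −ln(J_xy / √(J_x·J_y)) with J summed over loci and alleles, computed by
two rank-n matrix products.  Ancestry distance is the same computation on
hard-called ancestry dosages; it is near zero both for two unadmixed
conspecifics and for two individuals admixed at the same sites.  Distances
require complete cases; missing entries raise.

The Mantel test correlates strict lower triangles, permuting one matrix's
rows/columns simultaneously; p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm),
one-sided greater (sidedness is a declared choice), 1000 permutations and
an explicit seed by default.  Geographic distance is haversine on WGS84
lon/lat for field data and Euclidean for the simulator's planar meters;
zones span at most a few km, so planar error is negligible.  The
nearest-heterospecific statistic averages the k = 3 smallest cross-taxon
distances and errors when fewer than k heterospecifics exist.  The
admixture-by-distance model reports the linear slope and F, and the
quadratic term is judged by the nested F-test
F = (SSE₁ − SSE₂)/(SSE₂/(n − 3)).

## Synthetic-data generator

The generator emulates a GBS study of a two-taxon contact zone: divergent
reference panels, spatially clustered georeferenced individuals, old
pulse admixture, maternal chloroplasts, ancestry-linked phenotypes, and
shallow binomial read counts.

Panels: ancestral frequencies uniform on (0.05, 0.95); each taxon's
frequency is a Balding–Nichols Beta draw with divergence F = 0.3 by
default, plus 10% near-fixed differences (0.02 vs 0.98) — a level at
which the HMM has informative emissions, standing in for a recently
diverged but distinguishable pair.  Panel tables carry expected allele
counts (2 × 15 individuals per taxon); panel sampling noise is *not*
modelled.  Sites are ≥ 200 bp apart with Morgan position proportional to
bp (uniform map); the default density is 1000 SNPs/Morgan on a 2 × 0.5
Morgan genome — a desk-scale genome preserving roughly the study-like
per-Morgan information density rather than the full genome size.

Forward mode: a breeding population of 150 plants per taxon (census sizes
below that let drift swamp the pulse signal; the requested individuals are
sampled from the final generation) receives an immigrant pulse at fraction
m = 0.1, then mates within taxon for t = 20 generations at selfing rates
0.95 (selfer) and 0.1 (outcrosser), fathers weighted by an exponential
pollen kernel (20 m scale) over planar positions in two Gaussian clusters
(centres 150 m apart, SD 40 m); meiosis draws Poisson(map length)
crossovers per chromosome; offspring inherit the mother's chloroplast and
position (± 5 m seed dispersal).  Even at breeding size 150, twenty
generations of drift move zone-mean admixture substantially around m —
that is realistic for zones of this size and is why recovery tests use
designed cohorts.

Designed cohorts build exact pedigree classes from explicit meioses (F1,
F2, BC1, BCk) or lay down single-pulse Markov tracts at a per-individual
target admixture (old_admixed); F1s form on the selfer by default, so
backcross lineages carry the selfer chloroplast.  Phenotypes are linear in
true admixture: taxon mean + slope × α + Gaussian noise, with default
separations ≥ 4 SD for petal size, herkogamy and protandry and full
overlap for flowering time; flower colour is Bernoulli (white frequency
0.3) in the selfer only, optionally coupled to admixture
(`color_admixture_effect`, percent per pink plant).  Reads: depth ~
Poisson(2.7) per site×individual, alleles drawn per ancestry copy from the
panel frequencies, alt counts binomial with ε = 0.01.

What passing tests on this generator do *not* show about real data: no
selection against admixed ancestry, no panel sampling noise or panel
misassignment, no allele-sharing through the pedigree at the read level
(alleles are redrawn from panel frequencies given ancestry, so allelic —
as opposed to ancestry — heterozygosity does not track inbreeding), no
reference bias or mapping artefacts, uniform recombination, symmetric
pulse into both taxa, and planar geography.

All draws flow from one seeded generator per stage (`seed`, `seed+1`,
`seed+2` for panels/zone/reads); the same config reproduces byte-identical
output, and the simulator writes its seed into the VCF header.

## Filters

Applied in a fixed, logged order: individual missingness (> 19%), site
missingness (> 25%, computed over retained individuals), scaffold
mean-depth quantiles (outside 5–90%), 1-kb high-heterozygosity windows
(≥ 10 het sites in > 50% of selfer individuals — selfers should be mostly
homozygous, so these flag paralogs/misalignment; windows tile from
position 0), QUAL < 30, MQ < 30, any-sample FMT/DP > 100, biallelic-SNP
restriction, greedy left-to-right 200-bp spacing (leftmost kept), and
panel coverage (≥ 10 of 30 panel individuals with data, both taxa
represented) when a coverage table is supplied.  VCF positions are
1-based; internal intervals are half-open 0-based with conversion at the
boundary.  The stack is idempotent; with < ~20 scaffolds the depth-quantile
rule is aggressive by construction (interpolated quantiles fall between
scaffold means), so small simulations open the band to (0, 1).

## Problem sizes and numerical conventions

Validation cohorts: 50 F1 individuals × 1000 sites and 100 old-admixed
individuals × 2000 sites at depth 2.7× (each fits in well under a minute
on one core); oracle checks run at ≤ 8 sites (path enumeration) and
n ≤ 200 (brute-force distance scans).  Posterior rows are normalized to
1e−9; emissions are rescaled per site before the scaled recursions;
degenerate inputs (no reads at a site, m = 0, constant distance matrices,
zero-variance predictors, clusters of one) are handled explicitly as
documented above.  Ties at the 0.9 posterior threshold do not qualify
(strictly greater).

## Known limitations

Single-pulse transition model only (no multi-pulse or tract-length
inference); no phasing; panel frequencies are point estimates; the hybrid
class boundaries are conventions, not estimates; the mixed-model partial
R² convention is one of several in use; Mantel sidedness is fixed to
"greater"; and the simulator's neutrality means empirical asymmetries in
introgression arise only through mating system and drift, not selection.
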