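# Methods

This note documents the statistical models implemented in `haplopop`, the
design of the synthetic-data generator, the numerical conventions, and the
limitations a user should know about. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Data model

A dataset is an N×L table of haploid allele calls (integer fragment lengths;
`MISSING = -1` in memory, `0`/empty on disk), with a two-level sampling
hierarchy: sample → population → region. Coordinates attach to populations
(all individuals of a population share them); whether field coordinates were
ever recorded per tree is immaterial to every statistic computed here, all
of which operate at population resolution or coarser. Names are
case-sensitive and whitespace-trimmed. All statistics tabulate allele counts
over non-missing calls only, with the per-cell non-missing sample size N_j
carried everywhere.

## Diversity

**Unbiased haploid diversity.** Per (population, locus),
`uh = n/(n−1) · (1 − Σ_a p_a²)` on non-missing calls; cells with n < 2 are
undefined and excluded (with a warning) from the over-loci mean. The
reported standard error is the standard deviation across loci divided by
√L — loci are the replication unit.

**Rarefaction.** The probability that allele a appears in a size-g
subsample drawn without replacement from stratum j is
`Q_ja(g) = 1 − C(N_j − N_ja, g)/C(N_j, g)`; allelic richness is
`α_g = Σ_a Q_ja(g)` and private allelic richness
`π_g = Σ_a Q_ja(g) Π_{k≠j} (1 − Q_ka(g))`. Binomial coefficients are
evaluated through log-gamma differences, never factorials, so N in the
hundreds is exact to double precision; the closed form is verified against
exhaustive subset enumeration for all N_j ≤ 12 and against Monte-Carlo
rarefaction at larger N. Strata with N_j < g at a locus are excluded from
that locus, both as focal and as comparison strata for π_g. The default g
is the largest value every stratum supports at every non-empty locus; at
the emulated study scale this gives g = 8 per population and g ≈ 60–63 per
region (the per-region value moves with the realized missing-data pattern,
which is why a nominal island size of 65 supports a g in the low sixties).

## Mating system

The 1:1 idiomorph test is the textbook goodness-of-fit
`χ² = (n₁ − n₂)²/(n₁ + n₂)` with df = 1 and no continuity correction,
reported alongside the two-sided exact binomial p (preferable when
n₁+n₂ < 20). NONE (amplification failure) and BOTH (a violation of
heterothallism) are counted but excluded from the test. Note that the
uncorrected χ² p and the exact binomial p differ by a continuity term of
order 0.8/√n — they agree to 0.02 only for samples in the thousands — so
both are always reported. No multiple-testing correction is applied across
populations by default (an optional Bonferroni flag exists).

## Multilocus linkage (rBarD)

For each pair of individuals, d_l ∈ {0,1} indicates mismatch at locus l
(pairs missing at l are dropped from that locus — pairwise deletion, which
keeps the per-locus variances additive), and D = Σ_l d_l. With V_O the
variance of D over pairs, var_l the per-locus mismatch variances and
V_E = Σ var_l:

    I_A = V_O/V_E − 1,   r̄_d = (V_O − V_E) / (2 Σ_{l<m} √(var_l var_m)).

Variances use the number-of-pairs denominator. The null permutes each locus
column independently within the population (999 permutations by default)
and p uses the +1 correction. Under missing data the variable number of
scored loci per pair inflates V_O slightly, giving a small positive offset
of r̄_d even for unlinked loci (≈ +0.05–0.1 at the emulated scale — the same
order as published population means for comparable data); the permutation
null shares the missing pattern, so the test stays calibrated (rejection
rate within [0.02, 0.09] at α = 0.05 over 200 null simulations in the
acceptance suite). Clone-correction (collapsing repeated MLGs before the
statistic) is available behind a flag, off by default. MLGs are defined by
exact vector equality; missing is not a wildcard unless requested.

## AMOVA and pairwise F_ST

Distances are per-locus 0/1 allele mismatches (infinite-allele convention;
a stepwise squared-length metric is behind a flag). "Weighted average over
loci" is implemented as: per-locus sums of squares with per-locus pairwise
deletion and per-locus group sizes in the quadratic-form divisors, summed
over loci. Degrees of freedom use the nominal individual counts. Variance
components follow the expected mean squares of the unbalanced three-level
design (coefficients n', n'' from the region/population size composition);
negative components are reported as computed, and percent-of-total uses the
raw total. With one region the design collapses to the two-level AMOVA.
Φ_SC is reported NA only when the among-populations-within-regions stratum
has zero degrees of freedom (every region holds a single population).

Permutation schemes: Φ_ST — individuals across all populations; Φ_SC —
individuals among populations within their region; Φ_CT — whole populations
among regions (coefficients recomputed per permutation since region sizes
change). Defaults: 20,000 permutations for the global AMOVA, 999 for
pairwise F_ST; every p uses the +1 correction. The implementation reduces
each sum of squares to per-group allele counts (so a permutation costs a
bincount per locus rather than an O(N²) distance pass) and is checked
against an explicit pairwise-distance oracle.

## DAPC

Individuals are encoded as 0/1 allele indicators; missing calls are
replaced by the mean frequency of the corresponding allele over the whole
set of individuals, so imputation adds no between-group signal (column
means equal global frequencies exactly). Columns are centred, not scaled.
Cluster discovery runs k-means (50 restarts by default) on the leading PCs
for K = 1..k_max and selects K by `BIC(K) = n·ln(WSS_K/n) + K·ln(n)`, ties
toward smaller K; WSS is floored at 10⁻¹² of the total sum of squares so
that exact cluster recovery (numerically zero residual) lets the K-penalty
decide rather than ranking floating-point dust. The discriminant step fits
an LDA (SVD solver, tolerance 1e-8, robust to singular within-class
scatter) on the retained PCs with K−1 discriminant functions and Gaussian
posterior memberships.

**Retained-PC default.** Cluster discovery keeps the PCs explaining ≥99% of
variance, i.e. essentially all informative components. This follows the
standard DAPC advice (dimension reduction protects the discriminant step,
not k-means) and matters concretely: truncating the PC space concentrates
within-group variance onto few axes, and this BIC then prefers spurious
K > 1 on completely unstructured data. Even with the default, the BIC is
mildly liberal for single samples much larger than ~100 hypervariable
genotypes; at realistic single-population sizes (≤ ~60) K = 1 is selected
essentially always under panmixia, and on fully separated clusters
selection is exact. K-recovery on *weakly* separated noisy clusters is
seed-dependent — a property of this BIC variant, not of the implementation.

## Spatial analyses

Geographic distances are great-circle (haversine, mean Earth radius
6371.0088 km); with sites spanning thousands of km, planar distances on raw
degrees would distort by several percent. GRA centroids are computed on an
azimuthal-equidistant projection about the mean coordinate, giving planar
x/y in km; flags are invariant to translating all coordinates.

**Edwards' chord distance** between strata:
`D_E = √(1 − (1/L) Σ_l Σ_a √(p_1la · p_2la))`, dropping loci where either
stratum has no call (L reduced accordingly). The Mantel statistic is the
Pearson correlation of lower triangles with a simultaneous row/column
permutation null (one-sided for positive association, 999 permutations);
it is cross-checked against scikit-bio's implementation. The distance-pair
KDE uses a Gaussian product kernel with per-axis normal-reference
bandwidths h = σ·n^(−1/6) and a floor for degenerate axes.

**SAShA.** The observed distribution collects the great-circle distances
between every unordered pair of individuals sharing an allele, once per
shared allele per pair, aggregated over loci; the expected (panmictic)
distribution collects all pairs of individuals scored at the locus, once
per locus. The null permutes the allele column among scored individuals
within each locus (1,000 permutations; the expected distribution is
invariant under this permutation by construction, which the suite asserts
exactly). The statistic is the observed mean; the one-sided p tests
under-dispersion (observed < expected). For the restricted-allele subset
the expected side aggregates the all-pairs distances of each locus
represented in the subset, once per locus.

**GRA.** Each allele's carrier centroid is compared with centroids of
n_boot draws of N_a individuals sampled without replacement from all
individuals scored at that locus; the allele is restricted if the observed
centroid falls outside the per-axis 2.5–97.5% interval on at least one
axis (a joint-ellipse rule and with-replacement resampling are options).
An allele carried by every scored individual can never be restricted. The
per-allele false-positive rate of the two-axis rule under random placement
lies between the 5% per-axis level and the ~9.75% independence bound, which
the acceptance suite verifies. No multiple-testing correction is applied,
mirroring standard usage of the method.

## Synthetic-data generator

The generator is frequency-level (a Balding–Nichols-style compound
Dirichlet hierarchy), not coalescent: the analyses only ever see
frequencies and genotypes, and the F-model gives direct control of
F_ST-scale differentiation. Per locus: ancestral frequencies
~ Dirichlet(c·1) (c = 0.8 at the emulated scale, giving realistically
uneven hypervariable loci); region pools ~ compound around the ancestral
vector with parameter `F_region`; population pools likewise with `F_pop`.
Then, in order:

1. **Isolation by distance** — a Gaussian random field, spatially
   correlated as exp(−d/`ibd_range_km`) across populations, perturbs
   per-allele log frequencies; its sd (`ibd_decay`) is scaled up on rare
   alleles, reflecting that new variants stay geographically local. An
   isotropic field (rather than neighbour smoothing or a one-dimensional
   cline, both of which either homogenize or waste signal on cross-axis
   pairs) makes genetic divergence grow smoothly with true distance in
   every direction.
2. **Founder truncation** — a population with `founder_k` keeps only the
   first k alleles of a per-region colonisation order (Gumbel top-k with
   survival odds ∝ frequency^`founder_bias`), then renormalises. One order
   per region means sister islands carry nested founder subsets — a single
   colonisation wave — so pooled island richness stays truncated while
   island–island differentiation stays near zero; the frequency bias means
   the rare tail is lost first, which is what depresses rarefied richness
   without inflating F_ST.
3. **Migration admixture** — directed region→region rates mix each
   population with the source region pools (mainland→island only at the
   emulated scale: colonisation is one-way).

Individuals are drawn i.i.d. from their population frequencies; corruption
is applied in the fixed order clone → linkage → missingness (the order is
part of the model: it defines the nulls the analyses see). Clonality copies
a previous individual's full genotype; linkage copies the allele
frequency-rank of the previous locus with probability `linkage_rho`;
missingness is i.i.d. Bernoulli per call. Mating types are
Bernoulli(`mat_ratio`) with an amplification-failure probability
`mat_none_rate`. One seeded generator stream drives every draw, so a config
is byte-reproducible, and a `TruthRecord` retains all latent frequencies,
founder subsets, the clone map and the missing mask for oracle tests.

**Emulated study scale.** `paper_scale_config()` encodes the sampling
design being emulated: 11 populations (3 island with `founder_k = 12`, 8
mainland) in 2 regions, sizes (25, 20, 20, 20, 8, 21, 17, 29, 25, 14, 21)
totalling 220 (mean 20), 8 loci with inventories (16, 22, 25, 26, 27, 28,
46, 30) — range 16–46, total 220 alleles — 3% missing calls, mat_ratio 0.5
with 7% amplification failure, and coordinates approximating the sampled
localities (span ≈ 3,000 km). The differentiation knobs
(`F_region = F_pop = 0.004`, migration 0.12, `ibd_decay = 0.5`, range
1,000 km, founder bias 4) were calibrated once so that one realisation
reproduces the study system's qualitative signature set: regional island
richness below the mainland, all pairwise F_ST below 0.05 (the published
range tops out near 0.02, against an estimator noise floor of ~0.01–0.03
for the smallest samples), a positive Mantel correlation, and a
non-significant near-1:1 mating-type ratio.

**What the generator does not emulate.** No stepwise mutation model (allele
labels are exchangeable; fragment-length adjacency carries no signal — one
reason the stepwise AMOVA metric is only a flag); no coalescent genealogy,
so linkage between loci exists only through the explicit `linkage_rho`
mechanism; no within-population spatial structure (individuals of a
population are exchangeable and co-located); mating type is independent of
the genotype. Passing tests therefore demonstrate correctness of the
statistics and calibration of their nulls under these idealisations — not
that real data meet them. One tension is worth naming: a printed global
Φ_ST ≈ 0.08 alongside pairwise F_ST ≤ 0.023 is not jointly attainable in
any frequency-model parameterisation we examined; the generator favours the
pairwise range (its global Φ_ST comes out ≈ 0.02–0.03), keeping "weak
differentiation" qualitatively intact. Similarly, a strong Mantel
correlation with pairwise F_ST this small sits at the edge of what the
design (8–29 haploids per population) can resolve — the per-seed
probability of a positive observed correlation is about 0.9 at these
settings — so the end-to-end checks treat the Mantel sign and the F_ST
ceiling as properties of the generating scenario verified over several
seeds, not of every realisation.

## Problem sizes and determinism

Default permutation counts are 999 (rBarD, pairwise F_ST, Mantel), 20,000
(global AMOVA), 1,000 (SAShA, GRA bootstrap); the test suite and the
acceptance script scale these to 99–1,000, which changes p-value
granularity but none of the point statistics. The pipeline derives one
sub-seed per stage by hashing the stage name with the global seed, so stage
results are stable regardless of execution order, and `report.json` is
byte-identical across reruns of the same config and seed.
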