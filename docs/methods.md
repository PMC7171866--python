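# Methods

This note documents the models behind `assemblage`, the parameters that
matter, the design decisions that were genuinely open, and what the
synthetic-data validation does and does not demonstrate.

## Process inference

### βMNTD and βNTI

For communities *k*, *m* with within-sample relative abundances *f* and
cophenetic taxon distances Δ:

    βMNTD(k,m) = ½ [ Σ_{i∈k} f_ik · min_{j∈m} Δ_ij  +  Σ_{j∈m} f_jm · min_{i∈k} Δ_ji ]

The nearest-taxon search runs over the *other* community's present taxa and
includes the focal taxon itself when shared (Δ = 0), so identical communities
score exactly zero. Taxa absent from a sample are excluded from that sample's
sum; the unweighted variant replaces *f* by 1/richness.

The null model shuffles taxon identities across the tips of the phylogeny.
One permutation per randomization is applied to the whole cophenetic matrix
and reused for all pairs (matrix-level shuffling): this matches the common
reference behaviour, keeps the cost at O(n_null × pairwise βMNTD), and makes
the null draws of different pairs share randomness — irrelevant for per-pair
inference, relevant only if one were to model correlations between pairs.
βNTI is the standardized effect size with the sample (ddof = 1) null standard
deviation; 999 randomizations by default. An exhaustive mode enumerates all
tip permutations for small trees and is used as a cross-check. Pairs whose
null distribution has zero spread (e.g. star phylogenies) get βNTI = NaN and
are excluded from summaries but counted.

|βNTI| > 2 is the conventional significance cut: +2 flags heterogeneous
selection (phylogenetic turnover above chance), −2 homogeneous selection.

### Raup–Crick on Bray-Curtis

For each pair, null communities are reassembled from the regional (all-sample)
pool: each community's observed richness is drawn without replacement with
probability proportional to occupancy (implemented by Gumbel top-k, which is
equivalent to sequential weighted sampling), every drawn taxon receives one
read, and the remaining reads are allocated multinomially by regional
relative abundance. Bray-Curtis between the two null communities is compared
with the observed value:

    RC_raw = [#(null < obs) + 0.5·#(null = obs)] / n_null
    RC_bray = 2 (RC_raw − ½) ∈ [−1, 1]

Comparisons are exact float comparisons — at a common rarefaction depth the
discrete count space makes exact ties meaningful, and they carry weight 0.5.
Default 9999 randomizations. Occupancy and abundance weights default to the
table's own regional pool but can be overridden, which is how the calibration
tests feed the null its own output. The pairwise-pool variant (weights from
the two samples only) is expressible through the same override.

### Classification

Selection is judged first: βNTI > +2 → heterogeneous selection, < −2 →
homogeneous selection. Only the remaining pairs consult RC_bray: > +0.95 →
dispersal limitation, < −0.95 → homogenising dispersal, otherwise drift.
Fractions are reported over classified pairs and always sum to one.

### Phylogenetic signal

A taxon's niche value is the abundance-weighted mean of an environmental
variable over the samples it occurs in (a taxon seen once inherits that
sample's value; unobserved taxa are dropped). The correlogram statistic per
phylogenetic-distance class is the negative Pearson correlation between class
membership and niche distance over taxon pairs, so positive values mean
closer relatives have more similar niches. p-values are two-sided
permutation tests with progressive Holm correction (class *k* corrected
against classes 1..*k*). Signal is tested one variable at a time
(temperature and fluorescence are the usual candidates); multivariate niche
distance is out of scope.

## Interaction-adjusted similarity

TINA_w between samples A and B with relative abundances *p* and association
kernel K:

    s(A,B) = p_Aᵀ K p_B / √( (p_Aᵀ K p_A)(p_Bᵀ K p_B) )

This self-similarity-normalized (generalized cosine) form reproduces the
three analytic anchors exactly: identical communities → 1, disjoint
communities with neutral association (a = 0.5) → 0.5, disjoint with complete
avoidance (a = 0) → 0. With the identity kernel it reduces to the cosine
similarity of relative-abundance vectors.

The default kernel is the Pearson correlation of relative-abundance profiles
rescaled as a = (ρ+1)/2 (Spearman optional). Correlation matrices are
positive semidefinite, so the cosine stays in [0, 1]; arbitrary user kernels
need not be PSD and the cosine is clipped to the unit interval. Zero-variance
taxa get the neutral association 0.5 rather than being dropped, keeping the
taxon set aligned with the other metrics. A compositionality-robust
estimator (SparCC-style) is deliberately not re-implemented; the estimator
tag is recorded in output headers so results are labelled with their kernel.
PINA is the same cosine with K = 1 − Δ/max(Δ).

## β-diversity and spatial statistics

* **Bray-Curtis** is computed on counts; at a common rarefaction depth this
  equals the relative-abundance version (a flag forces the latter).
* **Generalized UniFrac** follows the branch-proportion formulation with
  moderation exponent α on branch weights; α = 0.5 by default (the usual
  compromise between sensitivity to abundant and rare lineages), and α = 1
  equals normalized weighted UniFrac, which is the cross-check oracle.
* **Sequential β-diversity** compares each station with its immediate
  predecessor in cruise order; the abrupt-change flag is strictly greater
  than the threshold. 0.8 (picoeukaryotes) and 0.7 (prokaryotes) are
  documented presets, not constants.
* **Mantel** tests are one-sided (positive association) with the add-one
  permutation rule; Spearman is available for rank-based reports.
  **Correlograms** use indicator-membership classes (default 1000 km), with
  the sign convention that positive r at short distance means distance decay.
* **PERMANOVA** partitions the Gower-centred −½D² matrix with sequential
  (Type I) sums of squares in the user-given term order — term order is part
  of the model. Permutations are free (unrestricted); strata are out of
  scope. Marginal (Type III) SS would be a natural extension.
* **Variance partitioning** embeds the dissimilarity by principal
  coordinates (positive-eigenvalue axes), fits each predictor set by
  least squares, and reports Ezekiel-adjusted R² combined by
  inclusion–exclusion. Adjusted R² can be slightly negative; fractions are
  reported as-is.
* **LCBD** uses the Hellinger transform; values are each sample's share of
  the total sum of squares and sum to one by construction. Significance
  permutes each species independently across samples, one-sided.

## Synthetic metacommunity generator

The generator is this package's model, designed so that each assembly
process can be switched on with known strength; it emulates the statistical
structure the inference assumes rather than any particular ocean.

* **Phylogeny**: Yule (pure-birth) tree, scaled to unit root-to-tip depth.
* **Niches**: Brownian motion along branches, σ_BM = 5 trait units per unit
  branch length by default, root at 22.5 — chosen so tip optima span a
  surface-ocean-like temperature range (≈ 12–33 °C) when the gradient runs
  15–30 °C.
* **Stations**: a 1-D equatorial transect, default 20 stations every 500 km
  (a cruise-track spacing), with linear / two-level step / constant
  environmental gradients plus Gaussian noise.
* **Regional pool**: Fisher log-series abundances (p = 0.9999), i.e. many
  rare taxa, matching the strongly uneven rank-abundance curves of marine
  amplicon surveys; uniform optional.
* **Selection**: sampling weight ∝ exp(−s(E−μ)²/2τ²). Only τ/√s (the
  effective niche width) shapes the filter; s = 0 is neutral.
* **Dispersal**: weight × exp(−d(k, home_i)/λ) with one home station per
  taxon (drawn uniformly). λ = ∞ removes the kernel. A single home per
  taxon is the simplest structure that produces spatial taxon turnover and
  hence distance decay.
* **Drift**: expected local relative abundances are perturbed by a Dirichlet
  draw with concentration I·p (Sloan-type neutral sampling), where I is the
  effective number of immigrating individuals; var(p_loc) ≈ p(1−p)/(I+1).
  This term is essential: communities that *multinomially resample a shared
  pool* are more similar than random reassembly at every realistic community
  size, and the Raup–Crick null correctly reads that as homogenising
  dispersal, not drift. Ecological drift — abundances wandering away from
  the common expectation — requires finite immigration. Default I = 1000,
  within the range of neutral-model fits to marine bacterioplankton.
* **Sampling**: one multinomial draw of J (default 10⁴) reads per station.

### Regime presets

The presets name the process they are constructed to make dominant:

| regime | selection s | niche breadth τ | gradient | λ (km) | I |
|---|---|---|---|---|---|
| drift | 0 | – | linear (irrelevant) | ∞ | 1000 |
| homogeneous_selection | 20 | 2 | constant, no noise | ∞ | 100 |
| heterogeneous_selection | 20 | 2 | linear 15–30 | ∞ | 1000 |
| dispersal_limitation | 0 | – | – | 500 | 1000 |

The homogeneous-selection preset uses stronger drift (I = 100): under a
uniform environment the compositional turnover that βNTI standardizes is
drift-generated, and the regime's signature is precisely that this turnover
is phylogenetically constrained. Recovery of this regime is intrinsically
the weakest — per-pair βNTI concentrates just above the −2 cut, and a single
tree realization can even lean the other way — so validation pools pairs over
replicate metacommunities; the pooled dominance of homogeneous over
heterogeneous calls is the regime property being asserted, while the modal
process overall remains drift by construction.

### What the synthetic validation does not show

The generator draws communities independently given the regime parameters;
it has no temporal dynamics, speciation, ocean circulation, biotic
interactions, or covarying environmental fields, and its "environment" is a
single scalar. Passing recovery tests therefore demonstrates that the
inference machinery responds correctly to each isolated mechanism at survey
scale, not that real-ocean attributions are unbiased — in real data the
processes co-occur, covary with space and are filtered through primer and
OTU-delineation choices that the generator does not model.

## Numerical choices

* Problem sizes in the validation suite: regime recovery runs at 20 stations
  × 300 taxa and J = 10⁴ with 999 randomizations for both null models; null
  calibrations use ≈ 400–800 pairs at 999 randomizations; these sizes keep
  the whole suite in the ten-minute range on one core while leaving
  Monte-Carlo error well inside the asserted tolerances.
* Rarefaction uses multivariate hypergeometric sampling (without
  replacement); samples below depth are dropped, not resampled.
* All stochastic operations take explicit integer seeds; pipeline stages
  derive child seeds from one master seed via `numpy.random.SeedSequence`,
  so reruns are bit-identical (output headers record version, seed and a
  parameter hash, no timestamps).
* Strict inequalities at every published threshold (abundance 0.1%/0.001%,
  occupancy 80%/20%, |βNTI| 2, RC 0.95, abrupt-change 0.8/0.7); abundance
  percentages are rounded to 12 decimals before comparison so exact-boundary
  cases are not tipped by float accumulation.
* Degenerate inputs fail loudly: empty communities, constant niche values,
  zero-variance distance matrices, all-identical LCBD tables, trees without
  branch lengths (unless explicitly allowed), basal polytomies (unless
  midpoint rooting is requested).

## Known limitations

* βNTI's homogeneous-selection sensitivity at a few hundred taxa is limited
  (see above); real surveys with 10³–10⁴ taxa and deeply structured rRNA
  trees give the statistic more room.
* The RC null uses the regional pool; no γ-diversity correction across
  subregions.
* PERMANOVA offers sequential SS only, and permutations are unrestricted.
* The Mantel correlogram reports NaN for classes with fewer than two pairs
  or constant membership (e.g. a class width exceeding the maximal
  distance).
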