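# Methods

This note documents the statistical models, estimator conventions, the
synthetic-data generator, and the numerical and design choices behind
`ssrpop`. It states only what the package itself computes; every number
quoted here is reproduced by the test suite or the worked example.

## The data model

A panel is N accessions × L codominant SSR loci, two allele fragment
sizes (bp) per call, with a both-or-neither missingness rule: a half-call
(one allele present) carries no usable genotype information for a
codominant diploid marker and is coerced to fully missing at parse time
(counted and logged, never fatal). Accessions missing at every locus can
be dropped as an explicit analysis-time policy (`drop_all_missing`).
Phenotypes are 12 integer-coded spike/grain descriptors, each with a fixed
ordered universe of permitted classes; metadata adds landrace, region,
climate stage and optional decimal-degree coordinates, with the
region→climate mapping validated when both are present.

## Phenotypic diversity

For each trait and stratum, H = −Σ p ln p over the observed class
frequencies (natural log throughout) and H′ = H / ln S. **S defaults to
the number of classes observed in the whole collection for that trait**,
not the descriptor's theoretical universe: only under observed-class
normalisation can a trait that segregates all its realised classes evenly
reach H′ = 1, which is how near-unity per-trait values arise in practice.
The theoretical-universe normalisation is available via
`s_mode="theoretical"`. H′ is defined 0 when S ≤ 1 or a single class is
observed. Trait PCA is an eigen-decomposition of the covariance of the
centred integer codes (correlation behind `scale=True`; the choice matters
little because all 12 descriptors live on comparable 5-class scales).
Cluster trait means are Σ(n·Cᵢ)/N; mean separation uses one-way ANOVA on
the codes (treating ordinal classes as numeric; Kruskal-Wallis behind
`method="kruskal"`) with Tukey HSD pairwise comparisons at 5% rendered as
compact letter displays.

## Marker statistics

All frequency-based indices use allele frequencies over non-missing
copies. He = 1 − Σp² is the plain (uncorrected) expected heterozygosity;
PIC = 1 − Σf² is numerically identical but conventionally computed on the
pooled collection, with markers at PIC ≥ 0.5 flagged informative.
Fis = (He − Ho)/He (undefined and reported missing when He = 0; negative
values indicate heterozygote excess and are reported as-is). Per-locus
Fst is the Gst form (Ht − H̄s)/Ht with Ht computed from the unweighted
mean of stratum frequency vectors; a multiallelic Weir-Cockerham theta is
provided separately (`weir_cockerham_fst`) and is the cross-check used to
calibrate the simulator. Gene flow is the island-model approximation
Nm = 0.25(1 − Fst)/Fst applied to the across-loci mean Fst.

MLG identification compares unordered allele pairs per locus; by default a
missing locus is a wildcard and accessions are grouped by the transitive
closure of pairwise matches. A strict mode (both present and equal at
every locus) is available. The genotype accumulation curve draws, per
permutation, a random locus order and counts MLGs along nested prefixes —
sampling without replacement while guaranteeing a monotone per-permutation
curve. The curve defaults to strict matching: under the wildcard rule an
accession missing one locus of a small subset matches everything and
transitively merges unrelated genotypes, which destroys monotonicity; on
missing-free panels the policies coincide. Private alleles occur in
exactly one stratum; diagnostic alleles exceed 70% frequency in one
stratum while staying below 30% in every other.

## Admixture model

The sampler implements the no-linkage admixture model with independent
allele-frequency priors: cluster frequencies p_kl ~ Dirichlet(λ) (λ = 1),
ancestry vectors q_i ~ Dirichlet(α), and a latent origin z for every
observed allele copy. One sweep updates z ~ Categorical(q_ik · p_k,l,a),
then p from Dirichlet(λ + counts) and q from Dirichlet(α + counts);
missing copies contribute nothing. α is fixed at 1.0 by default; the
optional Metropolis update (normal proposal, sd 0.05, uniform prior on
(0, 10)) mirrors the reference implementation's inferred-α mode and is
needed whenever near-degenerate ancestry must be expressed — with α = 1
and 2L = 20 observed copies the posterior mean of max q is bounded by
21/22 ≈ 0.954 regardless of the data.

The marginal likelihood per K is estimated from the post-burn-in
log-likelihood trace as mean(lnL) − var(lnL)/2, and
ΔK = |L̄(K+1) − 2L̄(K) + L̄(K−1)| / sd(L(K)) over independent runs; the
run with maximum lnP(D) at the selected K is retained. Accessions are
assigned to their majority cluster when max q strictly exceeds 0.75, else
ADMIXED. The pipeline runs the sampler on one representative per MLG and
propagates memberships to duplicates.

The inner loop is a numba-compiled kernel (~0.2 ms per sweep at N = 150,
L = 10, K = 5), which keeps the desk-scale battery (burn-in 2000, 5000
sampling sweeps, 5 runs per K over K = 1..5) at roughly half a minute per
panel; production-scale settings (10⁵ + 10⁵, 10 runs) remain the
configuration default.

**Known behaviour of ΔK.** ΔK carries the well-documented bias towards
K = 2: the curvature of L(K) is usually largest at the first split. On
synthetic panels it recovers the generative K reliably only when loci are
informative enough — at the emulated panel's profile (10 loci, ~10
alleles per locus, divergence Fst ≈ 0.5) the recovery test passes at
≥ 8/10 batteries, whereas weakly divergent or allele-poor panels tip the
statistic to K = 2 even when mean lnP(D) peaks at the true K.

## Distances, networks, Mantel

Nei's (1972) standard distance pools the identity sums across loci before
the ratio, D = −ln(ΣJxy / √(ΣJx · ΣJy)); the per-locus-averaged variant is
behind a flag. Disjoint supports give D = ∞ with a warning. Bruvo's
distance converts sizes to repeat counts (÷ repeat unit), scores allele
pairs as 1 − 2^(−|x−y|), and takes the minimum over the two diploid
matchings, averaging over loci comparable in both genotypes (missing loci
dropped — the fixed-ploidy "exclusive" policy). The codominant squared
genotypic distance is half the squared Euclidean distance between
allele-count vectors per locus, summed and rescaled by L/(comparable
loci); the rescaling trades strict metricity for comparability under
missing data (the triangle-inequality property is exact on complete data).

The minimum spanning network is a Kruskal MST plus every non-tree edge
whose weight ties (within 1e-12, exact for these dyadic-rational
distances) the maximum-weight edge on the tree path between its
endpoints. Geographic distance is the haversine great circle in km
(R = 6371.0088), transformed ln(1 + d) for Mantel use. The Mantel test is
one-sided for positive association: r is the Pearson correlation of
lower-triangle entries and p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm) under
simultaneous row/column permutation.

## AMOVA

One level, from squared distances: SS_total = Σ_{i<j} d²/N,
SS_within = Σ_g Σ_{i<j∈g} d²/n_g, df = (k−1, N−k); σ²_within = MS_within,
σ²_among = (MS_among − MS_within)/n₀ with the unbalanced-design
n₀ = (N − Σn_g²/N)/(k−1). Φ = σ²_among/(σ²_among + σ²_within), with a
negative among-component truncated to 0 for Φ and the percentage column
but reported raw in `est_var_raw`. Significance comes from whole-label
permutation (the only exchangeable unit at one level), one-sided on Φ.
The pipeline excludes ADMIXED accessions from the genetic-group
stratification before testing.

## The synthetic generator

The generator emulates a gene-bank landrace panel: defaults are 11 groups
totalling 302 accessions (group sizes patterned on an uneven real
collection), 10 loci with 4–16 alleles, divergence Fst 0.5, 10 selfing
generations, 13.6% admixed accessions, 5% missing calls, and five
region centres in central/southern Tunisia with ~0.12° coordinate
scatter. Divergence uses the Balding-Nichols construction — population
frequencies ~ Dirichlet(p_anc(1 − F)/F) around symmetric-Dirichlet
ancestral frequencies — the simplest one-parameter model whose expected
differentiation equals F. Selfing is mechanistic rather than a direct
Fis setting: each heterozygous locus resolves to a random homozygote with
probability 1/2 per generation, which reproduces both Fis ≈ 1 and the
duplicate-MLG redundancy of a selfing panel. Admixed accessions draw
two-parent ancestry ~ Dirichlet(1, 1) over a random population pair.
Traits draw, per population and trait, a class distribution from a
symmetric Dirichlet with parameter `trait_concentration` (default 0.3,
giving landrace-like near-homogeneity within groups while keeping
collection-level polymorphism); this knob is a free parameter, not an
estimate — real data constrain the genotype-trait association only
loosely. All randomness flows from `cfg.seed`.

What the generator does **not** emulate: mutation, linkage between loci,
null alleles and scoring error, hierarchical population structure, and
realistic geographic sampling density. Passing tests therefore
demonstrate correctness of the estimators and recoverability under the
stated generative model, not performance guarantees on any particular
real collection.

## Test and acceptance problem sizes

The acceptance checks use panels the package can analyse in minutes on
one core: recovery batteries at N = 150, 10 loci, 10 alleles/locus,
Fst = 0.5, desk-scale MCMC; AMOVA/Mantel calibrations at N = 30–60 with
199–999 permutations; the MLG census fixture at 302 accessions/188
genotypes. Production-scale MCMC settings are exposed but not exercised
by the default suite.

## Reproducibility

Every pipeline stage derives its seed from the root seed by stable
hashing of the stage name (CRC32 mixed with a Knuth multiplier, reduced
mod 2³¹−1), so stages re-run individually reproduce the full-run outputs
byte-for-byte. The battery derives per-(K, run) seeds the same way.
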