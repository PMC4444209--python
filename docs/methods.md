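# Methods

`admixqtl` implements an in-situ quantitative-genetic workflow for a pair of
hybridising tree species (*Populus alba* × *P. tremula* and their natural
hybrids serve as the motivating system). The package covers five analyses —
ancestry inference, admixture mapping, heritability, selection signals, and
phenotype structure — plus a synthetic-data generator that reproduces the
statistical structure those analyses assume. This note records the models,
the defaults and why, the numerical choices, and the limits of what the
synthetic validation shows.

Orientation is fixed everywhere: admixture proportion Q is the *P. alba*
genome fraction (1 = pure alba, 0 = pure tremula), and locus-specific
ancestry (LSA) is coded 0 (tremula/tremula), 0.5 (interspecific
heterozygote), 1 (alba/alba).

## Ancestry inference (`admixqtl.ancestry`)

**Model.** Loci are treated as independent given Q, and each of the two
allele copies at a locus derives from the alba gene pool with probability Q:

    L(Q) = ∏_loci ∏_copies [ Q·p_alba(a) + (1−Q)·p_trem(a) ].

Q is the 1-D bounded maximiser of this likelihood (Brent on [0,1], with an
explicit boundary check because the optimum is frequently at 0 or 1 for
parental trees). LSA is the MAP state of a per-locus three-state posterior
with binomial-ancestry prior {(1−Q)², 2Q(1−Q), Q²} and genotype likelihoods
from the parental allele-frequency vectors; ties resolve to the lowest
state, a deterministic convention.

**Zero-frequency smoothing.** An allele unseen in a parental reference
sample of n diploids is rare, not impossible; frequencies are floored at
ε = 1/(2n+1) (default n = 50) and renormalised. A consequence worth knowing:
even at a fully diagnostic locus the heterozygote posterior is ≈0.98 rather
than 1; it converges to 1 as the assumed parental sample grows.

**Missing genotypes** drop out of the Q likelihood and leave the LSA
posterior equal to its prior.

**Taxon delimitation** thresholds Q with the open interval as "hybrid"
(Q exactly at a threshold is parental-like). Two named presets exist because
different analyses use different delimitations: `mantel_hybrids` (0.01,
0.99) for the hybrid-only genotype–phenotype correlations and
`network_hybrids` (0.05, 0.95) for the admixed-tree correlation networks.

**Known limitation.** This is a per-locus estimator with no sharing of
information along the genome. MAP calls at weakly informative (low-delta)
loci default to the prior mode, which is "heterozygote" for trees with
Q between roughly 1/3 and 2/3. Downstream consumers must account for this
(see heterozygote-excess below).

## Admixture mapping (`admixqtl.mapping`)

**Residualisation.** Each trait is reduced to standardized residuals from a
one-way fixed-effects ANOVA on sampling locality: subtract the locality
mean, divide by the root mean squared error (RSS/(n−k)). Mapping is
therefore invariant to affine rescaling of raw phenotypes, and among-zone
differences cannot masquerade as QTL.

**Single-locus models.** For each trait × locus, three Gaussian linear
models: null (intercept), additive (y ~ lsa), dominant (y ~ lsa +
1{lsa=0.5}); the dominant model is the additive term plus a heterozygosity
indicator, so its third coefficient is the heterozygote deviation d.
Log-likelihoods use the maximum-likelihood residual variance, and AIC counts
that variance as a parameter: AIC = n·log(2πRSS/n) + n + 2(p+1). A locus
whose ancestry is constant in the sample is skipped and logged. Individuals
missing either value are dropped pairwise, and the null is refit on the same
subset so AICs stay comparable.

**Screening.** A locus is a candidate for a trait when the better of the two
ancestry models improves on the null by at least 4 AIC units (inclusive at
exactly 4). The threshold is an AIC difference against the intercept-only
model; 4 units corresponds to a relative likelihood of e² ≈ 7.4 and yields a
per-locus null candidate rate of ~2.5% at n = 260 (measured by Monte-Carlo,
consistent with the χ² tail mixture of the two tests).

**Model selection.** Candidates enter forward selection (repeatedly add the
candidate, with its winning single-locus coding, that lowers AIC most, while
the drop is ≥ 4) then backward elimination (repeatedly remove the locus
whose removal raises AIC least, while that rise is < 4). Ties break on
(lower AIC, candidate order); exact duplicate ancestry columns are collapsed
to the first and logged. The forward/backward threshold deliberately reuses
the screening threshold; both are configurable.

**Variance explained.** The final model is summarised by the
likelihood-ratio pseudo-R²,
R²_LR = 1 − exp(−(2/n)(logL_model − logL_null)), which for Gaussian ML fits
equals 1 − RSS_model/RSS_null. A rescaled variant (divided by its maximum
attainable value 1 − exp((2/n)·logL_null)) is also emitted because the two
conventions coexist in the literature; the unrescaled value is primary.

**Gene action.** From the three ancestry-class means with a = (m1−m0)/2 and
d = m05 − (m1+m0)/2: over-dominant if the heterozygote mean exceeds both
homozygote means by more than τ, under-dominant if below both, dominant
toward the species whose homozygote the heterozygote matches within τ,
additive otherwise. τ defaults to 0.5·SE(m05), so the classification
sharpens with sample size.

**Caveat that is a property of the design, not a bug.** In an admixed panel
every locus's ancestry is correlated with genome-wide Q, so a true QTL
anywhere lifts the apparent signal at many loci ("admixture
linkage disequilibrium"). Forward/backward selection is the defence the
workflow provides; with markers of moderate delta the retained set still
includes structure-driven false positives, and the package reports
sensitivity and FDR against ground truth whenever a dataset carries a
`SimTruth`. This dependence also means per-locus screening hits are strongly
clustered within traits (measured design effect ≈ 11 at the study
dimensions), which matters when attaching Monte-Carlo error bars to
candidate rates: the trait, not the trait×locus pair, is the independent
unit.

## Heritability and Mantel correlation (`admixqtl.quantgen`)

**Half-sib model.** Seedlings in open-pollinated maternal families follow a
one-way random-effects model y_ij = μ + s_i + e_ij with among-family
variance Var(s) and within-family variance Var(e), fit by REML to respect
the unbalanced family sizes. The implementation profiles the restricted
likelihood over the variance ratio λ = Var(s)/Var(e) (Var(e) has a closed
form given λ), optimises on log λ with the λ = 0 boundary checked
explicitly, and agrees with lme4 to ~1e-7 on test data and with the
balanced-ANOVA closed form (MSB−MSW)/n₀ whenever that estimate is positive.

**Paternity-corrected multiplier.** With a fraction Cp of sibs sharing a
father (correlation of paternity), mean sib relatedness is
r̄ = Cp/2 + (1−Cp)/4 and h² = (1/r̄)·Var(s)/(Var(s)+Var(e)). Cp = 0 gives
the textbook half-sib multiplier 4, Cp = 1 the full-sib 2; at the study's
Cp = 0.31, 1/r̄ = 3.053, and the integer-rounded multiplier 3 is what the
reporting uses. h² is not truncated at 1 — estimates above 1 are a
recognised signature of maternal effects in young seedlings and are worth
seeing.

Estimator behaviour at the study scale: with only 15 families the h² ratio
is slightly biased downward (Jensen effect on the intraclass ratio, partly
offset by the Var(s) ≥ 0 boundary); at the study dimensions the mean
estimate stays within ±0.1 of truth across h² ∈ {0.2, 0.5, 0.8}
(200-replicate check in the acceptance suite).

**Mantel.** Genomic distance is |Q_i − Q_j| (Q doubles as a hybrid index),
phenotypic distance |y_i − y_j|; r is the Pearson correlation of
upper-triangle entries. Because both matrices are distances, a positive r
corresponds to a positive similarity correlation. Significance is one-sided
(large r) by jointly permuting rows and columns of one matrix,
p = (#{r_perm ≥ r_obs}+1)/(n_perm+1); n ≤ 8 supports exact enumeration of
all n! relabelings. The CLI default is 9999 permutations; the full-pipeline
default is 999 to keep an end-to-end run cheap. The hybrid-only variant
filters with the (0.01, 0.99) preset.

## Selection signals (`admixqtl.selection`)

**Per-locus test.** Under neutral admixture the probability that tree i is
an interspecific heterozygote at any locus is 2Q_i(1−Q_i), so the null
distribution of the het count at a locus is Poisson-binomial. The upper
tail P(X ≥ observed) is computed exactly by dynamic-programming convolution
(O(n²), supported to n = 5000); a locus is flagged at p < α (default 0.05,
no multiple-testing correction — the flags feed an enrichment test, they are
not endpoints). A cross-zone criterion ("excess in ≥ 2 hybrid zones") is
the intersection count over locality-stratified runs.

**Calibration scope.** The test is exactly calibrated when ancestry states
are known (type-I ≤ α verified on 10⁴ null loci). When LSA is *estimated*,
the MAP heterozygote-overcall at weakly informative loci (see above) makes
the flags anti-conservative for low-delta markers; analyses on estimated
ancestry should read pooled flag counts with that in mind. The full Bayesian
genomic-clines machinery that the field uses for publication-grade excess
calls is out of scope here by design; this exact conditional test supplies
the binary per-locus flag the enrichment question needs.

**Enrichment.** Fisher's exact one-sided test on the 2×2 table (QTL yes/no ×
excess yes/no), via scipy with the sample odds ratio reported.

## Phenotype structure (`admixqtl.phenostruct`)

PCA is an eigendecomposition of the correlation matrix by default (traits
are relative abundances on heterogeneous scales); the covariance option
exists because the choice is not universal. Missing cells are mean-imputed
per trait and logged; component signs are fixed (largest-magnitude loading
positive) for reproducibility. Taxon contrasts use one-way ANOVA plus Tukey
HSD (statsmodels) with a greedy compact-letter display. Shapiro–Wilk
annotates normality but gates nothing — rank correlations are used
downstream regardless, since most metabolite abundances are non-normal.

Correlation networks keep trait pairs with Spearman rho strictly > 0.5 at
p < 0.001, per taxon subset (admixed trees via the (0.05, 0.95) preset;
parental-like by label). p-values: exact enumeration for n ≤ 9, seeded
Monte-Carlo permutation (10⁴ resamples) for 10 ≤ n ≤ 20, t-approximation
above — full enumeration beyond n ≈ 9 is computationally infeasible, and the
study's subsets are all far larger anyway. Constant traits are excluded and
logged. Layout is networkx's Fruchterman–Reingold with a fixed seed, purely
cosmetic.

## Synthetic data (`admixqtl.simulate`)

The generator emulates the study design: three localities with
(alba-like, tremula-like, hybrid) counts defaulting to 51/46/163 over 260
trees; 77 multi-allelic co-dominant markers on 19 chromosomes with per-locus
parental allele-frequency differentials delta ~ U(0.2, 1) (individual loci
can be pinned, e.g. delta = 1 for planted-QTL experiments); 38 traits in
three functional groups (8 chlorogenic acids, 12 salicinoids, 18
flavonoids).

Hybrid Q values come from a mixture of discrete hybrid classes — F1 (Q =
0.5), F2 (Beta(8,8)), backcrosses toward either parent (Beta(12,4),
Beta(4,12)) — with default weights (0.25, 0.35, 0.20, 0.20). The class
weights are a free parameter, not an inferred quantity: real hybrid zones
mix generations in unknown proportions, and the mixture just reproduces a
plausible Q spread. Given Q, per-locus ancestry is drawn independently
(P(het) = 2Q(1−Q)); genotypes are drawn from the species frequency vectors
conditional on ancestry.

Latent-scale phenotypes are

    z = locality effect + Σ_QTL [ a·(2·anc−1) + d·1{anc=0.5} ]
        + λ·group factor + √(1−λ²)·N(0,1),

with effects in residual-SD units and λ (default 0.5) the within-group
latent-factor loading, so null traits in a group correlate at λ². By default
hybrid-zone phenotypes are exponentiated (exp(z)) to emulate the skewed,
strictly positive abundance distributions — 34/38 real traits are
non-normal, and the exponentiated generator reproduces that under
Shapiro–Wilk. The common garden defaults to the latent Gaussian scale
because its truth parameter is h², which exponentiation would not preserve;
recovery experiments for h² and for variance explained likewise run on the
Gaussian scale, where those truths are defined. Rank-based analyses are
transform-invariant, so network results are unaffected either way.

The common garden draws 15 families of 5–17 seedlings; per trait with
heritability h², among-family variance is r̄·h²·σ²_P (r̄ from Cp as above)
and the residual is the remainder. `SimTruth` records every generating
value (true Q, per-locus ancestry, QTL list, locality means, variance
components), which is what the recovery tests and the pipeline's
sensitivity/FDR summary consume.

**What the generator does not emulate** — and hence what passing tests do
not establish about field data: linkage and recombination (ancestry is
independent across loci given Q, reasonable for 77 markers spread over 19
chromosomes but wrong locally), genotyping error, locality-specific allele
frequencies, selection shaping the ancestry distribution itself,
non-Gaussian residual structure beyond a monotone transform, and
block/maternal effects in the garden (an optional fixed-block pre-adjustment
hook exists but defaults off).

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds through `numpy`'s
`default_rng`; a fixed seed makes datasets, pipeline outputs and layouts
byte-identical across runs (output headers carry the tool version and a
config hash, deliberately no timestamps). The validation suite sizes its
simulations to the study dimensions (n = 260 trees, 77 loci for mapping;
15 families for heritability; n = 109 admixed trees for networks) with
replicate counts of 100–200 for recovery rates and 10⁴ trait replicates for
the null-calibration scan, which the vectorised screening path makes cheap.
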