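# admixqtl

Quantitative genetics of metabolite traits in natural hybrid zones:
admixture mapping, paternity-corrected half-sib heritability, Mantel
genotype–phenotype correlations, interspecific heterozygote-excess tests,
and metabolite correlation networks — with a synthetic hybrid-zone
generator carrying full ground truth for validation.

The package is written for population/quantitative geneticists working on
naturally hybridising species (the motivating system is *Populus alba* ×
*P. tremula*, whose hybrid zones mix parental-like trees with hybrids of
many generations). Instead of a designed cross, the mapping panel is the
hybrid zone itself: each tree carries a genome-wide admixture proportion
Q ∈ [0,1] (the *P. alba* fraction) and, at every marker, a locus-specific
ancestry LSA ∈ {0, ½, 1} (tremula-homozygous, interspecific heterozygote,
alba-homozygous). Phenotypes are relative metabolite abundances in three
functional groups of the phenylpropanoid pathway (chlorogenic acids,
salicinoids, flavonoids).

## The statistics at the core

- **Ancestry.** Q maximises the independent-loci admixture likelihood
  ∏ₗ∏ₐ [Q·p_alba(a) + (1−Q)·p_trem(a)]; LSA is the MAP state of a
  three-state posterior with prior {(1−Q)², 2Q(1−Q), Q²} and genotype
  likelihoods from parental allele frequencies.
- **Admixture mapping.** Traits are reduced to standardized residuals from
  ANOVA on locality, then regressed on LSA per locus with an additive
  (y ~ lsa) and a dominant (y ~ lsa + 1{lsa=½}) Gaussian model. Loci with
  ΔAIC ≥ 4 over the null enter forward-selection / backward-elimination at
  the same threshold; the final model's variance explained is the
  likelihood-ratio pseudo-R², R²_LR = 1 − exp(−(2/n)(logL_M − logL_0)),
  and each retained locus is classified by gene action (additive, alba- or
  tremula-dominant, over-/under-dominant) from its three ancestry-class
  means.
- **Heritability.** One-way random-effects REML on open-pollinated maternal
  families; because a fraction Cp of sibs share a father, mean sib
  relatedness is r̄ = Cp/2 + (1−Cp)/4 and h² = (1/r̄)·Var(s)/(Var(s)+Var(e)).
  Cp = 0.31 gives 1/r̄ = 3.05, i.e. the multiplier 3 (h² is not truncated
  at 1).
- **Mantel.** r = Pearson correlation of the upper triangles of the
  |ΔQ| and |Δtrait| distance matrices; one-sided permutation p.
- **Selection signal.** Under neutral admixture a tree is heterozygous at a
  locus with probability 2Q(1−Q); the locus-level het count is
  Poisson-binomial and its upper tail is computed exactly. Excess loci are
  tested for enrichment among metabolite QTL with Fisher's exact test.
- **Networks.** All-pairs Spearman rho; edges at rho > 0.5 and p < 0.001,
  per taxon subset; Fruchterman–Reingold layout.

docs/methods.md documents every model, default and numerical choice.

## Worked example

`analysis/` holds the numbered study scripts; each reads the synthetic
study written by the first one and prints what it finds:

```bash
python analysis/01_simulate_study.py
python analysis/02_infer_ancestry.py
python analysis/03_map_qtl.py
```

which prints (seeded, so reproducible):

```
hybrid zones: 260 trees (163 hybrids) x 77 loci, 38 traits, 5 planted QTL
common garden: 183 seedlings in 15 families (Cp = 0.31)

Q: mean absolute error vs truth = 0.030 (corr 0.991)
LSA: MAP accuracy = 0.835; per-locus accuracy rises with the parental
  allele-frequency differential (r = 0.95)
taxon classes (0.05 < Q < 0.95): {'hybrid': 164, 'alba-like': 51,
  'tremula-like': 45}

383 candidate trait-locus pairs; 26 retained after forward/backward selection
planted-QTL recovery: sensitivity 1.00 (5/5), FDR 0.81
PVE of final models: mean 0.07, range 0.02-0.31
```

Reading this: with 77 microsatellite-grade markers (delta between 0.2 and
1), Q is recovered to ±0.03 and ancestry calls are right 84% of the time.
All five planted QTL are found, but the high FDR is the expected signature
of admixture structure — every locus correlates with genome-wide Q, so
moderate-delta markers pick up structure-driven signal that model selection
only partly removes. `04_heritability_and_mantel.py` then recovers the
planted heritabilities (e.g. h² = 0.34 at truth 0.35 for the first
salicinoid; multiplier 3.053 → 3 at Cp = 0.31),
`05_selection_signals.py` runs the heterozygote-excess and enrichment
tests per hybrid zone, and `06_phenotype_structure.py` prints PCA variance
percentages, Tukey contrasts and the per-taxon correlation networks.

The same stages are available as a CLI
(`admixqtl simulate|ancestry|map|h2|mantel|clines|network|pca|all`) and as
one call, `admixqtl.io.run_full_pipeline`, which writes one TSV per stage
and a summary with sensitivity/FDR whenever ground truth is attached.
Fixed seed ⇒ byte-identical outputs.

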