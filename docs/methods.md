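# Methods

`orchardsim` is a stochastic simulator for comparing pedigree-based (BLUP)
and marker-based (GBLUP) genetic evaluation in a forest-tree breeding
program that uses clonally replicated progeny tests and selects seed-orchard
parents under an effective-population-size constraint.  This note documents
the generative model, the estimation machinery, the numerical choices, and
the limits of what the simulations can show.

## Breeding design and genomes

The simulated unit is one cycle of a conifer-style program: `n_parents = 50`
unrelated, non-inbred founders are mated in a single-pair design (SPM), so
each parent enters exactly one cross and the progeny consist of 25 disjoint
full-sib families of `family_size` 80 or 160 (2 050 or 4 050 individuals in
total including parents).

Genomes carry `n_chrom = 2` chromosomes of 120 cM.  SNP markers sit on a
regular grid of 1, 5 or 10 markers per cM (240–2 400 markers genome-wide);
`n_qtl = 200` biallelic QTL are placed uniformly at random, by default at
positions distinct from the marker grid so that markers never carry effects
(a `qtl_on_markers` switch collapses the two panels for sensitivity
checks).  Founder allele frequencies are Uniform(0.1, 0.9) per locus,
bounded away from fixation so the genomic relationship matrix is always
well defined.

### Founder linkage disequilibrium

By default founder loci segregate **independently** (linkage equilibrium).
This is a deliberate modelling decision, not an omission: in a progeny
population of 25 large full-sib families, strong marker–QTL LD arises from
co-segregation alone — measured mean r² between loci 1 cM apart is ≈ 0.48
*within* families (≈ 0.015 pooled across families, where phases cancel; run
`analysis/01_calibrate_founder_ld.py`).  Within-family co-segregation is
exactly the signal genomic evaluation exploits in a progeny test, and this
regime reproduces the reference accuracy structure: GBLUP is rewarded only
insofar as markers track segregation within and between families, and its
advantage over pedigree evaluation grows steeply with marker density.

An optional founder-LD model is provided for sensitivity analyses: a latent
Gaussian first-order copying process along each chromosome with step
correlation exp(−k·Δ cM), thresholded at the per-locus frequency quantile.
The sweep in `calibrate_ld_decay` gives k = 0.28 for a founder-panel mean
r²(1 cM) of 0.2.  Switching this on changes the qualitative conclusions:
ancestral LD lets even a 1 SNP/cM panel tag the QTL, GBLUP then beats BLUP
at every density, and the density response flattens.  We treat founder LD
as a scenario axis (`ld_decay_rate`, default `None` = equilibrium), with
the equilibrium default defining the reference conditions.

### Meiosis

Gametes follow Haldane's model: crossover counts per chromosome are
Poisson(length/100), crossover positions uniform, starting haplotype fair,
no interference, no obligate chiasma, no mutation, no sex chromosomes.
Recombination fractions between locus pairs therefore satisfy
c = ½(1 − e^(−2d)) with d in Morgans, which the tests verify by Monte
Carlo at 10 and 120 cM.

## Trait model and clonal phenotypes

The trait is strictly additive: allele-substitution effects for the 200 QTL
are drawn from the standard Normal, and TBVᵢ = Σ_q dosage_iq · effect_q.
Residual variance is anchored to the **realized** additive variance of the
offspring generation each replicate, σ²_E = Var(TBV)·(1 − h²)/h² with
h² = 0.2, so the single-tree heritability is exact in every dataset rather
than on average.  A genotype planted as N_R ramets (1, 6 or 12; 1 = no
cloning) is observed as a clone-mean phenotype

  yᵢ = TBVᵢ + (1/N_R) Σ_r e_ir,  e_ir ~ N(0, σ²_E) i.i.d.,

so the effective residual variance is σ²_E/N_R and the clone-mean
heritability is h²/(h² + (1 − h²)/N_R) — 0.6 at N_R = 6.  Ramet residuals
are independent: no common-environment (C) effects, no dominance or
epistasis, no G×E, single trait, single generation.  Parents are never
phenotyped.

## Genetic evaluation

Both evaluations fit the intercept-only animal model to the offspring clone
means,

  y = 1μ + u + e,  u ~ N(0, σ²_A K),  e ~ N(0, σ²_e I),

differing only in K.  Clonal data enter as clone means with the shrunken
residual variance rather than as repeated records, exactly matching the
generative formula and avoiding a permanent-environment component the
design does not define.

* **BLUP**: K is the pedigree numerator matrix A restricted to the
  offspring.  Under SPM with unrelated founders this block is exactly
  block-diagonal, 0.5·I + 0.5·J per family, whose eigendecomposition is
  assembled per 80×80 (or 160×160) family block — no large decomposition is
  ever formed.  With unphenotyped, ungenotyped parents the offspring block
  yields the same offspring ranking as the full-pedigree model.  The
  general tabular (recursive) A is also implemented and is checked against
  a gene-dropping estimate of twice the kinship.
* **GBLUP**: K is VanRaden's G = ZZ′/(2Σp(1−p)) over the offspring, with M
  the 0/1/2 dosage matrix of the second allele, p the allele frequencies
  **observed in the genotyped offspring**, monomorphic loci dropped before
  the denominator.  Centring at observed frequencies makes G singular (rows
  sum to zero), so a relative jitter of 10⁻⁶ × mean diagonal is added
  before use; tests confirm the jitter moves well-conditioned predictions
  by less than 10⁻⁴ in correlation.

Variance components are estimated by REML.  K is eigendecomposed once per
replicate; in the eigenbasis each restricted-likelihood evaluation is O(n),
and the problem reduces to a bounded scalar minimisation over
log κ (κ = σ²_e/σ²_A), tolerance 10⁻⁸, κ clamped to [10⁻⁶, 10⁶] with
boundary hits flagged.  The additive variance is profiled out analytically.
Breeding values are the mixed-model solutions
û = U diag(λ/(λ+κ)) U′(y − 1μ̂) with μ̂ the GLS intercept; unit tests pin
these to dense-matrix REML likelihoods and to a dense Henderson-equation
solve at 10⁻⁶/10⁻⁸.  Accuracy is the Pearson correlation between EBV and
TBV over the offspring (the selection candidates).

## Orchard selection and gain

The seed-orchard set maximises mean EBV subject to exactly Ne selections
(Ne ∈ {5, 10, 20, 25}) with no two sharing a parent.  For equally
contributing, pairwise-unrelated, non-inbred selections the status
effective number equals the census count, so Ne is implemented as the set
size.  Under SPM the families are the connected components of the
relatedness graph, so the integer program has an exact combinatorial
solution: take each family's best candidate and keep the top Ne family
maxima (EBV ties broken towards the lowest candidate index for
determinism).  Tests verify exact agreement with exhaustive subset
enumeration on small instances.

Standardized gain is ΔG = (mean TBV of the selected − mean offspring TBV) /
SD(offspring TBV), i.e. the selection differential in units of the realized
additive genetic SD.  Alternatives (phenotypic SD, theoretical additive SD)
were considered; the realized additive SD keeps ΔG unit-free, replicate-
specific and comparable across clonal designs.

## Experiments, pairing and summaries

One replicate = one dataset (map, founders, gametes, effects, residuals).
Within a replicate, BLUP and GBLUP are fitted to identical data, all clonal
sizes share the same genotypes and effects, and all Ne targets share the
same EBVs, so every contrast is paired.  The per-replicate seed is split
into named child streams (map / founders / meiosis / effects /
residuals-per-N_R) via `numpy` SeedSequence spawn keys; per-replicate seeds
derive from the master seed and the cell coordinates, so any cell is
reproducible in isolation and reruns are bit-identical.

Cell summaries report Monte-Carlo means, standard errors SD/√n, paired
GBLUP − BLUP differences, and two-sided paired t-tests at α = 0.05 for the
significance flags (the test behind the flags is a package choice; any
reasonable paired test gives the same flags at these effect sizes).
Default replication is 30 iterations for the bundled drivers and tests
(standard errors ≈ 2.6× those of a 200-iteration run); the full 200 is a
single config change (`n_iterations: 200`).

## Numerical and degenerate-input behaviour

* Relationship matrices must be symmetric; `ensure_invertible` raises the
  smallest eigenvalue above 10⁻⁸ by escalating diagonal jitter and records
  the amount applied.
* G requires at least one polymorphic marker; an all-monomorphic panel is
  an error naming the filter.
* REML refuses zero-variance phenotypes; degenerate (zero-variance) TBV
  vectors are rejected when calibrating σ²_E.
* Selection with Ne above the number of available families is infeasible
  and raises; empty selections are rejected in the gain computation.
* Map positions are strictly increasing within chromosomes; QTL drawn onto
  an existing position are resampled.

## Known limitations

* Single generation, forward selection only: no recurrent selection,
  no inbreeding accumulation over cycles, no overlapping generations.
* Purely additive trait; no dominance/epistasis means clonal values and
  breeding values coincide, which favours clonal testing relative to a
  world with non-additive variance.
* The equilibrium-founder default means all marker information is
  family-linked; programs whose base populations carry strong ancestral LD
  should switch the founder-LD model on and recalibrate.
* GBLUP with very sparse panels (1 SNP/cM) still captures family structure
  here because the evaluation handles the low-rank G exactly (eigenbasis +
  explicit jitter); pipelines that invert a near-singular G less carefully
  can degrade much further in that regime, so sparse-panel comparisons are
  implementation-sensitive.
* Status effective number is the only diversity currency; no
  kinship-penalised or unequal-contribution optimisation.
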