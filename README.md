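# orchardsim

Stochastic simulation of **pedigree-based (BLUP) versus genomic (GBLUP)
genetic evaluation in forest-tree breeding**, with clonal replication in
progeny tests and seed-orchard selection under an effective-population-size
constraint.

## The problem

Tree breeders must decide where to invest: in *clonally replicated progeny
trials* (planting each candidate genotype as N_R ramets, which averages away
environmental noise) or in *genomic evaluation* (dense SNP genotyping, which
resolves the Mendelian sampling term that pedigrees cannot see).  This
package simulates one breeding cycle of an outcrossing conifer-style program
and measures, under controlled conditions, how much each investment buys in
breeding-value accuracy and in realized genetic gain delivered through a
seed orchard.

The simulated design: 50 founders crossed in single-pair matings (25
full-sib families of 80 or 160), genomes of 2 × 120 cM with SNP panels of
1/5/10 markers per cM and 200 standard-Normal QTL, narrow-sense heritability
h² = 0.2 (a typical growth trait), clone-mean phenotypes with N_R ∈ {1, 6,
12} ramets, and orchard sets of Ne ∈ {5, 10, 20, 25} mutually unrelated
top-ranked offspring.

## The model

Both evaluations fit the animal model to offspring clone means,

    y = 1μ + u + e,   u ~ N(0, σ²_A·K),   e ~ N(0, σ²_e·I)

with K = A (pedigree numerator relationships; exactly block-diagonal
0.5·I + 0.5·J per full-sib family here) for BLUP, or K = G (VanRaden,
G = ZZ′ / 2Σpₘ(1−pₘ), Z the dosage matrix centred at observed allele
frequencies) for GBLUP.  Variance components come from REML: K is
eigendecomposed once, the likelihood is profiled down to a bounded
one-dimensional search over σ²_e/σ²_A, and EBVs are the mixed-model
solutions û = U diag(λᵢ/(λᵢ+κ)) U′(y − 1μ̂).  Accuracy is cor(EBV, TBV)
over the selection candidates.  The orchard set solves
max mean EBV s.t. |S| = Ne and ≤ 1 selection per family (the exact integer
optimum under this design), and standardized gain is
ΔG = (mean TBV of S − mean TBV) / SD(TBV).

See `docs/methods.md` for the generative model, founder-LD treatment,
numerical details and limitations.

## Worked example

Simulate one replicate (family size 80, 5 SNPs/cM, 6 ramets per genotype),
evaluate it both ways, and pick a 10-clone orchard:

```bash
$ orchardsim simulate --seed 7 --family-size 80 --density 5 --n-r 6 --out-dir demo
wrote replicate (seed=7) to demo

$ orchardsim evaluate --method blup  --pedigree demo/pedigree.txt \
      --pheno demo/phenotypes.csv --out demo/ebv_blup.csv
BLUP: sigma2_a=115.6 sigma2_e=35.43 h2=0.765 accuracy=0.848

$ orchardsim evaluate --method gblup --plink demo/genotypes \
      --pheno demo/phenotypes.csv --out demo/ebv_gblup.csv
GBLUP: sigma2_a=73.4 sigma2_e=64.35 h2=0.533 accuracy=0.928

$ orchardsim select --ebv demo/ebv_gblup.csv --ne 10 --out demo/orchard.csv
selected 10 offspring, mean EBV 16.6911, standardized gain 1.703
```

Reading the numbers: with 6 ramets the clone-mean heritability rises from
0.2 to ~0.6, so even pedigree BLUP ranks candidates well (accuracy 0.848 —
the fitted `h2` is the REML estimate on the clone-mean scale, here a noisy
0.765).  A 5 SNP/cM panel adds within-family information and lifts accuracy
to 0.928; selecting the 10 best mutually unrelated candidates on those EBVs
realizes a response of 1.70 additive-genetic standard deviations.
`demo/` holds the genotypes (PLINK .ped/.map, optionally VCF), pedigree,
phenotype table and a manifest sufficient to reproduce the replicate
bit-exactly.

The replicated study itself is driven by the numbered scripts:

```bash
python analysis/01_calibrate_founder_ld.py      # LD regimes + decay sweep
python analysis/02_run_scenarios.py --reps 30   # the full scenario grid
python analysis/03_summarize_tables.py          # headline comparisons
```

which write the accuracy table, the GBLUP/BLUP ratio table, standardized
gains and paired gain differences with significance flags under `results/`.
Headline pattern at 30 replicates: BLUP accuracy climbs from ~0.70 (no
cloning) to ~0.88 (12 ramets) independent of markers; GBLUP needs ≥5
SNPs/cM to overtake BLUP (~112% relative accuracy without cloning) and its
advantage in standardized gain shrinks steadily as ramets are added — with
extensive clonal testing, genomic evaluation adds little response.

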