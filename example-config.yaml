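# Canonical scenario-grid configuration (all values shown are the defaults;
# an empty file gives exactly this grid).  Consumed by `orchardsim grid
# --config ...` and `orchardsim simulate --config ...`.

n_parents: 50            # founders, crossed in single-pair matings (25 families)
family_sizes: [80, 160]  # offspring per cross
n_ramets: [1, 6, 12]     # clonal copies per offspring genotype (1 = no cloning)
marker_densities: [1.0, 5.0, 10.0]   # SNPs per cM
ne_targets: [5, 10, 20, 25]          # orchard sizes (status effective number)

n_chrom: 2
chrom_length: 120.0      # cM
n_qtl: 200
h2: 0.2                  # single-tree narrow-sense heritability
freq_min: 0.1            # founder allele-frequency law: Uniform(freq_min, freq_max)
freq_max: 0.9
ld_decay_rate: null      # null = linkage-equilibrium founders; a positive k
                         # switches on the exp(-k * cM) founder-LD model
                         # (k = 0.28 gives founder r^2(1 cM) ~ 0.2)
qtl_on_markers: false    # true: QTL effects sit on marker loci instead

n_iterations: 200        # stochastic replicates per grid cell
seed: 1                  # master seed
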