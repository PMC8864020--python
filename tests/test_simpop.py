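"""Genetic map construction, founder LD, meiosis and offspring generation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from orchardsim import (
    FounderConfig,
    GeneticMap,
    MatingDesign,
    build_map,
    founder_ld_at_distance,
    make_offspring,
    meiosis,
    simulate_founders,
)


def haldane(d_cM: float) -> float:
    return 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))


class TestBuildMap:
    @pytest.mark.parametrize(
        "n_chrom,length,density,n_qtl,exp_markers",
        [
            (2, 120, 10, 200, 2400),
            (1, 120, 1, 0, 120),
            (2, 120, 5, 200, 1200),
        ],
    )
    def test_locus_counts(self, n_chrom, length, density, n_qtl, exp_markers):
        gmap = build_map(n_chrom, length, density, n_qtl, seed=0)
        assert gmap.n_markers == exp_markers
        assert gmap.n_qtl == n_qtl
        assert gmap.n_loci == exp_markers + n_qtl

    @given(
        n_chrom=st.integers(1, 3),
        density=st.sampled_from([0.5, 1.0, 2.5, 5.0]),
        n_qtl=st.integers(0, 40),
        seed=st.integers(0, 1000),
    )
    def test_invariants(self, n_chrom, density, n_qtl, seed):
        gmap = build_map(n_chrom, 60.0, density, n_qtl, seed=seed)
        assert gmap.pos_cM.min() >= 0 and gmap.pos_cM.max() <= 60.0
        for sl in gmap.chrom_slices():
            assert np.all(np.diff(gmap.pos_cM[sl]) > 0)
        # QTL are disjoint from the marker panel by default
        assert not np.any(gmap.is_qtl & gmap.is_marker)

    def test_qtl_on_markers_mode(self):
        gmap = build_map(2, 120, 1, 100, seed=0, qtl_on_markers=True)
        assert gmap.n_loci == 240
        assert np.all(gmap.is_marker)
        assert gmap.n_qtl == 100
        assert np.all(gmap.is_marker[gmap.qtl_idx])

    def test_errors(self):
        with pytest.raises(ValueError):
            build_map(2, 120, 0.0, 10)
        with pytest.raises(ValueError):
            build_map(1, 10, 1, 100, seed=0, qtl_on_markers=True)  # 10 markers < 100 qtl


class TestFounders:
    def test_marginal_allele_frequencies(self):
        gmap = build_map(1, 60, 5, 0, seed=1)
        cfg = FounderConfig(n_parents=200)
        rng = np.random.default_rng(2)
        # regenerate the frequency draw to compare against
        p = np.random.default_rng(2).uniform(0.1, 0.9, gmap.n_loci)
        panel = simulate_founders(gmap, cfg, rng)
        freq = panel.haplotypes.reshape(400, -1).mean(axis=0)
        assert np.abs(freq - p).max() < 0.12  # binomial error at 400 haplotypes

    def test_linkage_equilibrium_default(self):
        """Default founders: adjacent-locus r^2 is pure sampling noise
        (~1/(2 n_parents)), and so is cross-chromosome r^2."""
        r2 = founder_ld_at_distance(ld_decay_rate=50.0, distance_cM=1.0,
                                    n_panels=200, seed=3)
        assert r2 < 0.03  # E[r^2] under independence ~ 0.01 at 100 haplotypes

    def test_cross_chromosome_independence(self):
        gmap = build_map(2, 30, 1, 0, seed=4)
        cfg = FounderConfig(n_parents=50, ld_decay_rate=0.28)
        rng = np.random.default_rng(4)
        vals = []
        for _ in range(200):
            H = simulate_founders(gmap, cfg, rng).haplotypes.reshape(100, -1).astype(float)
            a = H[:, gmap.chrom == 0].mean(axis=1)
            b = H[:, gmap.chrom == 1].mean(axis=1)
            if a.std() > 0 and b.std() > 0:
                vals.append(np.corrcoef(a, b)[0, 1] ** 2)
        assert np.mean(vals) < 0.03

    def test_ld_model_hits_calibration_target(self):
        """The copying model at the calibrated decay constant gives mean
        founder r^2(1 cM) within +-0.05 of the 0.2 target."""
        r2 = founder_ld_at_distance(ld_decay_rate=0.28, distance_cM=1.0,
                                    n_panels=200, seed=5)
        assert abs(r2 - 0.2) < 0.05

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FounderConfig(n_parents=7)
        with pytest.raises(ValueError):
            FounderConfig(freq_min=0.0)
        with pytest.raises(ValueError):
            FounderConfig(ld_decay_rate=-1.0)


class TestMeiosis:
    def test_nearly_coincident_loci_coinherited(self, rng):
        pos = np.array([50.0, 50.0 + 1e-9])
        gmap = GeneticMap(np.zeros(2, int), pos, np.zeros(2, bool), np.ones(2, bool), 120.0)
        haps = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        for _ in range(2000):
            g = meiosis(haps, gmap, rng)
            assert g[0] == g[1]

    @pytest.mark.parametrize("dist,expected", [(10.0, haldane(10)), (120.0, haldane(120))])
    def test_recombination_fraction_light(self, dist, expected, rng):
        pos = np.array([0.0, dist])
        gmap = GeneticMap(np.zeros(2, int), pos, np.zeros(2, bool), np.ones(2, bool), 120.0)
        haps = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        n = 20_000
        rec = sum(int(g[0] != g[1]) for g in (meiosis(haps, gmap, rng) for _ in range(n)))
        assert abs(rec / n - expected) < 0.012


class TestOffspring:
    @pytest.mark.parametrize("family_size,total", [(80, 2050), (160, 4050)])
    def test_population_sizes(self, family_size, total, rng):
        gmap = build_map(2, 120, 0.05, 5, rng)
        founders = simulate_founders(gmap, FounderConfig(50), rng)
        pop = make_offspring(founders, MatingDesign(50, family_size), gmap, rng)
        assert pop.pedigree.n == total
        assert pop.offspring_mask.sum() == total - 50
        assert len(np.unique(pop.offspring_family)) == 25

    def test_mendelian_consistency_and_allele_frequency(self, rng):
        gmap = build_map(1, 50, 1, 10, rng)
        founders = simulate_founders(gmap, FounderConfig(4), rng)
        design = MatingDesign(4, 200)
        pop = make_offspring(founders, design, gmap, rng)
        parents = pop.genotypes[:4]
        # each parent appears in exactly one cross (SPM)
        assert set(zip(pop.pedigree.sire[4:], pop.pedigree.dam[4:])) == {(1, 2), (3, 4)}
        compatible = {
            0: {0},
            1: {0, 1},
            2: {1},
        }
        for fam, (si, di) in enumerate([(0, 1), (2, 3)]):
            kids = pop.genotypes[4:][pop.offspring_family == fam]
            for locus in range(gmap.n_loci):
                allowed = {
                    a + b
                    for a in compatible[int(parents[si, locus])]
                    for b in compatible[int(parents[di, locus])]
                }
                assert set(np.unique(kids[:, locus])) <= allowed
        # offspring allele frequency tracks the parental mean
        par_freq = parents.mean(axis=0) / 2
        off_freq = pop.genotypes[4:].mean(axis=0) / 2
        # binomial sampling error with 400 offspring of 2 crosses
        assert np.abs(off_freq - par_freq).max() < 4 * np.sqrt(0.25 / (2 * 400)) + 0.05

    def test_dosage_range(self, rng):
        gmap = build_map(2, 120, 0.1, 20, rng)
        founders = simulate_founders(gmap, FounderConfig(10), rng)
        pop = make_offspring(founders, MatingDesign(10, 30), gmap, rng)
        assert pop.genotypes.min() >= 0 and pop.genotypes.max() <= 2

    def test_odd_parent_count_rejected(self):
        with pytest.raises(ValueError):
            MatingDesign(7, 10)
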