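"""Pedigree A (tabular method), VanRaden G, and jitter regularisation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from orchardsim import (
    FounderConfig,
    MatingDesign,
    Pedigree,
    build_map,
    ensure_invertible,
    full_sib_block_A,
    make_offspring,
    pedigree_A,
    simulate_founders,
    vanraden_G,
)


def random_pedigree(n_founders: int, n_total: int, rng) -> Pedigree:
    ids = np.arange(1, n_total + 1)
    sire = np.zeros(n_total, int)
    dam = np.zeros(n_total, int)
    for i in range(n_founders, n_total):
        s, d = rng.choice(i, size=2, replace=False)
        sire[i], dam[i] = ids[s], ids[d]
    return Pedigree(ids, sire, dam)


def gene_drop_kinship(ped: Pedigree, n_drops: int, rng) -> np.ndarray:
    """Monte-Carlo 2x kinship by dropping uniquely labelled founder alleles."""
    s, d = ped.parent_indices()
    n = ped.n
    alleles = np.empty((n, 2, n_drops), dtype=np.int32)
    for i in range(n):
        if s[i] < 0:
            alleles[i, 0] = 2 * i
            alleles[i, 1] = 2 * i + 1
        else:
            for slot, parent in ((0, s[i]), (1, d[i])):
                pick = rng.integers(2, size=n_drops)
                alleles[i, slot] = alleles[parent, pick, np.arange(n_drops)]
    A = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            m = 0.0
            for a in range(2):
                for b in range(2):
                    m += np.mean(alleles[i, a] == alleles[j, b])
            A[i, j] = A[j, i] = m / 2.0
    return A


class TestPedigreeA:
    def test_unrelated_founders_identity(self):
        ped = Pedigree(np.arange(1, 5), np.zeros(4, int), np.zeros(4, int))
        assert np.array_equal(pedigree_A(ped).values, np.eye(4))

    def test_textbook_values(self):
        # 2 founders, their 2 full-sib offspring
        ped = Pedigree(np.array([1, 2, 3, 4]), np.array([0, 0, 1, 1]),
                       np.array([0, 0, 2, 2]))
        A = pedigree_A(ped).values
        assert A[0, 2] == pytest.approx(0.5)  # parent-offspring
        assert A[2, 3] == pytest.approx(0.5)  # full sibs
        assert A[2, 2] == pytest.approx(1.0)  # non-inbred (parents unrelated)

    def test_inbred_diagonal(self):
        # offspring of full sibs is inbred: F = 0.25
        ped = Pedigree(np.arange(1, 6), np.array([0, 0, 1, 1, 3]),
                       np.array([0, 0, 2, 2, 4]))
        A = pedigree_A(ped).values
        assert A[4, 4] == pytest.approx(1.25)

    def test_against_gene_drop(self, rng):
        ped = random_pedigree(10, 50, rng)
        A = pedigree_A(ped).values
        A_mc = gene_drop_kinship(ped, 10_000, rng)
        assert np.abs(A - A_mc).max() < 0.02

    def test_subset_and_ordering_errors(self, rng):
        ped = random_pedigree(4, 10, rng)
        A = pedigree_A(ped).values
        sub = pedigree_A(ped, subset=ped.ids[4:]).values
        assert np.allclose(sub, A[4:, 4:])
        with pytest.raises(ValueError, match="precede"):
            Pedigree(np.array([1, 2]), np.array([2, 0]), np.array([0, 0]))

    def test_spm_offspring_block_structure(self, rng):
        """Offspring A under single-pair mating = block-diag(0.5 I + 0.5 J)."""
        gmap = build_map(1, 20, 0.2, 2, rng)
        founders = simulate_founders(gmap, FounderConfig(6), rng)
        pop = make_offspring(founders, MatingDesign(6, 4), gmap, rng)
        A_off = pedigree_A(pop.pedigree, subset=pop.offspring_ids).values
        assert np.allclose(A_off, full_sib_block_A(3, 4).values)


class TestVanRadenG:
    def test_forced_two_individual_example(self):
        G = vanraden_G(np.array([[0], [2]]))
        assert np.allclose(G.values, [[2, -2], [-2, 2]])

    def test_rows_sum_to_zero_with_observed_freqs(self, rng):
        M = rng.integers(0, 3, size=(15, 40))
        G = vanraden_G(M)
        assert np.abs(G.values.sum(axis=1)).max() < 1e-10

    @given(seed=st.integers(0, 500))
    def test_against_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.integers(0, 3, size=(10, 30)).astype(float)
        p = M.mean(axis=0) / 2
        poly = (p > 0) & (p < 1)
        Mp, pp = M[:, poly], p[poly]
        denom = 2 * np.sum(pp * (1 - pp))
        naive = np.empty((10, 10))
        for i in range(10):
            for j in range(10):
                naive[i, j] = sum(
                    (Mp[i, m] - 2 * pp[m]) * (Mp[j, m] - 2 * pp[m]) for m in range(Mp.shape[1])
                ) / denom
        assert np.abs(vanraden_G(M).values - naive).max() < 1e-10

    def test_monomorphic_loci_dropped_and_error(self):
        M = np.array([[0, 2, 1], [0, 0, 1], [0, 1, 0]])
        G = vanraden_G(M)  # first locus monomorphic, dropped
        assert G.n_markers == 2
        with pytest.raises(ValueError, match="monomorphic"):
            vanraden_G(np.zeros((3, 4)))

    def test_structure_in_spm_population(self, rng):
        """Mean diagonal ~ 1; full sibs ~ 0.5; different families ~ 0."""
        gmap = build_map(2, 120, 10, 0, rng)
        founders = simulate_founders(gmap, FounderConfig(50), rng)
        pop = make_offspring(founders, MatingDesign(50, 4), gmap, rng)
        G = vanraden_G(pop.offspring_genotypes).values
        fam = pop.offspring_family
        same = (fam[:, None] == fam[None, :]) & ~np.eye(100, dtype=bool)
        diff = fam[:, None] != fam[None, :]
        assert abs(np.diag(G).mean() - 1.0) < 0.1
        assert abs(G[same].mean() - 0.5) < 0.1
        assert abs(G[diff].mean()) < 0.05


class TestEnsureInvertible:
    def test_identity_unchanged(self):
        from orchardsim import RelationshipMatrix
        rm = RelationshipMatrix(np.eye(5), np.arange(5), "pedigree")
        out = ensure_invertible(rm)
        assert out.jitter == 0.0 and np.array_equal(out.values, np.eye(5))

    def test_centered_G_regularised(self, rng):
        M = rng.integers(0, 3, size=(12, 50))
        G = vanraden_G(M)  # singular: rows sum to zero
        out = ensure_invertible(G, tol=1e-8)
        assert out.jitter > 0
        assert np.linalg.eigvalsh(out.values).min() >= 1e-8 - 1e-12

    def test_jitter_barely_perturbs_blup(self, rng):
        from orchardsim import EigenK, blup_predict, reml_fit
        A = full_sib_block_A(5, 8)
        y = rng.standard_normal(40) + 2.0
        jittered = A.values + 1e-6 * np.eye(40)
        ebv0, ebv1 = (
            blup_predict(y, ek, reml_fit(y, ek)).ebv
            for ek in (EigenK.from_dense(A.values), EigenK.from_dense(jittered))
        )
        assert np.corrcoef(ebv0, ebv1)[0, 1] > 1 - 1e-4
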