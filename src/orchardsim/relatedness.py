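"""Pedigree (A) and genomic (G) relationship matrices.

A is built with the standard tabular (recursive) method; G follows
VanRaden's first method, G = ZZ' / (2 * sum p(1-p)) with Z the dosage matrix
column-centred at twice the observed allele frequency.  Because centring at
observed frequencies makes G singular (rows sum to zero), a small diagonal
jitter can be applied before mixed-model use.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg

from .simpop import Pedigree

__all__ = [
    "RelationshipMatrix",
    "pedigree_A",
    "vanraden_G",
    "ensure_invertible",
    "full_sib_block_A",
]


@dataclass(frozen=True)
class RelationshipMatrix:
    """Square symmetric relationship matrix over an ordered individual set."""

    values: np.ndarray
    ids: np.ndarray
    kind: str  # "pedigree" | "genomic"
    allele_freqs: np.ndarray | None = None
    n_markers: int | None = None
    jitter: float = 0.0

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if self.ids.size != v.shape[0]:
            raise ValueError("ids must match matrix dimension")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pedigree_A(pedigree: Pedigree, subset: np.ndarray | None = None) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    A_ij is twice the kinship coefficient; founders are taken unrelated and
    non-inbred.  ``subset`` (ids) optionally restricts the returned block,
    e.g. to the phenotyped offspring.
    """
    n = pedigree.n
    s, d = pedigree.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        if i:
            row = np.zeros(i)
            if si >= 0:
                row += 0.5 * A[si, :i]
            if di >= 0:
                row += 0.5 * A[di, :i]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0)
    ids = pedigree.ids
    if subset is not None:
        pos = {int(x): k for k, x in enumerate(ids)}
        try:
            idx = np.array([pos[int(x)] for x in subset])
        except KeyError as e:  # pragma: no cover - defensive
            raise ValueError(f"subset id {e} not in pedigree") from None
        A = A[np.ix_(idx, idx)]
        ids = np.asarray(subset)
    return RelationshipMatrix(A, np.asarray(ids), "pedigree")


def full_sib_block_A(n_families: int, family_size: int, ids: np.ndarray | None = None) -> RelationshipMatrix:
    """Offspring-block A under single-pair mating with unrelated founders:
    block-diagonal with one (0.5 I + 0.5 J) block per full-sib family."""
    f = family_size
    block = 0.5 * np.eye(f) + 0.5 * np.ones((f, f))
    A = scipy.linalg.block_diag(*([block] * n_families))
    if ids is None:
        ids = np.arange(1, n_families * f + 1)
    return RelationshipMatrix(A, np.asarray(ids), "pedigree")


def vanraden_G(
    genotype_matrix: np.ndarray,
    ids: np.ndarray | None = None,
    allele_freqs: np.ndarray | None = None,
) -> RelationshipMatrix:
    """Genomic relationship matrix G = ZZ' / (2 * sum p(1-p)).

    M holds dosages 0/1/2 of the second allele; p defaults to the observed
    frequencies in the genotyped set (so each row of G sums to zero).
    Monomorphic loci are dropped before the denominator is computed.
    """
    M = np.asarray(genotype_matrix, dtype=float)
    if M.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (individuals x loci)")
    p = M.mean(axis=0) / 2.0 if allele_freqs is None else np.asarray(allele_freqs, float)
    if p.size != M.shape[1]:
        raise ValueError("allele_freqs must match the number of loci")
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all loci are monomorphic after the polymorphism filter")
    pk = p[poly]
    Z = M[:, poly] - 2.0 * pk
    denom = 2.0 * float(np.sum(pk * (1.0 - pk)))
    G = (Z @ Z.T) / denom
    if ids is None:
        ids = np.arange(1, M.shape[0] + 1)
    return RelationshipMatrix(G, np.asarray(ids), "genomic", allele_freqs=pk, n_markers=int(poly.sum()))


def ensure_invertible(
    matrix: RelationshipMatrix,
    jitter: float | None = None,
    tol: float = 1e-8,
) -> RelationshipMatrix:
    """Add diagonal jitter until the smallest eigenvalue clears ``tol``.

    Default jitter is 1e-6 times the mean diagonal.  A matrix that is
    already safely positive definite is returned unchanged; the amount
    applied is recorded in the metadata.
    """
    K = matrix.values
    lo = float(scipy.linalg.eigh(K, eigvals_only=True, subset_by_index=(0, 0))[0])
    if lo >= tol:
        return matrix
    eps = jitter if jitter is not None else 1e-6 * float(np.mean(np.diag(K)))
    total = 0.0
    for _ in range(30):
        need = tol - lo
        step = max(eps, need)
        K = K + step * np.eye(K.shape[0])
        total += step
        lo += step
        if lo >= tol:
            break
    return replace(matrix, values=K, jitter=matrix.jitter + total)
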