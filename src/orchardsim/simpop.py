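"""Genetic maps, founder haplotypes with linkage disequilibrium, meiosis,
and single-pair-mating offspring populations.

The simulated breeding unit is a conifer-style progeny test: 50 unrelated,
non-inbred founders are crossed in a single-pair mating (SPM) design giving
25 disjoint full-sib families.  Genomes consist of a small number of long
chromosomes carrying a regular SNP-marker grid plus QTL interleaved at
uniform random positions.  Founder haplotypes are in linkage equilibrium by
default (population LD then arises downstream from family co-segregation);
an optional thresholded Gaussian copying process generates ancestral LD that
decays exponentially with genetic distance.  Gametes are produced under
Haldane's model (Poisson crossovers, no interference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "GeneticMap",
    "FounderConfig",
    "HaplotypePanel",
    "Pedigree",
    "MatingDesign",
    "Population",
    "DEFAULT_LD_DECAY",
    "build_map",
    "simulate_founders",
    "meiosis",
    "make_offspring",
    "founder_ld_at_distance",
    "calibrate_ld_decay",
]

#: Per-cM decay constant of the latent copying correlation exp(-k * d_cM)
#: for the optional founder-LD model.  Calibrated (see
#: :func:`calibrate_ld_decay` and the 01_calibrate_founder_ld analysis
#: driver) so that mean founder r^2 between loci 1 cM apart is ~0.2.
#: The default founder population is in linkage equilibrium
#: (``ld_decay_rate=None``): founder loci segregate independently and
#: population LD emerges downstream from co-segregation within the full-sib
#: families, the regime that reproduces the reference accuracy tables.
DEFAULT_LD_DECAY = 0.28


# ---------------------------------------------------------------------------
# genetic map


@dataclass(frozen=True)
class GeneticMap:
    """Ordered loci on one or more chromosomes.

    Loci are stored chromosome-major, position-sorted.  ``is_qtl`` and
    ``is_marker`` may overlap only when the map was built with
    ``qtl_on_markers=True``.
    """

    chrom: np.ndarray  # (L,) int, 0-based chromosome index
    pos_cM: np.ndarray  # (L,) float, position in centiMorgan
    is_qtl: np.ndarray  # (L,) bool
    is_marker: np.ndarray  # (L,) bool
    chrom_length: float

    def __post_init__(self) -> None:
        if self.chrom.shape != self.pos_cM.shape or self.chrom.shape != self.is_qtl.shape:
            raise ValueError("map arrays must have equal length")
        if np.any(self.pos_cM < 0) or np.any(self.pos_cM > self.chrom_length):
            raise ValueError("locus positions must lie in [0, chrom_length]")
        for sl in self.chrom_slices():
            if np.any(np.diff(self.pos_cM[sl]) <= 0):
                raise ValueError("positions must be strictly increasing within a chromosome")

    @property
    def n_loci(self) -> int:
        return self.chrom.size

    @property
    def n_chromosomes(self) -> int:
        return int(self.chrom.max()) + 1 if self.n_loci else 0

    @property
    def marker_idx(self) -> np.ndarray:
        return np.flatnonzero(self.is_marker)

    @property
    def qtl_idx(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    @property
    def n_markers(self) -> int:
        return int(self.is_marker.sum())

    @property
    def n_qtl(self) -> int:
        return int(self.is_qtl.sum())

    def chrom_slices(self) -> list[slice]:
        """Contiguous slice per chromosome (loci are chromosome-major)."""
        out = []
        for c in range(int(self.chrom.max()) + 1 if self.n_loci else 0):
            idx = np.flatnonzero(self.chrom == c)
            if idx.size:
                out.append(slice(int(idx[0]), int(idx[-1]) + 1))
            else:
                out.append(slice(0, 0))
        return out


def build_map(
    n_chrom: int,
    length_cM: float,
    marker_density: float,
    n_qtl: int,
    seed: int | np.random.Generator | None = None,
    qtl_on_markers: bool = False,
) -> GeneticMap:
    """Place a regular marker grid and uniformly scattered QTL.

    Markers sit on a grid of spacing ``1/marker_density`` cM (grid centred in
    its cells so endpoints stay inside the chromosome).  QTL positions are
    uniform on the map, split evenly across chromosomes in expectation, and
    by default form loci disjoint from the marker panel; with
    ``qtl_on_markers`` the effects are instead assigned to existing markers.
    """
    if marker_density <= 0:
        raise ValueError("marker_density must be positive")
    if n_chrom < 1 or length_cM <= 0:
        raise ValueError("need at least one chromosome of positive length")
    if n_qtl < 0:
        raise ValueError("n_qtl must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    m_per = int(round(marker_density * length_cM))
    spacing = 1.0 / marker_density
    marker_pos = (np.arange(m_per) + 0.5) * spacing

    if qtl_on_markers:
        if n_qtl > n_chrom * m_per:
            raise ValueError("n_qtl exceeds the number of available marker positions")
        chrom = np.repeat(np.arange(n_chrom), m_per)
        pos = np.tile(marker_pos, n_chrom)
        is_marker = np.ones(pos.size, dtype=bool)
        is_qtl = np.zeros(pos.size, dtype=bool)
        hit = rng.choice(pos.size, size=n_qtl, replace=False)
        is_qtl[hit] = True
        return GeneticMap(chrom, pos, is_qtl, is_marker, float(length_cM))

    qtl_chrom = rng.integers(n_chrom, size=n_qtl)
    qtl_pos = rng.uniform(0.0, length_cM, size=n_qtl)

    chroms, poss, qflag = [], [], []
    for c in range(n_chrom):
        qp = qtl_pos[qtl_chrom == c]
        # continuous positions collide with the grid with probability zero,
        # but resample any exact duplicate so ordering stays strict
        all_pos = np.concatenate([marker_pos, qp])
        while np.unique(all_pos).size < all_pos.size:
            qp = rng.uniform(0.0, length_cM, size=qp.size)
            all_pos = np.concatenate([marker_pos, qp])
        flag = np.concatenate([np.zeros(m_per, bool), np.ones(qp.size, bool)])
        order = np.argsort(all_pos)
        chroms.append(np.full(all_pos.size, c))
        poss.append(all_pos[order])
        qflag.append(flag[order])

    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    is_qtl = np.concatenate(qflag)
    return GeneticMap(chrom, pos, is_qtl, ~is_qtl, float(length_cM))


# ---------------------------------------------------------------------------
# founders


@dataclass(frozen=True)
class FounderConfig:
    """Founder-population settings.

    Allele frequencies are Uniform(freq_min, freq_max) per locus, bounded
    away from fixation so the genomic relationship matrix stays well
    defined.  ``ld_decay_rate`` is the per-cM decay constant k of the latent
    locus-to-locus copying correlation exp(-k * d) of the optional
    founder-LD model; ``None`` (the default) puts founder loci in linkage
    equilibrium, so population LD arises only from family co-segregation in
    the progeny.
    """

    n_parents: int = 50
    freq_min: float = 0.1
    freq_max: float = 0.9
    ld_decay_rate: float | None = None

    def __post_init__(self) -> None:
        if self.n_parents < 2 or self.n_parents % 2:
            raise ValueError("n_parents must be even and >= 2 (single-pair mating)")
        if not (0.0 < self.freq_min < self.freq_max < 1.0):
            raise ValueError("allele frequencies must satisfy 0 < freq_min < freq_max < 1")
        if self.ld_decay_rate is not None and self.ld_decay_rate <= 0:
            raise ValueError("ld_decay_rate must be positive (or None for linkage equilibrium)")


@dataclass(frozen=True)
class HaplotypePanel:
    """Phased haplotypes, alleles coded 0/1, shape (n, 2, L)."""

    ids: np.ndarray
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("alleles must be coded 0/1")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def genotypes(self) -> np.ndarray:
        """Dosage of the '1' allele, shape (n, L), values in {0,1,2}."""
        return self.haplotypes.sum(axis=1, dtype=np.int8)


def simulate_founders(
    gmap: GeneticMap,
    config: FounderConfig,
    rng: np.random.Generator,
) -> HaplotypePanel:
    """Draw founder haplotypes, by default in linkage equilibrium.

    Per-locus allele frequencies p_l ~ Uniform(freq_min, freq_max).  With
    ``ld_decay_rate=None`` every locus is an independent Bernoulli(p_l)
    draw.  With a finite decay constant k, along each chromosome a latent
    standard-Gaussian AR process with step correlation exp(-k * d_cM) is
    thresholded at the p_l quantile, so every locus is Bernoulli(p_l)
    marginally while nearby loci are positively correlated with correlation
    decaying in genetic distance.  Chromosomes and haplotypes are
    independent.
    """
    L = gmap.n_loci
    n_hap = 2 * config.n_parents
    p = rng.uniform(config.freq_min, config.freq_max, size=L)
    if config.ld_decay_rate is None:
        haps = (rng.random((n_hap, L)) < p).astype(np.uint8)
        ids = np.arange(1, config.n_parents + 1)
        return HaplotypePanel(ids, haps.reshape(config.n_parents, 2, L))
    thresh = norm.ppf(p)
    haps = np.empty((n_hap, L), dtype=np.uint8)
    for sl in gmap.chrom_slices():
        pos = gmap.pos_cM[sl]
        if pos.size == 0:
            continue
        z = np.empty((n_hap, pos.size))
        z[:, 0] = rng.standard_normal(n_hap)
        step = np.exp(-config.ld_decay_rate * np.diff(pos))
        innov = rng.standard_normal((n_hap, pos.size - 1)) if pos.size > 1 else None
        for j in range(1, pos.size):
            r = step[j - 1]
            z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * innov[:, j - 1]
        haps[:, sl] = z < thresh[sl]
    ids = np.arange(1, config.n_parents + 1)
    return HaplotypePanel(ids, haps.reshape(config.n_parents, 2, L))


def founder_ld_at_distance(
    ld_decay_rate: float,
    distance_cM: float = 1.0,
    n_panels: int = 50,
    n_parents: int = 50,
    n_loci: int = 60,
    seed: int | None = 0,
) -> float:
    """Monte-Carlo mean r^2 between founder loci ``distance_cM`` apart.

    r^2 is the squared Pearson correlation of the 0/1 allele indicators over
    the 2*n_parents founder haplotypes, averaged over adjacent pairs of an
    equally spaced map and over independent panels.
    """
    rng = np.random.default_rng(seed)
    pos = np.arange(n_loci) * distance_cM
    gmap = GeneticMap(
        np.zeros(n_loci, dtype=int), pos.astype(float),
        np.zeros(n_loci, bool), np.ones(n_loci, bool),
        float(pos[-1] + distance_cM),
    )
    cfg = FounderConfig(n_parents=n_parents, ld_decay_rate=ld_decay_rate)
    vals = []
    for _ in range(n_panels):
        panel = simulate_founders(gmap, cfg, rng)
        H = panel.haplotypes.reshape(2 * n_parents, n_loci).astype(float)
        sd = H.std(axis=0)
        keep = sd > 0
        Hc = (H - H.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        r = (Hc[:, :-1] * Hc[:, 1:]).mean(axis=0)
        ok = keep[:-1] & keep[1:]
        vals.append(np.mean(r[ok] ** 2))
    return float(np.mean(vals))


def calibrate_ld_decay(
    target_r2: float = 0.2,
    distance_cM: float = 1.0,
    k_grid: np.ndarray | None = None,
    seed: int | None = 0,
    **mc_kwargs,
) -> tuple[float, "np.ndarray"]:
    """Sweep decay constants and pick the one whose mean r^2 at
    ``distance_cM`` is closest to ``target_r2``.

    Returns ``(k_best, table)`` where table has columns (k, r2).
    """
    if k_grid is None:
        k_grid = np.linspace(0.2, 1.2, 11)
    r2 = np.array([
        founder_ld_at_distance(k, distance_cM, seed=seed, **mc_kwargs) for k in k_grid
    ])
    best = int(np.argmin(np.abs(r2 - target_r2)))
    return float(k_grid[best]), np.column_stack([k_grid, r2])


# ---------------------------------------------------------------------------
# pedigree and mating


@dataclass(frozen=True)
class Pedigree:
    """Records (id, sire, dam); 0 denotes an unknown parent.

    Ordering is topological: both parents of an individual appear earlier.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray

    def __post_init__(self) -> None:
        n = self.ids.size
        if self.sire.size != n or self.dam.size != n:
            raise ValueError("pedigree columns must have equal length")
        if np.unique(self.ids).size != n:
            raise ValueError("duplicate individual ids in pedigree")
        index = {int(i): k for k, i in enumerate(self.ids)}
        for k in range(n):
            for par in (int(self.sire[k]), int(self.dam[k])):
                if par == 0:
                    continue
                if par not in index:
                    raise ValueError(f"unknown parent id {par}")
                if index[par] >= k:
                    raise ValueError("parents must precede offspring in the pedigree")

    @property
    def n(self) -> int:
        return self.ids.size

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based positional indices of sire and dam; -1 for unknown."""
        index = {int(i): k for k, i in enumerate(self.ids)}
        s = np.array([index.get(int(x), -1) if x else -1 for x in self.sire])
        d = np.array([index.get(int(x), -1) if x else -1 for x in self.dam])
        return s, d


@dataclass(frozen=True)
class MatingDesign:
    """Single-pair mating: each parent used in exactly one cross."""

    n_parents: int = 50
    family_size: int = 80

    def __post_init__(self) -> None:
        if self.n_parents < 2 or self.n_parents % 2:
            raise ValueError("n_parents must be even (single-pair mating)")
        if self.family_size < 1:
            raise ValueError("family_size must be >= 1")

    @property
    def n_families(self) -> int:
        return self.n_parents // 2

    @property
    def total_size(self) -> int:
        return self.n_parents + self.n_families * self.family_size


@dataclass(frozen=True)
class Population:
    """Parents plus offspring: pedigree, dosages at all loci, family labels.

    ``family`` is -1 for parents and the 0-based full-sib family index for
    offspring; ordering is parents first, then offspring family-major.
    """

    pedigree: Pedigree
    genotypes: np.ndarray  # (N, L) int8 dosages in {0,1,2}
    family: np.ndarray  # (N,) int
    n_parents: int
    gmap: GeneticMap

    @property
    def offspring_mask(self) -> np.ndarray:
        return self.family >= 0

    @property
    def offspring_genotypes(self) -> np.ndarray:
        return self.genotypes[self.offspring_mask]

    @property
    def offspring_family(self) -> np.ndarray:
        return self.family[self.offspring_mask]

    @property
    def offspring_ids(self) -> np.ndarray:
        return self.pedigree.ids[self.offspring_mask]


# ---------------------------------------------------------------------------
# meiosis


def meiosis(
    parent_haplotypes: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete under Haldane's model.

    Crossover count per chromosome is Poisson(length_cM / 100), crossover
    positions are uniform, the starting haplotype is fair, and the gamete
    switches source haplotype at each crossover (no interference).
    """
    if parent_haplotypes.ndim != 2 or parent_haplotypes.shape[0] != 2:
        raise ValueError("parent_haplotypes must have shape (2, n_loci)")
    gamete = np.empty(gmap.n_loci, dtype=parent_haplotypes.dtype)
    for sl in gmap.chrom_slices():
        pos = gmap.pos_cM[sl]
        if pos.size == 0:
            continue
        n_x = rng.poisson(gmap.chrom_length / 100.0)
        start = rng.integers(2)
        if n_x:
            xpos = np.sort(rng.uniform(0.0, gmap.chrom_length, size=n_x))
            source = (start + np.searchsorted(xpos, pos)) % 2
        else:
            source = np.full(pos.size, start)
        h = parent_haplotypes[:, sl]
        gamete[sl] = np.where(source == 0, h[0], h[1])
    return gamete


def make_offspring(
    founders: HaplotypePanel,
    design: MatingDesign,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> Population:
    """Cross founders pairwise (SPM) and gene-drop gametes to offspring.

    Pairs are (founder 1, founder 2), (founder 3, founder 4), ...; each
    offspring dosage is the sum of one maternal and one paternal gamete.
    """
    if founders.n_individuals != design.n_parents:
        raise ValueError("founder panel size does not match the mating design")
    L = gmap.n_loci
    n_off = design.n_families * design.family_size
    geno = np.empty((design.n_parents + n_off, L), dtype=np.int8)
    geno[: design.n_parents] = founders.genotypes

    par_ids = founders.ids
    off_ids = np.arange(design.n_parents + 1, design.n_parents + n_off + 1)
    sire = np.zeros(design.n_parents + n_off, dtype=int)
    dam = np.zeros_like(sire)
    family = np.full(design.n_parents + n_off, -1, dtype=int)

    row = design.n_parents
    for fam in range(design.n_families):
        f_idx, m_idx = 2 * fam, 2 * fam + 1
        fh = founders.haplotypes[f_idx]
        mh = founders.haplotypes[m_idx]
        for _ in range(design.family_size):
            geno[row] = meiosis(fh, gmap, rng) + meiosis(mh, gmap, rng)
            sire[row] = par_ids[f_idx]
            dam[row] = par_ids[m_idx]
            family[row] = fam
            row += 1

    ids = np.concatenate([par_ids, off_ids])
    ped = Pedigree(ids, sire, dam)
    return Population(ped, geno, family, design.n_parents, gmap)
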