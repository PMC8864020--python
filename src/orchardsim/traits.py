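"""Additive trait architecture, true breeding values, and clone-mean
phenotypes at a target narrow-sense heritability.

The trait is purely additive: 200 QTL by default, allele-substitution
effects drawn from the standard Normal and applied to 0/1/2 dosages.  The
residual variance is anchored to the realized additive variance of the
offspring generation so that the single-tree heritability equals h2 exactly
in every replicate.  Clonal replication (N_R ramets per offspring genotype)
enters as the mean of N_R i.i.d. residual draws, shrinking the effective
residual variance to sigma2_e / N_R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TraitArchitecture",
    "ClonalDesign",
    "PhenotypeSet",
    "draw_qtl_effects",
    "true_breeding_values",
    "calibrate_residual_variance",
    "simulate_phenotypes",
]


@dataclass(frozen=True)
class TraitArchitecture:
    """Per-QTL additive allele-substitution effects and the target h2."""

    qtl_effects: np.ndarray
    h2: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.qtl_effects)):
            raise ValueError("QTL effects must be finite")
        if not (0.0 < self.h2 < 1.0):
            raise ValueError("h2 must lie strictly between 0 and 1")

    @property
    def n_qtl(self) -> int:
        return self.qtl_effects.size


@dataclass(frozen=True)
class ClonalDesign:
    """Number of clonal ramets per offspring genotype (1 = no cloning)."""

    n_ramets: int = 1

    def __post_init__(self) -> None:
        if self.n_ramets < 1:
            raise ValueError("n_ramets must be >= 1")


@dataclass(frozen=True)
class PhenotypeSet:
    """True breeding values and observed clone-mean phenotypes."""

    tbv: np.ndarray
    phenotype: np.ndarray
    sigma2_e: float
    n_ramets: int

    def __post_init__(self) -> None:
        if self.tbv.shape != self.phenotype.shape:
            raise ValueError("tbv and phenotype must align")


def draw_qtl_effects(n_qtl: int, h2: float, rng: np.random.Generator) -> TraitArchitecture:
    """Sample standard-Normal allele-substitution effects for n_qtl loci."""
    if n_qtl < 1:
        raise ValueError("need at least one QTL")
    return TraitArchitecture(rng.standard_normal(n_qtl), h2)


def true_breeding_values(qtl_dosages: np.ndarray, qtl_effects: np.ndarray) -> np.ndarray:
    """TBV_i = sum_q dosage_iq * effect_q."""
    qtl_dosages = np.asarray(qtl_dosages)
    qtl_effects = np.asarray(qtl_effects, dtype=float)
    if qtl_dosages.ndim != 2 or qtl_dosages.shape[1] != qtl_effects.size:
        raise ValueError("dosage matrix columns must match the number of QTL effects")
    return qtl_dosages.astype(float) @ qtl_effects


def calibrate_residual_variance(tbv_offspring: np.ndarray, h2: float) -> float:
    """Residual variance giving single-tree heritability h2 against the
    realized additive variance of the offspring generation.

    sigma2_e = Var(TBV) * (1 - h2) / h2.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2 must lie strictly between 0 and 1")
    var_a = float(np.var(tbv_offspring, ddof=1))
    if var_a <= 1e-12:
        raise ValueError("degenerate TBV: zero additive variance")
    return var_a * (1.0 - h2) / h2


def simulate_phenotypes(
    tbv: np.ndarray,
    sigma2_e: float,
    clonal_design: ClonalDesign | int,
    rng: np.random.Generator,
) -> PhenotypeSet:
    """Clone-mean phenotype: TBV plus the mean of N_R i.i.d. residuals.

    phenotype_i = TBV_i + mean_{r=1..N_R} e_ir,  e_ir ~ Normal(0, sigma2_e),
    so the effective residual variance is sigma2_e / N_R.
    """
    if sigma2_e < 0:
        raise ValueError("sigma2_e must be non-negative")
    design = ClonalDesign(clonal_design) if isinstance(clonal_design, (int, np.integer)) else clonal_design
    n = tbv.size
    resid = rng.normal(0.0, np.sqrt(sigma2_e), size=(n, design.n_ramets)).mean(axis=1)
    return PhenotypeSet(np.asarray(tbv, float), tbv + resid, float(sigma2_e), design.n_ramets)
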