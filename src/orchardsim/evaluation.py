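"""Single-trait animal-model REML and BLUP/GBLUP breeding-value prediction.

Model: y = 1*mu + u + e with u ~ N(0, sigma2_a * K) and e ~ N(0, sigma2_e * I),
where K is a pedigree (A) or genomic (G) relationship matrix and y are
clone-mean phenotypes (so the fitted residual variance is the effective
sigma2_E / N_R).  K is eigendecomposed once; in the eigenbasis the covariance
is diagonal, every restricted-likelihood evaluation is O(n), and REML reduces
to a bounded one-dimensional search over the variance ratio
kappa = sigma2_e / sigma2_a.  For the block-diagonal full-sib offspring A the
eigenbasis is assembled per 0.5*I + 0.5*J family block, avoiding any large
decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "EigenK",
    "VarianceComponents",
    "EvaluationResult",
    "restricted_loglik",
    "reml_fit",
    "blup_predict",
    "accuracy",
]

_LOG_2PI = np.log(2.0 * np.pi)


class EigenK:
    """Eigendecomposition of a relationship matrix with fast rotation.

    Provides eigvals (ascending is not required) plus rotate/unrotate
    between the observation basis and the eigenbasis.
    """

    def __init__(self, eigvals: np.ndarray, U: np.ndarray | None = None,
                 block_U: np.ndarray | None = None, n_blocks: int | None = None):
        self.eigvals = np.asarray(eigvals, float)
        self._U = U
        self._block_U = block_U
        self._n_blocks = n_blocks
        if (U is None) == (block_U is None):
            raise ValueError("provide exactly one of U or block_U")

    @property
    def n(self) -> int:
        return self.eigvals.size

    @classmethod
    def from_dense(cls, K: np.ndarray) -> "EigenK":
        w, U = np.linalg.eigh(np.asarray(K, float))
        return cls(w, U=U)

    @classmethod
    def from_equal_full_sib_blocks(cls, n_families: int, family_size: int) -> "EigenK":
        """Eigenbasis of block-diag(0.5 I + 0.5 J) without forming it.

        Each family block has one eigenvalue 0.5*(1 + family_size) (the
        family mean) and family_size - 1 eigenvalues of 0.5.
        """
        f = family_size
        B = 0.5 * np.eye(f) + 0.5 * np.ones((f, f))
        wB, UB = np.linalg.eigh(B)
        return cls(np.tile(wB, n_families), block_U=UB, n_blocks=n_families)

    def rotate(self, v: np.ndarray) -> np.ndarray:
        """U' v."""
        if self._U is not None:
            return self._U.T @ v
        f = self._block_U.shape[0]
        return (v.reshape(self._n_blocks, f) @ self._block_U).ravel()

    def unrotate(self, w: np.ndarray) -> np.ndarray:
        """U w."""
        if self._U is not None:
            return self._U @ w
        f = self._block_U.shape[0]
        return (w.reshape(self._n_blocks, f) @ self._block_U.T).ravel()


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    ratio: float  # kappa = sigma2_e / sigma2_a
    loglik: float
    converged: bool
    boundary: bool

    def __post_init__(self) -> None:
        if self.sigma2_a < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def heritability(self) -> float:
        """sigma2_a / (sigma2_a + sigma2_e) on the scale of the fitted data."""
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)


@dataclass(frozen=True)
class EvaluationResult:
    ebv: np.ndarray
    method: str
    varcomp: VarianceComponents
    mu_hat: float
    accuracy: float | None = None

    def with_accuracy(self, tbv: np.ndarray) -> "EvaluationResult":
        return replace(self, accuracy=accuracy(self.ebv, tbv))


def _profile_stats(a: np.ndarray, b: np.ndarray, eigvals: np.ndarray, kappa: float):
    w = 1.0 / (eigvals + kappa)
    sxx = float(np.sum(w * a * a))
    sxy = float(np.sum(w * a * b))
    syy = float(np.sum(w * b * b))
    quad = syy - sxy * sxy / sxx
    return w, sxx, sxy, quad


def restricted_loglik(y: np.ndarray, eigK: EigenK, sigma2_a: float, sigma2_e: float) -> float:
    """Exact restricted log-likelihood (intercept-only fixed effects)."""
    a = eigK.rotate(np.ones(eigK.n))
    b = eigK.rotate(np.asarray(y, float))
    v = sigma2_a * eigK.eigvals + sigma2_e
    if np.any(v <= 0):
        raise ValueError("covariance is not positive definite at these components")
    w = 1.0 / v
    sxx = float(np.sum(w * a * a))
    sxy = float(np.sum(w * a * b))
    syy = float(np.sum(w * b * b))
    quad = syy - sxy * sxy / sxx
    n = eigK.n
    return -0.5 * (float(np.sum(np.log(v))) + np.log(sxx) + quad + (n - 1) * _LOG_2PI)


def reml_fit(
    y: np.ndarray,
    eigK: EigenK,
    ratio_bounds: tuple[float, float] = (1e-6, 1e6),
    xatol: float = 1e-8,
) -> VarianceComponents:
    """Profile REML over the variance ratio in the eigenbasis of K.

    The additive variance is profiled out analytically, leaving a bounded
    scalar minimisation over log(kappa); boundary solutions (e.g. a
    pure-noise trait driving sigma2_a to zero) are flagged.
    """
    y = np.asarray(y, float)
    if y.size != eigK.n:
        raise ValueError("phenotype length does not match K")
    if float(np.var(y)) <= 1e-14:
        raise ValueError("zero phenotypic variance")
    n = eigK.n
    a = eigK.rotate(np.ones(n))
    b = eigK.rotate(y)
    lam = eigK.eigvals
    lo, hi = np.log(ratio_bounds[0]), np.log(ratio_bounds[1])

    def neg_profile_ll(log_kappa: float) -> float:
        kappa = np.exp(log_kappa)
        _, sxx, _, quad = _profile_stats(a, b, lam, kappa)
        s2a = quad / (n - 1)
        return 0.5 * (
            (n - 1) * np.log(s2a)
            + float(np.sum(np.log(lam + kappa)))
            + np.log(sxx)
            + (n - 1) * (1.0 + _LOG_2PI)
        )

    res = minimize_scalar(neg_profile_ll, bounds=(lo, hi), method="bounded",
                          options={"xatol": xatol})
    log_kappa = float(res.x)
    kappa = float(np.exp(log_kappa))
    _, sxx, _, quad = _profile_stats(a, b, lam, kappa)
    s2a = quad / (n - 1)
    s2e = kappa * s2a
    boundary = (log_kappa - lo) < 1e-3 or (hi - log_kappa) < 1e-3
    return VarianceComponents(
        sigma2_a=float(s2a),
        sigma2_e=float(s2e),
        ratio=kappa,
        loglik=float(-res.fun),
        converged=bool(res.success),
        boundary=boundary,
    )


def blup_predict(
    y: np.ndarray,
    eigK: EigenK,
    varcomp: VarianceComponents,
    method: str = "BLUP",
) -> EvaluationResult:
    """Mixed-model-equation solution in the eigenbasis.

    u_hat = U diag(lambda / (lambda + kappa)) U' (y - 1*mu_hat), with mu_hat
    the generalised-least-squares intercept.  Equivalent to solving
    Henderson's equations with K and the fitted variance ratio.
    """
    y = np.asarray(y, float)
    if y.size != eigK.n:
        raise ValueError("phenotype length does not match K")
    kappa = varcomp.ratio
    a = eigK.rotate(np.ones(eigK.n))
    b = eigK.rotate(y)
    _, sxx, sxy, _ = _profile_stats(a, b, eigK.eigvals, kappa)
    mu = sxy / sxx
    shrink = eigK.eigvals / (eigK.eigvals + kappa)
    ebv = eigK.unrotate(shrink * (b - mu * a))
    if not np.all(np.isfinite(ebv)):
        raise ValueError("non-finite EBVs: singular mixed-model system")
    return EvaluationResult(ebv=ebv, method=method, varcomp=varcomp, mu_hat=float(mu))


def accuracy(ebv: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation between predicted and true breeding values."""
    ebv = np.asarray(ebv, float)
    tbv = np.asarray(tbv, float)
    if ebv.size != tbv.size or ebv.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(ebv) == 0 or np.std(tbv) == 0:
        raise ValueError("constant input vector")
    return float(np.corrcoef(ebv, tbv)[0, 1])
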