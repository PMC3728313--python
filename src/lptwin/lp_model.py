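"""Parameter types for the basic and extended limiting-pathway (LP) models.

The LP model posits that an observed quantitative trait is the maximum (or
minimum) of ``k`` latent, fully additive pathway phenotypes.  Each pathway
``j`` has mean ``mu[j]``, phenotypic variance ``sigma2[j]`` and heritability
``h2_path[j]``; a fraction ``c2_path`` of its environmental variance is shared
among siblings of a family.  Pathway additive genetic values may be correlated
across pathways according to a structured correlation matrix; environmental
effects are always independent across pathways.

The basic LP model is the special case of equal means (0), equal variances
(1), equal pathway heritabilities and uncorrelated pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "CorrelationKind",
    "CorrelationSpec",
    "LPParams",
    "CovarianceBundle",
    "InfeasibleCorrelationError",
    "build_correlation_matrix",
    "build_covariances",
]

#: tolerance on the minimum eigenvalue when declaring a matrix PSD;
#: absorbs eigen-decomposition floating-point noise
PSD_TOL = 1e-10


class InfeasibleCorrelationError(ValueError):
    """Raised when a requested pathway correlation structure is not PSD."""


class CorrelationKind(str, Enum):
    """Supported pathway genetic correlation structures.

    uniform
        Correlation ``rho`` between every pair of pathways.
    two_block
        Pathways split into two sets of sizes ``ceil(k/2)`` and
        ``floor(k/2)``; ``+rho`` within a set, ``-rho`` across sets.
    one_vs_rest
        Pathway 1 correlated ``-rho`` with each other pathway; pathways
        2..k mutually ``+rho``.
    """

    UNIFORM = "uniform"
    TWO_BLOCK = "two_block"
    ONE_VS_REST = "one_vs_rest"


@dataclass(frozen=True)
class CorrelationSpec:
    """Pathway genetic correlation structure.

    Parameters
    ----------
    kind
        One of ``uniform``, ``two_block``, ``one_vs_rest`` (string or
        :class:`CorrelationKind`).
    rho
        Dimensionless correlation in ``[-1, 1]``.
    """

    kind: CorrelationKind = CorrelationKind.UNIFORM
    rho: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", CorrelationKind(self.kind))
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")


def build_correlation_matrix(k: int, spec: CorrelationSpec) -> np.ndarray:
    """Construct the ``k x k`` pathway genetic correlation matrix.

    All three structures are rank-one perturbations of the identity,
    ``(1 - rho) I + rho s s'`` with a sign vector ``s``; they share the
    feasibility bound ``rho >= -1/(k-1)`` and are PSD for any
    ``rho in [max(0, -1/(k-1))..1]`` range admitted below.

    Raises
    ------
    InfeasibleCorrelationError
        If the implied matrix is not positive semi-definite; the message
        names the bound.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    rho = float(spec.rho)
    if k == 1:
        return np.ones((1, 1))

    if spec.kind is CorrelationKind.UNIFORM:
        sign = np.ones(k)
    elif spec.kind is CorrelationKind.TWO_BLOCK:
        sign = np.ones(k)
        sign[-(k // 2):] = -1.0
    else:  # one_vs_rest
        sign = np.ones(k)
        sign[0] = -1.0

    corr = (1.0 - rho) * np.eye(k) + rho * np.outer(sign, sign)

    min_eig = float(np.linalg.eigvalsh(corr)[0])
    if min_eig < -PSD_TOL:
        bound = -1.0 / (k - 1)
        raise InfeasibleCorrelationError(
            f"{spec.kind.value} correlation structure with rho={rho} and k={k} "
            f"is not positive semi-definite (min eigenvalue {min_eig:.3g}); "
            f"feasibility requires rho >= {bound:.4g}"
        )
    return corr


def _as_vector(x, k: int, name: str) -> np.ndarray:
    """Broadcast a scalar to length ``k`` or validate a length-``k`` vector."""
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.size == 1:
        arr = np.full(k, arr.item())
    if arr.shape != (k,):
        raise ValueError(f"{name} must be a scalar or length-{k} vector, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class LPParams:
    """Full specification of an extended LP model.

    Parameters
    ----------
    k
        Number of pathways (``>= 1``).
    mu
        Pathway phenotype means (phenotype sd units). Scalar broadcasts.
    sigma2
        Pathway phenotypic variances (strictly positive). Scalar broadcasts.
    h2_path
        Pathway heritabilities in ``[0, 1]``. Scalar broadcasts.
    c2_path
        Fraction of pathway environmental variance common to siblings, in
        ``[0, 1]``; a single value shared by all pathways.
    corr
        Pathway genetic correlation structure.
    combine
        ``"max"`` (default) or ``"min"``: how pathway phenotypes combine
        into the final phenotype.
    """

    k: int = 1
    mu: object = 0.0
    sigma2: object = 1.0
    h2_path: object = 0.5
    c2_path: float = 0.0
    corr: CorrelationSpec = field(default_factory=CorrelationSpec)
    combine: str = "max"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        mu = _as_vector(self.mu, self.k, "mu")
        sigma2 = _as_vector(self.sigma2, self.k, "sigma2")
        h2 = _as_vector(self.h2_path, self.k, "h2_path")
        if np.any(sigma2 <= 0):
            raise ValueError("all pathway variances must be strictly positive")
        if np.any((h2 < 0) | (h2 > 1)):
            raise ValueError("pathway heritabilities must lie in [0, 1]")
        if not 0.0 <= self.c2_path <= 1.0:
            raise ValueError(f"c2_path must lie in [0, 1], got {self.c2_path}")
        if self.combine not in ("max", "min"):
            raise ValueError(f"combine must be 'max' or 'min', got {self.combine!r}")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma2", sigma2)
        object.__setattr__(self, "h2_path", h2)
        object.__setattr__(self, "c2_path", float(self.c2_path))

    @classmethod
    def basic(cls, k: int, h2_path: float, c2_path: float = 0.0,
              combine: str = "max") -> "LPParams":
        """Basic LP model: standard-normal, equal, uncorrelated pathways."""
        return cls(k=k, mu=0.0, sigma2=1.0, h2_path=h2_path, c2_path=c2_path,
                   corr=CorrelationSpec(CorrelationKind.UNIFORM, 0.0),
                   combine=combine)


@dataclass(frozen=True)
class CovarianceBundle:
    """Pathway-level covariance components implied by an :class:`LPParams`.

    Attributes
    ----------
    sigmaA
        ``k x k`` additive-genetic covariance matrix,
        ``sigmaA[i, j] = corr[i, j] * sqrt(h2_i s2_i h2_j s2_j)``.
    varC
        Length-``k`` common-environment variances
        (``c2_path * (1 - h2_j) * sigma2_j``).
    varU
        Length-``k`` unique-environment variances
        (``(1 - c2_path) * (1 - h2_j) * sigma2_j``).
    """

    sigmaA: np.ndarray
    varC: np.ndarray
    varU: np.ndarray


def build_covariances(params: LPParams) -> CovarianceBundle:
    """Assemble the additive and environmental covariance components.

    The genetic correlation applies to additive values only; environmental
    effects are independent across pathways, so ``varC`` and ``varU`` are
    diagonal (returned as vectors).
    """
    corr = build_correlation_matrix(params.k, params.corr)
    sd_a = np.sqrt(params.h2_path * params.sigma2)
    sigmaA = corr * np.outer(sd_a, sd_a)
    var_env = (1.0 - params.h2_path) * params.sigma2
    varC = params.c2_path * var_env
    varU = var_env - varC
    return CovarianceBundle(sigmaA=sigmaA, varC=varC, varU=varU)


def factor_psd(cov: np.ndarray) -> np.ndarray:
    """Matrix square root ``L`` with ``L L' = cov`` for a PSD matrix.

    Uses Cholesky when possible, falling back to an eigen-decomposition with
    negative eigenvalues clipped at zero (needed at the rho -> 1 boundary
    where the additive covariance is singular).
    """
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)
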