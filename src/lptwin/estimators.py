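"""Twin-design estimators for LP-model cohorts.

Implements the classical twin (ACE) variance decomposition from MZ/DZ
correlations (Falconer estimators), the regression-based narrow-sense
heritability of the final phenotype, the final-level common-environment
proportion, and the phantom heritability

    pi = 1 - h2 / h2_ACE,

the fraction of the twin-based heritability estimate not attributable to
true additive variance.  ``run_replicates`` aggregates all quantities over
independent simulation replicates with Monte-Carlo standard errors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .family_sim import FamilyCohort, simulate_cohort
from .lp_model import LPParams, build_covariances, factor_psd

__all__ = [
    "TwinSummary",
    "ACEEstimate",
    "LPOutputs",
    "twin_correlations",
    "ace_estimates",
    "narrow_sense_h2",
    "c2_final",
    "phantom_heritability",
    "run_replicates",
]

#: quantities aggregated across replicates, in reporting order
REPLICATE_FIELDS = ("r_mz", "r_dz", "var_p", "h2_ace", "c2_ace",
                    "h2_narrow", "c2_final", "phantom")


@dataclass(frozen=True)
class TwinSummary:
    """Phenotypic variance and MZ/DZ twin correlations of a cohort."""

    r_mz: float
    r_dz: float
    var_p: float


@dataclass(frozen=True)
class ACEEstimate:
    """Falconer ACE decomposition; components sum to 1 by construction."""

    h2_ace: float
    c2_ace: float
    e2_ace: float


@dataclass
class LPOutputs:
    """Replicate-aggregated LP-model outputs.

    ``means``, ``medians`` and ``mc_se`` map each quantity in
    :data:`REPLICATE_FIELDS` to its mean, median and Monte-Carlo standard
    error (of the mean) across replicates; ``per_replicate`` holds the raw
    per-replicate values.
    """

    means: dict
    medians: dict
    mc_se: dict
    n_replicates: int
    n_families: int
    params: LPParams
    seed: int | None = None
    per_replicate: dict = field(default_factory=dict, repr=False)

    def __getattr__(self, name):
        means = self.__dict__.get("means", {})
        if name in means:
            return means[name]
        raise AttributeError(name)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "means": self.means,
            "medians": self.medians,
            "mc_se": self.mc_se,
            "n_replicates": self.n_replicates,
            "n_families": self.n_families,
            "seed": self.seed,
            "params": {
                "k": p.k,
                "mu": list(p.mu),
                "sigma2": list(p.sigma2),
                "h2_path": list(p.h2_path),
                "c2_path": p.c2_path,
                "corr_kind": p.corr.kind.value,
                "rho": p.corr.rho,
                "combine": p.combine,
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def twin_correlations(cohort: FamilyCohort) -> TwinSummary:
    """Pearson correlations of (offspring, co-twin) final phenotypes.

    The simulator labels one twin of each pair as the reference offspring;
    at cohort sizes of interest the difference between this ordered Pearson
    correlation and the intraclass correlation is below Monte-Carlo noise.
    """
    y = cohort.offspring.Y
    if np.var(y) <= 0 or np.var(cohort.mz_twin.Y) <= 0 or np.var(cohort.dz_twin.Y) <= 0:
        raise ValueError("degenerate cohort: zero phenotypic variance")
    r_mz = float(np.corrcoef(y, cohort.mz_twin.Y)[0, 1])
    r_dz = float(np.corrcoef(y, cohort.dz_twin.Y)[0, 1])
    return TwinSummary(r_mz=r_mz, r_dz=r_dz, var_p=float(np.var(y)))


def ace_estimates(r_mz: float, r_dz: float) -> ACEEstimate:
    """Falconer estimators: ``h2 = 2(rMZ - rDZ)``, ``c2 = 2 rDZ - rMZ``.

    Values are not truncated at [0, 1]: boundary behaviour (negative
    apparent common environment under strong epistasis) is informative, and
    truncation would bias replicate means.
    """
    h2 = 2.0 * (r_mz - r_dz)
    c2 = 2.0 * r_dz - r_mz
    return ACEEstimate(h2_ace=h2, c2_ace=c2, e2_ace=1.0 - r_mz)


def narrow_sense_h2(Y: np.ndarray, A: np.ndarray) -> float:
    """Narrow-sense heritability by regression on pathway additive values.

    Fits OLS of the final phenotype on the ``k`` additive-value columns plus
    an intercept and returns ``Var(sum_j beta_j A_j) / Var(Y)`` — the
    variance of the genetic fitted values over the phenotypic variance.
    Rank-deficient designs (perfectly collinear pathways) fall back to the
    minimum-norm least-squares solution with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    A = np.asarray(A, dtype=float)
    n, k = A.shape
    if n <= k + 1:
        raise ValueError("need more observations than pathways")
    Ac = A - A.mean(axis=0)
    beta, _, rank, _ = np.linalg.lstsq(Ac, Y - Y.mean(), rcond=None)
    if rank < k:
        warnings.warn(
            f"additive-value design is rank deficient ({rank} < {k}); "
            "using minimum-norm solution", RuntimeWarning)
    fitted = Ac @ beta
    return float(np.var(fitted) / np.var(Y))


def c2_final(params: LPParams, n: int = 100_000,
             rng: np.random.Generator | int | None = None,
             method: str = "mz_minus_broad") -> float:
    """Proportion of final-phenotype variance common to siblings.

    All methods are Monte-Carlo estimates at sample size ``n``; in the
    linear (k=1) case they coincide at ``c2_path * (1 - h2_path)`` scaled
    by the phenotypic variance.

    method="mz_minus_broad" (default)
        ``rMZ - H2``: the MZ-pair covariance (shared genome and shared
        common environment) minus the covariance of pairs sharing only the
        genome (broad-sense genetic variance), over ``Var(Y)``.  This is
        the classical identity ``rMZ = H2 + c2`` solved for the
        common-environment share, and attributes genetic-by-common-
        environment interaction variance to the common component.
    method="pair"
        Covariance of pairs sharing only the family-common environment
        ``C`` (independent additive values and unique environments) over
        ``Var(Y)`` — the "adopted sibling" contrast.
    method="regression"
        Mirrors the narrow-sense estimator: regress ``Y`` on the ``k``
        common-environment columns and return the fitted-value variance
        over ``Var(Y)``.
    """
    if method not in ("mz_minus_broad", "pair", "regression"):
        raise ValueError(f"unknown method {method!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cov = build_covariances(params)
    L = factor_psd(cov.sigmaA)
    k = params.k
    mu = params.mu[None, :]
    reduce_ = np.max if params.combine == "max" else np.min
    sd_c, sd_u = np.sqrt(cov.varC), np.sqrt(cov.varU)

    def finish(A, C):
        return reduce_(mu + A + C + rng.standard_normal((n, k)) * sd_u, axis=1)

    A = rng.standard_normal((n, k)) @ L.T
    C1 = rng.standard_normal((n, k)) * sd_c
    if method == "mz_minus_broad":
        C2 = rng.standard_normal((n, k)) * sd_c
        y_ref = finish(A, C1)
        y_mz = finish(A, C1)                    # shares genome and C
        y_gen = finish(A, C2)                   # shares genome only
        var_y = np.mean([np.var(y) for y in (y_ref, y_mz, y_gen)])
        cov_mz = np.mean((y_ref - y_ref.mean()) * (y_mz - y_mz.mean()))
        cov_gen = np.mean((y_ref - y_ref.mean()) * (y_gen - y_gen.mean()))
        return float((cov_mz - cov_gen) / var_y)
    if method == "pair":
        A2 = rng.standard_normal((n, k)) @ L.T
        y1, y2 = finish(A, C1), finish(A2, C1)  # share C only
        var_y = 0.5 * (np.var(y1) + np.var(y2))
        cov_pair = np.mean((y1 - y1.mean()) * (y2 - y2.mean()))
        return float(cov_pair / var_y)
    # regression
    y1 = finish(A, C1)
    return narrow_sense_h2(y1, C1) if np.any(cov.varC > 0) else 0.0


def phantom_heritability(h2_narrow: float, h2_ace: float) -> float:
    """Phantom heritability ``pi = 1 - h2_narrow / h2_ace`` (no clamping)."""
    if h2_ace <= 0:
        raise ValueError("phantom heritability undefined for h2_ace <= 0")
    return 1.0 - h2_narrow / h2_ace


def replicate_estimates(params: LPParams, n_families: int,
                        rng: np.random.Generator,
                        c2_method: str = "mz_minus_broad") -> dict:
    """All estimator outputs for a single simulated cohort."""
    cohort = simulate_cohort(params, n_families, rng)
    twins = twin_correlations(cohort)
    ace = ace_estimates(twins.r_mz, twins.r_dz)
    h2n = narrow_sense_h2(cohort.offspring.Y, cohort.offspring.A)
    c2f = c2_final(params, n=n_families, rng=rng, method=c2_method)
    out = {
        "r_mz": twins.r_mz, "r_dz": twins.r_dz, "var_p": twins.var_p,
        "h2_ace": ace.h2_ace, "c2_ace": ace.c2_ace,
        "h2_narrow": h2n, "c2_final": c2f,
    }
    out["phantom"] = (phantom_heritability(h2n, ace.h2_ace)
                      if ace.h2_ace > 0 else np.nan)
    return out


def run_replicates(params: LPParams, n_families: int = 100_000,
                   n_reps: int = 50, seed: int | None = None,
                   c2_method: str = "mz_minus_broad") -> LPOutputs:
    """Simulate ``n_reps`` independent cohorts and aggregate all estimators.

    Each replicate receives an independent child generator spawned from the
    root seed, so results are reproducible and replicates are exchangeable.
    Means, medians and Monte-Carlo standard errors (of the mean) are
    reported for every quantity.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    per = {f: np.empty(n_reps) for f in REPLICATE_FIELDS}
    for i, ss in enumerate(streams):
        est = replicate_estimates(params, n_families, np.random.default_rng(ss),
                                  c2_method=c2_method)
        for f in REPLICATE_FIELDS:
            per[f][i] = est[f]
    means = {f: float(np.nanmean(per[f])) for f in REPLICATE_FIELDS}
    medians = {f: float(np.nanmedian(per[f])) for f in REPLICATE_FIELDS}
    mc_se = {f: float(np.nanstd(per[f], ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else float("nan")
             for f in REPLICATE_FIELDS}
    # aggregate phantom through the identity on the aggregated components:
    # the ratio of replicate means avoids the Jensen bias of averaging
    # per-replicate ratios when h2_ace is small (per-replicate values and
    # their spread remain available in per_replicate / mc_se)
    for agg in (means, medians):
        if agg["h2_ace"] > 0:
            agg["phantom"] = phantom_heritability(agg["h2_narrow"], agg["h2_ace"])
    return LPOutputs(means=means, medians=medians, mc_se=mc_se,
                     n_replicates=n_reps, n_families=n_families,
                     params=params, seed=seed, per_replicate=per)
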