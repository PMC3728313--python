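"""Calibration of pathway-level inputs to observed twin correlations.

Given observed MZ/DZ correlations (rMZ, rDZ) and a pathway architecture
(k, correlation structure, means, variances), find the shared pathway
heritability ``h2_path`` and common-environment fraction ``c2_path`` such
that the simulated twin correlations match the observations.  This inverts
the forward model and underlies the three-trait illustration: the same
(rMZ, rDZ) pair is consistent with many LP architectures, each implying its
own narrow-sense heritability, phantom heritability and common-variance
contribution.

Matching is equivalent to matching the Falconer statistics
``h2_ACE = 2(rMZ - rDZ)`` and ``c2_ACE = 2 rDZ - rMZ``, which decouple the
search: nested bisection solves ``h2_path`` for ``h2_ACE`` (inner) at each
candidate ``c2_path`` for ``c2_ACE`` (outer).  Both maps are monotone
increasing.  All candidate evaluations reuse one fixed set of
standard-normal draws (common random numbers), which makes the Monte-Carlo
objective smooth in the parameters and the search deterministic given the
seed.  Medians across replicates are used inside the search; the returned
summary reports means as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import LPOutputs, ace_estimates, run_replicates
from .lp_model import CorrelationSpec, LPParams, build_covariances, factor_psd

__all__ = ["CalibrationTarget", "CalibrationResult", "InfeasibleCalibrationError",
           "calibrate"]


class InfeasibleCalibrationError(ValueError):
    """Target twin correlations unreachable within (h2_path, c2_path) in [0,1]^2."""


@dataclass(frozen=True)
class CalibrationTarget:
    """Observed twin correlations to match, and the matching budget.

    ``tol`` is the tolerance on each correlation.  ``n_families`` and
    ``n_reps`` size the final replicate summary; ``n_reps_search``
    replicates (with common random numbers) are used inside the search.
    """

    r_mz_obs: float
    r_dz_obs: float
    tol: float = 0.005
    n_families: int = 100_000
    n_reps: int = 50
    n_reps_search: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_dz_obs <= self.r_mz_obs <= 1.0):
            raise InfeasibleCalibrationError(
                f"infeasible target: need 0 <= rDZ <= rMZ <= 1, got "
                f"(rMZ={self.r_mz_obs}, rDZ={self.r_dz_obs})")


@dataclass
class CalibrationResult:
    """Solution of a calibration run; unpacks as (h2_path, c2_path, outputs)."""

    h2_path: float
    c2_path: float
    outputs: LPOutputs
    r_mz: float
    r_dz: float
    n_evals: int
    converged: bool

    def __iter__(self):
        return iter((self.h2_path, self.c2_path, self.outputs))


class _CRNTwinSimulator:
    """Evaluates median twin correlations on fixed standard-normal draws.

    Pre-draws, once, every normal deviate needed for ``n_reps`` cohorts and
    rescales them per candidate (h2_path, c2_path).  Parents enter the twin
    correlations only through their mid-additive value, which is drawn
    directly with covariance sigmaA/2.
    """

    _STREAMS = ("mid_parent", "mend_off", "mend_dz", "common",
                "u_off", "u_mz", "u_dz")

    def __init__(self, k: int, corr: CorrelationSpec, mu, sigma2,
                 combine: str, n_families: int, n_reps: int,
                 rng: np.random.Generator):
        self.template = LPParams(k=k, mu=mu, sigma2=sigma2, h2_path=0.5,
                                 c2_path=0.0, corr=corr, combine=combine)
        self.n_families = n_families
        self.z = [{s: rng.standard_normal((n_families, k)) for s in self._STREAMS}
                  for _ in range(n_reps)]
        self.n_evals = 0

    def params_at(self, h2_path: float, c2_path: float) -> LPParams:
        t = self.template
        return LPParams(k=t.k, mu=t.mu, sigma2=t.sigma2, h2_path=h2_path,
                        c2_path=c2_path, corr=t.corr, combine=t.combine)

    def twin_correlations(self, h2_path: float, c2_path: float) -> tuple[float, float]:
        """Median (rMZ, rDZ) across the fixed replicates."""
        params = self.params_at(h2_path, c2_path)
        cov = build_covariances(params)
        Lh = factor_psd(cov.sigmaA).T / np.sqrt(2.0)  # half-covariance factor
        sd_c, sd_u = np.sqrt(cov.varC), np.sqrt(cov.varU)
        mu = params.mu[None, :]
        reduce_ = np.max if params.combine == "max" else np.min

        r_mz, r_dz = [], []
        for z in self.z:
            G = z["mid_parent"] @ Lh                  # parental mid-value
            A_off = G + z["mend_off"] @ Lh
            A_dz = G + z["mend_dz"] @ Lh
            C = z["common"] * sd_c
            y_off = reduce_(mu + A_off + C + z["u_off"] * sd_u, axis=1)
            y_mz = reduce_(mu + A_off + C + z["u_mz"] * sd_u, axis=1)
            y_dz = reduce_(mu + A_dz + C + z["u_dz"] * sd_u, axis=1)
            r_mz.append(np.corrcoef(y_off, y_mz)[0, 1])
            r_dz.append(np.corrcoef(y_off, y_dz)[0, 1])
        self.n_evals += 1
        return float(np.median(r_mz)), float(np.median(r_dz))


def _bisect(f, lo: float, hi: float, f_lo: float, f_hi: float,
            tol_f: float, tol_x: float = 5e-4, max_iter: int = 24):
    """Monotone-increasing scalar root find; returns (x, f(x))."""
    x, fx = (lo, f_lo) if abs(f_lo) < abs(f_hi) else (hi, f_hi)
    for _ in range(max_iter):
        if hi - lo < tol_x:
            break
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid) < abs(fx):
            x, fx = mid, f_mid
        if abs(f_mid) <= tol_f:
            return mid, f_mid
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    return x, fx


def calibrate(k: int, corr: CorrelationSpec, target: CalibrationTarget,
              mu=0.0, sigma2=1.0, combine: str = "max",
              c2_method: str = "mz_minus_broad") -> CalibrationResult:
    """Solve for (h2_path, c2_path) matching observed twin correlations.

    Equal pathway heritabilities are assumed (the three-trait illustration
    calibrates a single shared value).  Returns the solution together with
    the full replicate summary (:class:`~lptwin.estimators.LPOutputs`)
    computed at the calibrated parameters with fresh, independent seeds.

    Raises
    ------
    InfeasibleCalibrationError
        If the target lies outside the attainable region of the model; the
        message reports the attainable boundary value.
    """
    h2_t = 2.0 * (target.r_mz_obs - target.r_dz_obs)
    c2_t = 2.0 * target.r_dz_obs - target.r_mz_obs
    root = np.random.SeedSequence(target.seed)
    ss_crn, ss_final = root.spawn(2)
    sim = _CRNTwinSimulator(k, corr, mu, sigma2, combine,
                            target.n_families, target.n_reps_search,
                            np.random.default_rng(ss_crn))
    # tolerance on the ACE statistics implied by the correlation tolerance:
    # both are +/-2-weighted combinations of (rMZ, rDZ)
    tol_f = 2.0 * target.tol

    def h2_ace_at(h2_path: float, c2_path: float) -> float:
        r_mz, r_dz = sim.twin_correlations(h2_path, c2_path)
        return ace_estimates(r_mz, r_dz).h2_ace

    def solve_h2(c2_path: float) -> float:
        f = lambda h2: h2_ace_at(h2, c2_path) - h2_t
        f1 = f(1.0)
        if f1 < -tol_f:
            raise InfeasibleCalibrationError(
                f"target h2_ACE={h2_t:.3f} unattainable: maximum at h2_path=1, "
                f"c2_path={c2_path:.3f} is {f1 + h2_t:.3f}")
        if h2_t <= tol_f / 2:
            return 0.0
        h2, _ = _bisect(f, 0.0, 1.0, -h2_t, f1, tol_f / 2)
        return h2

    def c2_ace_at(c2_path: float) -> tuple[float, float]:
        h2_path = solve_h2(c2_path)
        r_mz, r_dz = sim.twin_correlations(h2_path, c2_path)
        return h2_path, ace_estimates(r_mz, r_dz).c2_ace

    h2_lo, g_lo = c2_ace_at(0.0)
    if g_lo - c2_t > tol_f:
        raise InfeasibleCalibrationError(
            f"target c2_ACE={c2_t:.3f} unattainable: minimum at c2_path=0 "
            f"is {g_lo:.3f}")
    if abs(g_lo - c2_t) <= tol_f / 2:
        h2_path, c2_path = h2_lo, 0.0
    else:
        h2_hi, g_hi = c2_ace_at(1.0)
        if g_hi - c2_t < -tol_f:
            raise InfeasibleCalibrationError(
                f"target c2_ACE={c2_t:.3f} unattainable: maximum at c2_path=1 "
                f"is {g_hi:.3f}")
        state: dict = {}

        def g(c2: float) -> float:
            h2, val = c2_ace_at(c2)
            state[c2] = h2
            return val - c2_t

        c2_path, _ = _bisect(g, 0.0, 1.0, g_lo - c2_t, g_hi - c2_t, tol_f / 2)
        h2_path = state.get(c2_path)
        if h2_path is None:
            h2_path = solve_h2(c2_path)

    r_mz, r_dz = sim.twin_correlations(h2_path, c2_path)
    converged = (abs(r_mz - target.r_mz_obs) <= 2 * target.tol
                 and abs(r_dz - target.r_dz_obs) <= 2 * target.tol)

    params = sim.params_at(h2_path, c2_path)
    final_seed = int(np.random.default_rng(ss_final).integers(2**31 - 1))
    outputs = run_replicates(params, n_families=target.n_families,
                             n_reps=target.n_reps, seed=final_seed,
                             c2_method=c2_method)
    return CalibrationResult(h2_path=h2_path, c2_path=c2_path, outputs=outputs,
                             r_mz=r_mz, r_dz=r_dz, n_evals=sim.n_evals,
                             converged=converged)
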