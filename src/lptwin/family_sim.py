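"""Simulation of nuclear-family cohorts under the extended LP model.

Each simulated family contains two parents, an offspring, its monozygotic
(MZ) co-twin and its dizygotic (DZ) co-twin.  Parents receive independent
multivariate-normal additive values (random mating) and carry the full
environmental variance with no sibling sharing.  Offspring additive values
are the parental mid-value plus a Mendelian-sampling deviation with
covariance half the population additive covariance; the MZ twin copies the
offspring genome, the DZ twin draws an independent Mendelian deviation.
Siblings share the family-common environment ``C`` and receive independent
unique environment ``U``.

Final phenotypes are the maximum (or minimum) over pathway phenotypes; they
are deliberately not re-standardized, since every downstream quantity is a
variance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .lp_model import LPParams, build_covariances, factor_psd

__all__ = [
    "Role",
    "FamilyCohort",
    "simulate_parents",
    "mendelian_offspring",
    "assemble_phenotypes",
    "simulate_cohort",
]

SIBLING_ROLES = ("offspring", "mz_twin", "dz_twin")
PARENT_ROLES = ("mother", "father")


@dataclass
class Role:
    """Per-individual component matrices for one family role.

    ``A``, ``C``, ``U``, ``E`` are ``n x k`` (``C``/``U`` for siblings,
    ``E`` for parents); ``P`` is the ``n x k`` pathway phenotype matrix and
    ``Y`` the length-``n`` final phenotype.
    """

    A: np.ndarray
    C: Optional[np.ndarray] = None
    U: Optional[np.ndarray] = None
    E: Optional[np.ndarray] = None
    P: Optional[np.ndarray] = None
    Y: Optional[np.ndarray] = None

    @property
    def env(self) -> np.ndarray:
        """Total environmental deviation: ``C + U`` for siblings, ``E`` for parents."""
        if self.E is not None:
            return self.E
        return self.C + self.U


@dataclass
class FamilyCohort:
    """A simulated cohort of nuclear families."""

    n_families: int
    params: LPParams
    mother: Role
    father: Role
    offspring: Role
    mz_twin: Role
    dz_twin: Role
    seed: Optional[int] = None

    def role(self, name: str) -> Role:
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one row per individual for inspection/export."""
        rows = []
        k = self.params.k
        for name in PARENT_ROLES + SIBLING_ROLES:
            r = self.role(name)
            d = {"family": np.arange(self.n_families), "role": name}
            for j in range(k):
                d[f"A{j + 1}"] = r.A[:, j]
                d[f"P{j + 1}"] = r.P[:, j]
            d["Y"] = r.Y
            rows.append(pd.DataFrame(d))
        return pd.concat(rows, ignore_index=True)


def simulate_parents(n: int, params: LPParams,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw additive values and environment for ``n`` unrelated parents.

    Returns
    -------
    A : (n, k) array
        Additive values, ``MVN(0, sigmaA)``.
    E : (n, k) array
        Total environmental deviations, ``MVN(0, diag(varC + varU))`` —
        parents carry the full environmental variance with no sharing.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cov = build_covariances(params)
    L = factor_psd(cov.sigmaA)
    A = rng.standard_normal((n, params.k)) @ L.T
    E = rng.standard_normal((n, params.k)) * np.sqrt(cov.varC + cov.varU)
    return A, E


def mendelian_offspring(A_mother: np.ndarray, A_father: np.ndarray,
                        sigmaA: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Additive values of one offspring per family under random mating.

    ``A_off = (A_mother + A_father) / 2 + M`` with Mendelian-sampling
    deviation ``M ~ MVN(0, sigmaA / 2)`` drawn independently per offspring,
    so the population additive covariance is preserved across generations.
    """
    n, k = A_mother.shape
    L = factor_psd(sigmaA)
    M = rng.standard_normal((n, k)) @ (L.T / np.sqrt(2.0))
    return 0.5 * (A_mother + A_father) + M


def assemble_phenotypes(cohort: FamilyCohort, params: Optional[LPParams] = None) -> FamilyCohort:
    """Fill pathway phenotypes ``P`` and final phenotypes ``Y`` in place.

    ``P = mu + A + C + U`` for siblings, ``P = mu + A + E`` for parents;
    ``Y`` is the row-wise max (or min) of ``P``.  With ``k = 1`` the final
    phenotype equals the single pathway phenotype.
    """
    params = params or cohort.params
    reduce_ = np.max if params.combine == "max" else np.min
    for name in PARENT_ROLES + SIBLING_ROLES:
        r = cohort.role(name)
        r.P = params.mu[None, :] + r.A + r.env
        r.Y = reduce_(r.P, axis=1)
    return cohort


def simulate_cohort(params: LPParams, n_families: int,
                    seed: Optional[int | np.random.Generator] = None) -> FamilyCohort:
    """Simulate a fully populated cohort of nuclear families.

    Reproducible given ``(params, n_families, seed)``: a single generator is
    consumed in a fixed stream order (mother A, father A, mother E, father E,
    Mendelian offspring, Mendelian DZ, family C, then U for offspring, MZ
    and DZ twins).
    """
    if n_families < 2:
        raise ValueError("n_families must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = build_covariances(params)
    n, k = n_families, params.k

    A_m, E_m = simulate_parents(n, params, rng)
    A_f, E_f = simulate_parents(n, params, rng)
    A_off = mendelian_offspring(A_m, A_f, cov.sigmaA, rng)
    A_dz = mendelian_offspring(A_m, A_f, cov.sigmaA, rng)

    C = rng.standard_normal((n, k)) * np.sqrt(cov.varC)
    sd_u = np.sqrt(cov.varU)
    U = {name: rng.standard_normal((n, k)) * sd_u for name in SIBLING_ROLES}

    cohort = FamilyCohort(
        n_families=n, params=params,
        mother=Role(A=A_m, E=E_m),
        father=Role(A=A_f, E=E_f),
        offspring=Role(A=A_off, C=C, U=U["offspring"]),
        mz_twin=Role(A=A_off.copy(), C=C, U=U["mz_twin"]),
        dz_twin=Role(A=A_dz, C=C, U=U["dz_twin"]),
        seed=seed if isinstance(seed, int) else None,
    )
    return assemble_phenotypes(cohort, params)
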