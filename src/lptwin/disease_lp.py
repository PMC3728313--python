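"""Pathway-threshold disease model.

A minimal liability-threshold extension of the LP model: an individual is
affected when *any* standardized pathway phenotype exceeds a truncation
threshold.  Each pathway is truncated at proportion ``mu_path``, so with
``k`` independent, equally truncated pathways the overall prevalence is

    mu_total = 1 - (1 - mu_path)^k.

Two conventions are supported for specifying the truncation: ``per_pathway``
takes ``mu_path`` at face value; ``total`` back-solves the per-pathway
proportion so that independent pathways yield a requested overall
prevalence.  Standardization (per-pathway mean and sd divided out) makes
the threshold scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .family_sim import FamilyCohort, SIBLING_ROLES

__all__ = ["DiseaseSpec", "DiseaseResult", "pathway_threshold", "disease_status"]


def pathway_threshold(mu_path: float) -> float:
    """Liability threshold (sd units) for truncation proportion ``mu_path``.

    The upper ``mu_path`` tail of the standardized pathway phenotype is
    affected: ``t = Phi^{-1}(1 - mu_path)``.  Monotone decreasing in
    ``mu_path``; boundary proportions are rejected.
    """
    if not 0.0 < mu_path < 1.0:
        raise ValueError(f"mu_path must lie strictly in (0, 1), got {mu_path}")
    return float(stats.norm.isf(mu_path))


@dataclass(frozen=True)
class DiseaseSpec:
    """Truncation specification for the pathway-threshold disease model.

    With ``convention="per_pathway"``, ``mu`` is the per-pathway truncation
    proportion; with ``convention="total"``, ``mu`` is the desired overall
    prevalence under independent pathways and the per-pathway proportion is
    ``1 - (1 - mu)^(1/k)``.
    """

    mu: float
    k: int
    convention: str = "per_pathway"

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"mu must lie strictly in (0, 1), got {self.mu}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.convention not in ("per_pathway", "total"):
            raise ValueError(f"unknown convention {self.convention!r}")

    @property
    def mu_path(self) -> float:
        """Per-pathway truncation proportion."""
        if self.convention == "per_pathway":
            return self.mu
        return 1.0 - (1.0 - self.mu) ** (1.0 / self.k)

    @property
    def mu_total(self) -> float:
        """Overall prevalence implied for independent equal pathways."""
        if self.convention == "total":
            return self.mu
        return 1.0 - (1.0 - self.mu) ** self.k


@dataclass
class DiseaseResult:
    """Disease status and summary rates for a simulated cohort."""

    status: dict                # role -> boolean affected vector
    prevalence: float           # sample prevalence among offspring
    concordance_mz: float       # P(MZ co-twin affected | offspring affected)
    concordance_dz: float
    lambda_mz: float            # recurrence-risk ratio: concordance / prevalence
    lambda_dz: float
    threshold: float


def disease_status(cohort: FamilyCohort, spec: DiseaseSpec) -> DiseaseResult:
    """Assign affection status: any standardized pathway above threshold.

    Pathway phenotypes are standardized with the model means and total
    phenotypic sds before thresholding, so the truncation proportion refers
    to the marginal pathway distribution.  Prevalence is the offspring
    sample rate; concordances are casewise (probandwise with every affected
    reference twin as proband).
    """
    params = cohort.params
    if spec.k != params.k:
        raise ValueError(f"spec.k={spec.k} does not match cohort k={params.k}")
    t = pathway_threshold(spec.mu_path)
    sd = np.sqrt(params.sigma2)

    status = {}
    for name in SIBLING_ROLES:
        z = (cohort.role(name).P - params.mu[None, :]) / sd[None, :]
        status[name] = np.any(z > t, axis=1)

    aff = status["offspring"]
    prevalence = float(np.mean(aff))
    if prevalence == 0.0:
        raise ValueError("no affected offspring: cohort too small for this prevalence")
    conc_mz = float(np.mean(status["mz_twin"][aff]))
    conc_dz = float(np.mean(status["dz_twin"][aff]))
    return DiseaseResult(
        status=status, prevalence=prevalence,
        concordance_mz=conc_mz, concordance_dz=conc_dz,
        lambda_mz=conc_mz / prevalence, lambda_dz=conc_dz / prevalence,
        threshold=t,
    )
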