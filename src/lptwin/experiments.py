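"""Sweep drivers: parameter grids, sensitivity sweeps and the three-trait table.

Every driver returns a long-format :class:`pandas.DataFrame` (one row per
parameter combination) with the LP parameters flattened alongside the
replicate-aggregated estimates and their Monte-Carlo standard errors, ready
for CSV export or plotting.

The default experiment scale is 100,000 families x 50 replicates; a
``fast=True`` switch (20,000 x 10) is provided for desk-scale runs with
correspondingly wider Monte-Carlo error.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationTarget, calibrate
from .estimators import REPLICATE_FIELDS, run_replicates
from .lp_model import CorrelationKind, CorrelationSpec, LPParams

__all__ = ["TABLE1_TRAITS", "fig1_grid", "fig2_sweeps", "table1",
           "FULL_SCALE", "FAST_SCALE"]

FULL_SCALE = {"n_families": 100_000, "n_reps": 50}
FAST_SCALE = {"n_families": 20_000, "n_reps": 10}

#: observed MZ/DZ twin correlations (rMZ, rDZ) for the three illustration
#: traits: height (Danish male twins), blood triglyceride levels (Swedish
#: female twins, 20-29y), and high-fat dairy intake (UK twins, age-adjusted)
TABLE1_TRAITS = {
    "height": (0.89, 0.47),
    "triglycerides": (0.55, 0.28),
    "high_fat_dairy": (0.23, 0.13),
}


def _child_seeds(seed: int | None, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2**31 - 1, size=n)]


def _flatten(params: LPParams, out) -> dict:
    row = {
        "k": params.k,
        "mu": ",".join(f"{m:g}" for m in params.mu),
        "sigma2": ",".join(f"{s:g}" for s in params.sigma2),
        "h2_path": ",".join(f"{h:g}" for h in params.h2_path),
        "c2_path": params.c2_path,
        "corr_kind": params.corr.kind.value,
        "rho": params.corr.rho,
        "combine": params.combine,
    }
    for f in REPLICATE_FIELDS:
        row[f] = out.means[f]
        row[f"{f}_median"] = out.medians[f]
        row[f"{f}_se"] = out.mc_se[f]
    row["n_families"] = out.n_families
    row["n_replicates"] = out.n_replicates
    row["seed"] = out.seed
    return row


def fig1_grid(k_values: Sequence[int] = (1, 2, 3, 5, 10),
              h2_grid: Iterable[float] = np.round(np.arange(0.1, 1.0, 0.1), 2),
              cr_grid: Iterable[float] = np.round(np.arange(0.0, 1.01, 0.1), 2),
              n_families: int = FULL_SCALE["n_families"],
              n_reps: int = FULL_SCALE["n_reps"],
              seed: int | None = None) -> pd.DataFrame:
    """Forward sweep of basic LP models over (k, pathway h2, cr).

    Maps each model's simulated (rMZ, rDZ) to its narrow-sense heritability
    and final-level common-environment proportion, tracing the wedge of
    variance-component combinations consistent with twin data.
    """
    combos = [(k, h2, cr) for k in k_values for h2 in h2_grid for cr in cr_grid]
    seeds = _child_seeds(seed, len(combos))
    rows = []
    for (k, h2, cr), s in zip(combos, seeds):
        params = LPParams.basic(k=k, h2_path=h2, c2_path=cr)
        out = run_replicates(params, n_families=n_families, n_reps=n_reps, seed=s)
        rows.append(_flatten(params, out))
    return pd.DataFrame(rows)


def fig2_sweeps(panel: str, grid: Iterable[float],
                k_values: Sequence[int] = (2, 3, 5, 10),
                h2_path: float = 0.5,
                n_families: int = FULL_SCALE["n_families"],
                n_reps: int = FULL_SCALE["n_reps"],
                seed: int | None = None) -> pd.DataFrame:
    """Sensitivity sweeps of phantom heritability under the extended model.

    Panels:

    ``mean_offset``
        Two equal pathways whose means differ by the swept offset (sd
        units); phantom heritability is maximal at zero offset and falls as
        one pathway comes to dominate the maximum.
    ``var_diff``
        Two pathways, second pathway variance swept; phantom heritability
        is invariant (both tails scale together).
    ``h2_diff``
        Two pathways, second pathway heritability swept, first fixed.
    ``rho_sweep`` / ``rho_sweep_c10``
        Uniformly correlated pathways, rho swept for each k; the ``_c10``
        variant attributes 10% of each pathway's phenotypic variance to
        common environment (``c2_path = 0.1 / (1 - h2_path)``).

    The fixed-parameter choices (k=2, h2_path=0.5, no common environment,
    uncorrelated pathways unless swept) are this package's defaults.
    """
    def make_params(x: float, k: int) -> LPParams:
        if panel == "mean_offset":
            return LPParams(k=2, mu=(0.0, x), h2_path=h2_path)
        if panel == "var_diff":
            return LPParams(k=2, sigma2=(1.0, x), h2_path=h2_path)
        if panel == "h2_diff":
            return LPParams(k=2, h2_path=(h2_path, x))
        if panel in ("rho_sweep", "rho_sweep_c10"):
            c2 = 0.1 / (1.0 - h2_path) if panel == "rho_sweep_c10" else 0.0
            return LPParams(k=k, h2_path=h2_path, c2_path=c2,
                            corr=CorrelationSpec(CorrelationKind.UNIFORM, x))
        raise ValueError(f"unknown panel {panel!r}")

    two_pathway = panel in ("mean_offset", "var_diff", "h2_diff")
    ks = (2,) if two_pathway else tuple(k_values)
    combos = [(x, k) for k in ks for x in grid]
    seeds = _child_seeds(seed, len(combos))
    rows = []
    for (x, k), s in zip(combos, seeds):
        params = make_params(x, k)
        out = run_replicates(params, n_families=n_families, n_reps=n_reps, seed=s)
        row = _flatten(params, out)
        row["panel"] = panel
        row["swept_value"] = x
        rows.append(row)
    return pd.DataFrame(rows)


def table1(trait_targets: dict[str, tuple[float, float]] | None = None,
           k_values: Sequence[int] = (2, 4, 10),
           rho_values: Sequence[float] = (0.0, 0.2),
           n_families: int = FULL_SCALE["n_families"],
           n_reps: int = FULL_SCALE["n_reps"],
           n_reps_search: int = 5,
           seed: int | None = None) -> pd.DataFrame:
    """Three-trait illustration: calibrate each (trait, k, rho) cell.

    For each trait's observed (rMZ, rDZ) and each pathway architecture,
    inverts (h2_path, c2_path) so the simulated twin correlations match the
    observations, then reports phantom heritability, narrow-sense
    heritability and the final-level common-variance proportion.
    """
    traits = trait_targets or TABLE1_TRAITS
    combos = [(t, k, rho) for t in traits for k in k_values for rho in rho_values]
    seeds = _child_seeds(seed, len(combos))
    rows = []
    for (trait, k, rho), s in zip(combos, seeds):
        r_mz, r_dz = traits[trait]
        target = CalibrationTarget(r_mz_obs=r_mz, r_dz_obs=r_dz,
                                   n_families=n_families, n_reps=n_reps,
                                   n_reps_search=n_reps_search, seed=s)
        res = calibrate(k, CorrelationSpec(CorrelationKind.UNIFORM, rho), target)
        row = _flatten(res.outputs.params, res.outputs)
        row.update(trait=trait, r_mz_obs=r_mz, r_dz_obs=r_dz,
                   h2_path_cal=res.h2_path, c2_path_cal=res.c2_path,
                   converged=res.converged)
        rows.append(row)
    cols = ["trait", "r_mz_obs", "r_dz_obs", "k", "rho"]
    df = pd.DataFrame(rows)
    return df[cols + [c for c in df.columns if c not in cols]]
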