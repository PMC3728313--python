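"""Plain-text key-value configuration for LP model parameters.

Configs are YAML-compatible ``key: value`` files.  Vector-valued pathway
parameters accept comma-separated lists; scalars broadcast to all ``k``
pathways.  Example::

    k: 2
    mu: 0, 1.0
    sigma2: 1
    h2_path: 0.5
    c2_path: 0.2
    corr_kind: uniform
    rho: 0.2
    combine: max
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .lp_model import CorrelationSpec, LPParams

__all__ = ["params_from_mapping", "load_params"]

_PARAM_KEYS = {"k", "mu", "sigma2", "h2_path", "c2_path",
               "corr_kind", "rho", "combine"}


def _parse_value(v):
    if isinstance(v, str) and "," in v:
        return [float(x) for x in v.split(",")]
    return v


def params_from_mapping(cfg: dict) -> LPParams:
    """Build :class:`LPParams` from a flat mapping (unknown keys rejected)."""
    unknown = set(cfg) - _PARAM_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {k: _parse_value(v) for k, v in cfg.items()}
    corr = CorrelationSpec(kind=cfg.pop("corr_kind", "uniform"),
                           rho=float(cfg.pop("rho", 0.0)))
    return LPParams(corr=corr, **cfg)


def load_params(path: str | Path) -> LPParams:
    """Read LP parameters from a plain-text key-value (YAML) file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain key: value pairs")
    return params_from_mapping(cfg)
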