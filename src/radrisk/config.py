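"""Structured run configuration.

One YAML document describes a full analysis: the data source (a CSV
table or a synthetic-cohort spec), the baseline structure, the set of
candidate risk models, streamlining/selection options and MMI options.
Command-line flags override scalar entries.

Schema sketch::

    data:
      path: cohort.csv            # or
      synthetic: {seed: 1, ...}   # SyntheticConfig field overrides
      columns: {...}              # optional column-name overrides
    cause: cvd
    baseline:
      intercept: -5.0
      log_age: 5.0                # present key => term included
      sex: 0.0
      free: [intercept, log_age, sex]
      knots: [{position: 70, slope: 0, free_slope: true}]
      agex_knots: []
    streamline:
      enabled: false
      alpha: 0.05
      free_knot_candidates: []
    models:
      - label: err-lnt
        transfer: ERR
        shape: lnt
        params: {err: 0.0}
        free: [err]
        modifier: {age_power: 0.0}
        modifier_free: [age_power]
        profile_threshold: false  # true, or an explicit list of Gy values
    fit: {n_restarts: 3, seed: 0}
    mmi:
      total_n: 10000
      ci: 0.90
      seed: 1
      doses: [0.2, 1.0]
      covariates: {city: hiroshima, sex: male, a: 70, e: 30}
    output: outdir
"""

from __future__ import annotations

import yaml

from .baseline import BaselineModel, Knot
from .cohort import read_table
from .doseresponse import DoseResponse
from .model import RiskModel
from .modifiers import EffectModifier
from .simulate import SyntheticConfig, generate_table

__all__ = ["load_config", "baseline_from_config", "model_from_config",
           "table_from_config", "validate_config"]


def load_config(path):
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg):
    if "data" not in cfg:
        raise ValueError("config needs a 'data' block")
    if "cause" not in cfg:
        raise ValueError("config needs a 'cause'")
    labels = [m.get("label") for m in cfg.get("models", [])]
    if len(labels) != len(set(labels)):
        raise ValueError("model labels must be unique")
    ci = cfg.get("mmi", {}).get("ci", 0.90)
    if not 0.0 < ci < 1.0:
        raise ValueError("mmi.ci must be in (0, 1)")
    return cfg


def table_from_config(cfg, seed=None):
    """Load or generate the person-year table; returns (table, truth)
    with truth None for file input."""
    data = cfg["data"]
    if "path" in data:
        return read_table(data["path"],
                          columns=data.get("columns")), None
    syn = dict(data.get("synthetic", {}))
    if seed is not None:
        syn["seed"] = seed
    return generate_table(SyntheticConfig(**syn))


def baseline_from_config(d):
    d = dict(d or {})
    knots = [Knot(**k) for k in d.pop("knots", [])]
    agex_knots = [Knot(**k) for k in d.pop("agex_knots", [])]
    free = d.pop("free", [])
    return BaselineModel(intercept=d.get("intercept", 0.0),
                         city=d.get("city"), sex=d.get("sex"),
                         agex=d.get("agex"), log_age=d.get("log_age"),
                         knots=knots, agex_knots=agex_knots, free=free)


def model_from_config(d, baseline):
    """Build a RiskModel from one ``models:`` entry, sharing (a copy of)
    the given baseline."""
    shape = d["shape"]
    params = dict(d.get("params", {}))
    dr = DoseResponse(shape, free=d.get("free", []), **params)
    mod_cfg = d.get("modifier", {}) or {}
    modifier = EffectModifier(sex=mod_cfg.get("sex"),
                              age_power=mod_cfg.get("age_power"),
                              agex=mod_cfg.get("agex"),
                              free=d.get("modifier_free", []))
    return RiskModel(d.get("transfer", "ERR"), baseline.copy(), dr,
                     modifier, label=d.get("label"))
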