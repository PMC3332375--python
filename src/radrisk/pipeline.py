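"""End-to-end orchestration: streamline -> fit -> select -> MMI.

:func:`run_pipeline` executes the full workflow described by a run
configuration: optional baseline streamlining with the likelihood-ratio
criterion, per-model fitting (with threshold-grid profiling where the
shape carries a threshold dose), an AIC score table with Akaike
weights, and pooled MMI risk distributions over a dose grid.  Every
number in the plain-text report is recomputable from the bundle's
machine-readable outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (baseline_from_config, model_from_config,
                     table_from_config, validate_config)
from .fitting import fit, profile_threshold, streamline_baseline
from .mmi import mmi_pool, risk_distribution, score_models

__all__ = ["run_pipeline"]

log = logging.getLogger(__name__)


def run_pipeline(cfg, seed=None):
    """Run the configured analysis; returns the report bundle.

    The bundle is a dict with keys ``table``, ``truth``, ``audit``,
    ``fits`` (label -> PoissonRiskResults), ``scores`` (DataFrame
    mirroring a dev/N_par/AIC/weight selection table), ``mmi``
    (long-format DataFrame over the dose grid) and ``report`` (text).
    Failures in one stage leave earlier outputs in place together with
    a ``failures`` list.
    """
    validate_config(cfg)
    fit_opts = dict(cfg.get("fit", {}))
    bundle = {"failures": []}

    table, truth = table_from_config(cfg, seed=seed)
    bundle["table"] = table
    bundle["truth"] = truth
    log.info("table: %d cells, %.0f person-years", len(table),
             table.total_person_years)

    baseline = baseline_from_config(cfg.get("baseline"))
    cause = cfg["cause"]

    sl_cfg = cfg.get("streamline", {})
    bundle["audit"] = []
    if sl_cfg.get("enabled", False):
        probe = model_from_config(cfg["models"][0], baseline)
        reduced, audit = streamline_baseline(
            table, probe, cause, alpha=sl_cfg.get("alpha", 0.05),
            free_knot_candidates=sl_cfg.get("free_knot_candidates", ()),
            free_agex_knot_candidates=sl_cfg.get(
                "free_agex_knot_candidates", ()),
            **fit_opts)
        baseline = reduced.baseline
        bundle["audit"] = audit
        for rec in audit:
            log.info("streamline %(phase)s %(parameter)s "
                     "ddev=%(delta_dev).2f -> %(decision)s", rec)

    fits = {}
    for mcfg in cfg.get("models", []):
        spec = model_from_config(mcfg, baseline)
        try:
            prof = mcfg.get("profile_threshold", False)
            if prof:
                grid = prof if isinstance(prof, (list, tuple)) else None
                best, results = profile_threshold(
                    table, spec, cause, grid=grid,
                    refine=(spec.dose_response.shape == "linear-threshold"),
                    **fit_opts)
                key = "refined" if "refined" in results else best
                res = results[key]
                log.info("model %s: best D_th = %.4g Gy", spec.label, best)
            else:
                res = fit(table, spec, cause, **fit_opts)
            if not res.converged:
                raise RuntimeError("fit did not converge")
            fits[spec.label] = res
            log.info("model %s: dev=%.3f n_par=%d aic=%.3f", spec.label,
                     res.deviance, res.n_par, res.aic)
        except Exception as exc:  # partial bundle on stage failure
            log.error("model %s failed: %s", spec.label, exc)
            bundle["failures"].append({"stage": "fit", "model": spec.label,
                                       "error": str(exc)})
    bundle["fits"] = fits
    if not fits:
        bundle["report"] = _report(bundle)
        return bundle

    scores = score_models(list(fits.values()))
    dev_min = min(s.deviance for s in scores)
    bundle["scores"] = pd.DataFrame(
        [{"model": s.label, "dev": s.deviance,
          "delta_dev": s.deviance - dev_min, "n_par": s.n_par,
          "aic": s.aic, "delta_aic": s.delta_aic, "weight": s.weight}
         for s in scores])

    mmi_cfg = cfg.get("mmi", {})
    rows = []
    if mmi_cfg:
        total_n = int(mmi_cfg.get("total_n", 10_000))
        ci = float(mmi_cfg.get("ci", 0.90))
        mmi_seed = int(mmi_cfg.get("seed", 0)) if seed is None else int(seed)
        cov = dict(mmi_cfg.get("covariates",
                               {"city": "hiroshima", "sex": "male",
                                "a": 70.0, "e": 30.0}))
        for dose in mmi_cfg.get("doses", [1.0]):
            try:
                dists = {}
                for j, (label, res) in enumerate(fits.items()):
                    dists[label] = risk_distribution(
                        res, cov, dose, n=total_n,
                        seed=mmi_seed * 1009 + 7 * j)
                    for which in ("err", "ear"):
                        x = dists[label][which]
                        rows.append({
                            "model": label, "dose_gy": dose,
                            "measure": which, "weight":
                                scores[j].weight,
                            "mean": float(np.mean(x)),
                            "median": float(np.median(x)),
                            "q_lower": float(np.percentile(
                                x, 100 * (1 - ci) / 2)),
                            "q_upper": float(np.percentile(
                                x, 100 * (1 + ci) / 2))})
                pooled = mmi_pool(scores, dists, total_n=total_n, ci=ci)
                for which in ("err", "ear"):
                    st = pooled.summary_stats(which)
                    rows.append({"model": "MMI", "dose_gy": dose,
                                 "measure": which, "weight": 1.0,
                                 "mean": st["mean"], "median": st["median"],
                                 "q_lower": st["lower"],
                                 "q_upper": st["upper"]})
            except Exception as exc:
                log.error("MMI at %s Gy failed: %s", dose, exc)
                bundle["failures"].append({"stage": "mmi",
                                           "dose": dose,
                                           "error": str(exc)})
    bundle["mmi"] = pd.DataFrame(rows)
    bundle["report"] = _report(bundle)

    out = cfg.get("output")
    if out:
        _write_bundle(bundle, Path(out))
    return bundle


def _report(bundle):
    lines = ["radrisk pipeline report", "=" * 40]
    if bundle.get("truth"):
        t = bundle["truth"]
        lines.append(f"synthetic truth: {t['label']} (seed {t['seed']}, "
                     f"expected deaths {t['expected_deaths']:.1f})")
    if bundle.get("audit"):
        lines.append(f"streamlining: {len(bundle['audit'])} tests, "
                     + ", ".join(
                         f"{r['parameter']} {r['decision']}"
                         for r in bundle["audit"]))
    if "scores" in bundle:
        lines.append("")
        lines.append("model selection (dev / N_par / AIC / weight):")
        lines.append(bundle["scores"].to_string(index=False,
                                                float_format="%.4f"))
    mmi = bundle.get("mmi")
    if mmi is not None and len(mmi):
        lines.append("")
        lines.append("risk estimates (per-model and pooled MMI):")
        lines.append(mmi.to_string(index=False, float_format="%.4g"))
    if bundle["failures"]:
        lines.append("")
        lines.append(f"FAILURES: {bundle['failures']}")
    return "\n".join(lines)


def _jsonify(obj):
    # numpy scalars leak into result dicts; json needs plain types
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_bundle(bundle, outdir):
    from .cohort import write_table

    outdir.mkdir(parents=True, exist_ok=True)
    write_table(bundle["table"], outdir / "table.csv")
    if bundle.get("truth"):
        (outdir / "truth.json").write_text(
            json.dumps(bundle["truth"], indent=2, default=_jsonify))
    if bundle.get("audit"):
        (outdir / "streamline_audit.json").write_text(
            json.dumps(bundle["audit"], indent=2, default=_jsonify))
    if "scores" in bundle:
        bundle["scores"].to_csv(outdir / "scores.csv", index=False)
    if bundle.get("mmi") is not None and len(bundle["mmi"]):
        bundle["mmi"].to_csv(outdir / "mmi.csv", index=False)
    fits = {label: res.to_dict()
            for label, res in bundle.get("fits", {}).items()}
    (outdir / "fits.json").write_text(
        json.dumps(fits, indent=2, default=_jsonify))
    (outdir / "report.txt").write_text(bundle["report"])
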