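"""Model selection and multi-model inference (MMI).

Non-nested candidate models are scored by AIC = dev + 2 N_par and
combined with Akaike weights

    p_m = exp(-dAIC_m / 2) / sum_j exp(-dAIC_j / 2),

where dAIC_m is the AIC excess over the best model in the set.  The
weights, multiplied by the total sample size (10^4 by default), give
the number of risk realizations each model contributes to the pooled
uncertainty distribution.  Per-model realizations are produced by
pushing Latin-hypercube samples of the fitted parameters (multivariate
normal, Wald covariance) through the risk definitions ERR = h/h0 - 1
and EAR = h - h0; the pooled distribution yields means, medians and
percentile confidence bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import RiskModel

__all__ = [
    "aic_score", "akaike_weights", "ModelScore", "score_models",
    "lhs_parameter_samples", "risk_distribution", "allocate_samples",
    "mmi_pool", "mmi_dose_response", "MMIResult",
]

log = logging.getLogger(__name__)

#: default total number of pooled realizations
DEFAULT_TOTAL_N = 10_000


def aic_score(deviance, n_par):
    """AIC = deviance + 2 * number of model parameters."""
    if n_par < 0:
        raise ValueError("n_par must be >= 0")
    return float(deviance) + 2.0 * int(n_par)


def akaike_weights(aics):
    """Akaike weights from a list of AIC values (shift invariant,
    sums to 1)."""
    aics = np.asarray(aics, dtype=float)
    if aics.size == 0 or not np.all(np.isfinite(aics)):
        raise ValueError("need a non-empty list of finite AIC values")
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelScore:
    """One row of a model-selection table."""
    label: str
    deviance: float
    n_par: int
    aic: float
    delta_aic: float
    weight: float


def score_models(entries):
    """Score a model set.

    ``entries`` is a sequence of fit results (anything with ``deviance``
    and ``n_par`` attributes plus an identifying label) or of
    ``(label, deviance, n_par)`` triples.

    Returns a list of :class:`ModelScore` in input order.
    """
    rows = []
    for ent in entries:
        if isinstance(ent, tuple):
            label, dev, n_par = ent
        else:
            label = getattr(ent, "label", None) or \
                ent.model.risk_model.label
            dev, n_par = ent.deviance, ent.n_par
        rows.append((str(label), float(dev), int(n_par)))
    aics = np.array([aic_score(d, p) for _, d, p in rows])
    weights = akaike_weights(aics)
    amin = aics.min()
    return [ModelScore(label=lab, deviance=dev, n_par=p, aic=float(a),
                       delta_aic=float(a - amin), weight=float(w))
            for (lab, dev, p), a, w in zip(rows, aics, weights)]


def _psd_transform(cov):
    """Matrix L with L L^T = cov, repairing indefiniteness by clipping
    negative eigenvalues at zero (logged)."""
    cov = np.asarray(cov, dtype=float)
    if cov.size == 0:
        return cov.reshape(0, 0)
    evals, evecs = np.linalg.eigh(0.5 * (cov + cov.T))
    if np.any(evals < -1e-10 * max(evals.max(), 1.0)):
        log.warning("covariance not PSD; clipping %d negative eigenvalues",
                    int(np.sum(evals < 0)))
    evals = np.clip(evals, 0.0, None)
    return evecs @ np.diag(np.sqrt(evals))


def lhs_parameter_samples(result, n, seed):
    """Latin-hypercube samples of the fitted parameters.

    Draws ``n`` vectors from the multivariate normal centred at the
    estimates with the Wald covariance.  Each coordinate's underlying
    standard normal is stratified so its marginal hits each of the
    ``n`` equiprobable probability bins exactly once; correlations are
    induced by the linear transform L (with L L^T the covariance)
    applied to the stratified normals.

    Parameters
    ----------
    result : PoissonRiskResults
        Must carry an available covariance.
    n : int
    seed : int or numpy Generator

    Returns
    -------
    ndarray of shape (n, n_par), columns ordered as ``result.names``.
    """
    if result.covariance is None:
        raise ValueError("covariance unavailable; cannot sample")
    rng = np.random.default_rng(seed)
    k = result.n_par
    mean = result.theta
    if k == 0:
        return np.empty((int(n), 0))
    z = np.empty((int(n), k))
    for j in range(k):
        u = (rng.permutation(int(n)) + rng.uniform(size=int(n))) / int(n)
        z[:, j] = stats.norm.ppf(u)
    L = _psd_transform(result.covariance)
    return mean + z @ L.T


def risk_distribution(result, covariates, D, n=DEFAULT_TOTAL_N, seed=0,
                      max_bad_fraction=0.10):
    """Uncertainty distribution of (ERR, EAR) at one covariate point.

    Each sampled parameter vector is evaluated through the hazard; the
    risk realizations follow ERR = h/h0 - 1, EAR = h - h0.  Draws that
    make the hazard nonpositive are regenerated from the unstratified
    multivariate normal (their count is logged); more than
    ``max_bad_fraction`` inadmissible draws raises, signalling an
    unstable fit.

    Parameters
    ----------
    result : PoissonRiskResults
    covariates : dict
        ``{"city": ..., "sex": ..., "a": years, "e": years}``.
    D : float
        Dose in Gy.

    Returns
    -------
    dict with ``"err"`` and ``"ear"`` arrays of length ``n`` (EAR per
    person-year).
    """
    rm = result.risk_model
    names = result.names
    city, sex = covariates["city"], covariates["sex"]
    a, e = covariates["a"], covariates["e"]
    n = int(n)

    samples = lhs_parameter_samples(result, n, seed)
    if samples.shape[1] == 0:
        err, ear = rm.risk(city, sex, a, e, D)
        return {"err": np.full(n, float(err)),
                "ear": np.full(n, float(ear))}

    def evaluate(block):
        values = {nm: block[:, j] for j, nm in enumerate(names)}
        return rm.risk(city, sex, a, e, D, values=values, check=False)

    err, ear = evaluate(samples)
    h_ok = np.isfinite(err) & np.isfinite(ear) & (1.0 + err > 0)
    n_bad = int(np.sum(~h_ok))
    if n_bad:
        if n_bad > max_bad_fraction * n:
            raise RuntimeError(
                f"{n_bad}/{n} inadmissible realizations; fit too unstable "
                "for Wald-based propagation")
        log.info("regenerating %d inadmissible realizations", n_bad)
        rng = np.random.default_rng(None if seed is None else seed + 1)
        L = _psd_transform(result.covariance)
        bad = np.where(~h_ok)[0]
        for _ in range(100):
            z = rng.standard_normal((len(bad), len(names)))
            redraw = result.theta + z @ L.T
            e2, a2 = evaluate(redraw)
            ok = np.isfinite(e2) & np.isfinite(a2) & (1.0 + e2 > 0)
            err[bad[ok]] = e2[ok]
            ear[bad[ok]] = a2[ok]
            bad = bad[~ok]
            if bad.size == 0:
                break
        else:
            raise RuntimeError("could not regenerate admissible draws")
    return {"err": np.asarray(err, float), "ear": np.asarray(ear, float)}


def allocate_samples(weights, total=DEFAULT_TOTAL_N):
    """Integer sample allocation proportional to weights, summing to
    ``total`` exactly (largest-remainder rounding)."""
    weights = np.asarray(weights, dtype=float)
    raw = weights / weights.sum() * int(total)
    base = np.floor(raw).astype(int)
    short = int(total) - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


class MMIResult:
    """Pooled multi-model risk distribution at one covariate point.

    Attributes
    ----------
    allocations : dict
        label -> number of pooled realizations (sums to ``total_n``).
    pooled : dict
        ``"err"`` / ``"ear"`` arrays of length ``total_n``.
    ci : float
        Central confidence level of the reported bounds.
    """

    def __init__(self, scores, allocations, pooled, ci=0.90):
        self.scores = list(scores)
        self.allocations = dict(allocations)
        self.pooled = pooled
        self.ci = float(ci)
        self.total_n = int(sum(allocations.values()))

    def summary_stats(self, which="err"):
        """mean / median / lower / upper percentile bounds of the pooled
        distribution (empirical percentiles, linear interpolation)."""
        x = self.pooled[which]
        lo = 100 * (1 - self.ci) / 2
        return {
            "mean": float(np.mean(x)),
            "median": float(np.median(x)),
            "lower": float(np.percentile(x, lo)),
            "upper": float(np.percentile(x, 100 - lo)),
        }

    def summary(self):
        lines = [f"MMI pooled distribution (n = {self.total_n}, "
                 f"{100 * self.ci:.0f}% CI)"]
        for s in self.scores:
            lines.append(f"  {s.label:<28s} weight {s.weight:.4f}  "
                         f"samples {self.allocations[s.label]}")
        for which in ("err", "ear"):
            st = self.summary_stats(which)
            lines.append(
                f"  {which.upper():<4s} mean {st['mean']:.4g}  median "
                f"{st['median']:.4g}  CI ({st['lower']:.4g}, "
                f"{st['upper']:.4g})")
        return "\n".join(lines)


def mmi_pool(scores, distributions, total_n=DEFAULT_TOTAL_N, ci=0.90):
    """Merge per-model risk distributions into one pooled distribution.

    Parameters
    ----------
    scores : list of ModelScore
        Weights must sum to 1 (as produced by :func:`score_models`).
    distributions : dict
        label -> ``{"err": array, "ear": array}`` evaluated at identical
        covariates; each array must hold at least the model's allocated
        number of realizations.
    total_n : int
        Pooled sample size (default 10^4).
    ci : float
        Central confidence level for the percentile bounds.
    """
    labels = [s.label for s in scores]
    missing = set(labels) - set(distributions)
    if missing:
        raise ValueError(f"missing distributions for {sorted(missing)}")
    weights = np.array([s.weight for s in scores])
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    alloc = allocate_samples(weights, total_n)
    pooled = {}
    for which in ("err", "ear"):
        parts = []
        for lab, m in zip(labels, alloc):
            x = np.asarray(distributions[lab][which], dtype=float)
            if x.size < m:
                raise ValueError(
                    f"distribution for {lab!r} has {x.size} < {m} samples")
            parts.append(x[:m])
        pooled[which] = np.concatenate(parts) if parts else np.empty(0)
    return MMIResult(scores, dict(zip(labels, alloc.tolist())), pooled,
                     ci=ci)


def mmi_dose_response(scores, models, D):
    """Weight-averaged point dose-response across the model set.

    err_MMI(D) = sum_m p_m err_m(D); valid only when all members share
    the transfer type, and usable as a fixed dose-response inside the
    Poisson deviance to score the MMI curve itself.
    """
    if len(scores) != len(models):
        raise ValueError("scores and models must align")
    transfers = {m.transfer if isinstance(m, RiskModel) else "?"
                 for m in models}
    if len(transfers) > 1:
        raise ValueError(f"mixed transfer types {sorted(transfers)}")
    out = 0.0
    for s, m in zip(scores, models):
        dr = m.dose_response if isinstance(m, RiskModel) else m
        out = out + s.weight * dr.evaluate(D)
    return out
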