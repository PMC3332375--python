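"""Grouped Poisson regression of risk models.

The fitting objective is the grouped Poisson deviance

    dev = 2 * sum_i [ d_i ln(d_i / lam_i) - (d_i - lam_i) ],
    lam_i = h(cell_i) * person_years_i,

with the ``d ln(d/lam)`` term taken as 0 for empty cells (the standard
saturated-model convention), so dev >= 0 with equality iff the model
reproduces every cell count exactly.  Minimisation is derivative-free
(Nelder-Mead) with perturbed restarts; Wald standard errors come from
the observed information: the covariance of the estimates is twice the
inverse Hessian of the deviance at the optimum.

Model comparison uses likelihood-ratio tests for nested models (the
deviance difference is chi-square distributed; at the 5% level one
extra parameter must buy at least 3.84 deviance points) and AIC for
non-nested ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import xlogy

from .baseline import Knot
from .model import EvaluationError, RiskModel

__all__ = [
    "poisson_deviance", "PoissonRiskModel", "PoissonRiskResults", "fit",
    "profile_threshold", "default_threshold_grid", "lrt_improves",
    "LRTResult", "streamline_baseline", "deviance_decomposition",
]

#: deviance returned for inadmissible parameter points during fitting
_PENALTY = 1.0e10


def _deviance_terms(deaths, lam):
    if np.any(lam <= 0):
        raise EvaluationError("nonpositive expected deaths")
    return 2.0 * (xlogy(deaths, deaths / lam) - (deaths - lam))


def poisson_deviance(table, model, cause):
    """Grouped Poisson deviance of ``model`` on ``table`` for ``cause``."""
    city, sex, a, e, D, pyr, deaths = table.arrays(cause)
    lam = model.hazard(city, sex, a, e, D) * pyr
    return float(np.sum(_deviance_terms(deaths, lam)))


def deviance_decomposition(table, model, cause, dose_bins, age_bins,
                           right_closed=False):
    """Per-(dose, attained-age)-group deviance contributions.

    Each cell's deviance term is assigned to its (dose, age) group by
    the cell means; group sums add to :func:`poisson_deviance` exactly.

    Returns a DataFrame indexed by (dose_bin, age_bin) with columns
    ``deviance``, ``person_years``, ``deaths``, ``expected``.
    """
    from .cohort import stratify_totals  # reuse the binning convention

    city, sex, a, e, D, pyr, deaths = table.arrays(cause)
    lam = model.hazard(city, sex, a, e, D) * pyr
    terms = _deviance_terms(deaths, lam)

    base = stratify_totals(table, dose_bins, age_bins, cause,
                           right_closed=right_closed)
    dose_bins = np.asarray(dose_bins, float)
    age_bins = np.asarray(age_bins, float)
    side = "left" if right_closed else "right"
    i = np.searchsorted(dose_bins, D, side=side) - 1
    j = np.searchsorted(age_bins, a, side=side) - 1
    if right_closed:
        i[D == dose_bins[0]] = 0
        j[a == age_bins[0]] = 0

    dev = np.zeros((len(dose_bins) - 1, len(age_bins) - 1))
    lam_sum = np.zeros_like(dev)
    np.add.at(dev, (i, j), terms)
    np.add.at(lam_sum, (i, j), lam)
    out = base.copy()
    out["deviance"] = dev.reshape(-1)
    out["expected"] = lam_sum.reshape(-1)
    return out[["deviance", "person_years", "deaths", "expected"]]


@dataclass
class LRTResult:
    """Outcome of a likelihood-ratio test between nested fits."""
    improves: bool
    delta_dev: float
    critical: float
    p_value: float
    extra_par: int


def lrt_improves(dev_full, dev_reduced, extra_par, alpha=0.05,
                 tolerance=1e-6):
    """Does the larger (full) model significantly improve on the
    reduced one?

    The deviance difference of nested Poisson models is chi-square
    distributed with ``extra_par`` degrees of freedom; the full model
    is declared an improvement iff the deviance drops by at least the
    (1 - alpha) quantile -- 3.84 points for one parameter at the 5%
    level, boundary inclusive.
    """
    if extra_par < 1:
        raise ValueError("extra_par must be >= 1")
    delta = float(dev_reduced) - float(dev_full)
    if delta < -tolerance:
        raise ValueError(
            f"reduced-model deviance {dev_reduced} below full-model "
            f"deviance {dev_full}: models are not nested as stated")
    delta = max(delta, 0.0)
    # the decision threshold is quoted at the two decimals conventional
    # in this field (3.84 for 1 df, 5.99 for 2 df), boundary inclusive
    critical = round(float(stats.chi2.ppf(1.0 - alpha, extra_par)), 2)
    p = float(stats.chi2.sf(delta, extra_par))
    return LRTResult(improves=bool(delta >= critical), delta_dev=delta,
                     critical=critical, p_value=p, extra_par=extra_par)


class PoissonRiskModel:
    """Grouped Poisson regression model, statsmodels style.

    Built from data (a :class:`~radrisk.cohort.PersonYearTable`), a
    :class:`~radrisk.model.RiskModel` specification carrying
    free-parameter flags, and a cause label; :meth:`fit` returns a
    :class:`PoissonRiskResults`.

    Parameters
    ----------
    table : PersonYearTable
    risk_model : RiskModel
        Starting values are taken from the specification's current
        parameter values.
    cause : str
        Cause label (must be one of ``table.causes``).
    """

    def __init__(self, table, risk_model, cause):
        if cause not in table.causes:
            raise ValueError(f"cause {cause!r} not in table causes "
                             f"{table.causes}")
        self.table = table
        self.risk_model = risk_model
        self.cause = cause
        (self._city, self._sex, self._a, self._e, self._D,
         self._pyr, self._deaths) = table.arrays(cause)

    @property
    def free_names(self):
        return list(self.risk_model.free_parameters())

    def deviance(self, theta=None):
        """Deviance at free-parameter vector ``theta`` (current values
        if omitted); inadmissible points return a large penalty."""
        values = None
        if theta is not None:
            values = dict(zip(self.free_names, np.asarray(theta, float)))
        try:
            lam = self.risk_model.hazard(self._city, self._sex, self._a,
                                         self._e, self._D,
                                         values=values) * self._pyr
            dev = float(np.sum(_deviance_terms(self._deaths, lam)))
        except (EvaluationError, FloatingPointError):
            return _PENALTY
        if not np.isfinite(dev):
            return _PENALTY
        return dev

    def fit(self, n_restarts=3, tol=1e-6, maxfev=10_000, seed=0,
            perturb=0.1):
        """Minimise the deviance over the free parameters.

        Nelder-Mead with ``n_restarts`` perturbed restarts (relative
        perturbation ``perturb``, deterministic given ``seed``); the
        best optimum is kept.  Convergence tolerance is ``tol`` on the
        deviance change.  Returns a :class:`PoissonRiskResults`; with
        no free parameters the result is the evaluated deviance with
        ``n_par = 0``.
        """
        names = self.free_names
        start = np.array([self.risk_model.free_parameters()[n]
                          for n in names], dtype=float)
        if not names:
            dev = self.deviance()
            return PoissonRiskResults(
                model=self, params={}, theta=np.empty(0), deviance=dev,
                converged=bool(dev < _PENALTY), n_evaluations=1,
                covariance=np.empty((0, 0)))

        rng = np.random.default_rng(seed)
        starts = [start]
        for _ in range(max(0, int(n_restarts))):
            starts.append(start + perturb * np.maximum(np.abs(start), 1.0)
                          * rng.standard_normal(len(start)))

        # hybrid contract: quasi-Newton first (fast on the smooth
        # log-linear surface), then a simplex polish that is robust to
        # the kinks of the threshold shapes; the best optimum wins
        best = None
        n_eval = 0
        for s in starts:
            qn = optimize.minimize(self.deviance, s, method="BFGS",
                                   options={"maxiter": int(maxfev)})
            n_eval += qn.nfev
            res = optimize.minimize(
                self.deviance, qn.x if np.isfinite(qn.fun) else s,
                method="Nelder-Mead",
                options={"fatol": tol, "xatol": 1e-8,
                         "maxfev": int(maxfev), "adaptive": len(s) > 4})
            n_eval += res.nfev
            if np.isfinite(qn.fun) and qn.fun < res.fun:
                res = qn
            if best is None or res.fun < best.fun:
                best = res
        converged = bool(best.success and best.fun < _PENALTY)
        theta = np.asarray(best.x, dtype=float)

        cov = self._covariance(theta) if converged else None
        result = PoissonRiskResults(
            model=self, params=dict(zip(names, theta)), theta=theta,
            deviance=float(best.fun), converged=converged,
            n_evaluations=n_eval, covariance=cov)
        return result

    def _covariance(self, theta, rel_step=1e-4):
        """Wald covariance = 2 * inverse deviance Hessian, Hessian by
        central finite differences; None when singular/indefinite."""
        k = len(theta)
        h = rel_step * np.maximum(np.abs(theta), 1.0)
        H = np.empty((k, k))
        f0 = self.deviance(theta)
        if f0 >= _PENALTY:
            return None
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                if i == j:
                    fpp = self.deviance(theta + ei)
                    fmm = self.deviance(theta - ei)
                    H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
                else:
                    fpp = self.deviance(theta + ei + ej)
                    fpm = self.deviance(theta + ei - ej)
                    fmp = self.deviance(theta - ei + ej)
                    fmm = self.deviance(theta - ei - ej)
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (
                        4 * h[i] * h[j])
        if not np.all(np.isfinite(H)) or np.any(np.abs(H) >= _PENALTY / 10):
            return None
        try:
            cov = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None
        if np.any(np.diag(cov) < 0):
            return None
        return 0.5 * (cov + cov.T)


class PoissonRiskResults:
    """Fit results: estimates, Wald uncertainties, deviance, AIC.

    Attributes
    ----------
    params : dict
        Free-parameter estimates by prefixed name (optimizer scale for
        free knot positions).
    deviance : float
    n_par : int
        Number of free parameters (free knots count).
    converged : bool
    n_evaluations : int
    covariance : ndarray or None
        Wald covariance over the free parameters; ``None`` when the
        observed information was singular.
    """

    def __init__(self, model, params, theta, deviance, converged,
                 n_evaluations, covariance):
        self.model = model
        self.params = dict(params)
        self.theta = np.asarray(theta, dtype=float)
        self.deviance = float(deviance)
        self.converged = converged
        self.n_evaluations = int(n_evaluations)
        self.covariance = covariance
        # fitted copy of the specification with estimates written back
        self.risk_model = model.risk_model.copy()
        if self.params:
            self.risk_model.set_values(self.params)

    @property
    def names(self):
        return list(self.params)

    @property
    def n_par(self):
        return len(self.params)

    @property
    def aic(self):
        """AIC = deviance + 2 * number of free parameters."""
        return self.deviance + 2.0 * self.n_par

    @property
    def wald_se(self):
        """Wald standard errors by parameter name (NaN when the
        covariance is unavailable)."""
        if self.covariance is None:
            return {n: float("nan") for n in self.names}
        se = np.sqrt(np.diag(self.covariance))
        return dict(zip(self.names, se))

    def cov_params(self):
        if self.covariance is None:
            return None
        return pd.DataFrame(self.covariance, index=self.names,
                            columns=self.names)

    def summary(self):
        """Human-readable fit report."""
        lines = [
            f"Grouped Poisson fit: {self.model.risk_model.label}",
            f"  cause: {self.model.cause}   cells: "
            f"{len(self.model.table)}",
            f"  deviance: {self.deviance:.4f}   N_par: {self.n_par}   "
            f"AIC: {self.aic:.4f}",
            f"  converged: {self.converged}   evaluations: "
            f"{self.n_evaluations}",
            "  {:<22s} {:>12s} {:>12s}".format("parameter", "estimate",
                                               "wald se"),
        ]
        se = self.wald_se
        for n in self.names:
            lines.append("  {:<22s} {:>12.6g} {:>12.6g}".format(
                n, self.params[n], se[n]))
        return "\n".join(lines)

    def to_dict(self):
        return {
            "label": self.model.risk_model.label,
            "cause": self.model.cause,
            "transfer": self.model.risk_model.transfer,
            "shape": self.model.risk_model.dose_response.shape,
            "deviance": self.deviance,
            "n_par": self.n_par,
            "aic": self.aic,
            "converged": bool(self.converged),
            "params": {k: float(v) for k, v in self.params.items()},
            "wald_se": {k: float(v) for k, v in self.wald_se.items()},
            "covariance": (None if self.covariance is None
                           else self.covariance.tolist()),
        }


def fit(table, risk_model, cause, **options):
    """Convenience wrapper: build the model and fit in one call."""
    return PoissonRiskModel(table, risk_model, cause).fit(**options)


def default_threshold_grid():
    """The threshold-dose search grid in Gy: 0.0001-0.0005 by 0.0001,
    0.001, 0.005, 0.01-0.09 by 0.01, 0.1-0.9 by 0.1, 1 and 2 Gy
    (27 values)."""
    grid = ([0.0001, 0.0002, 0.0003, 0.0004, 0.0005, 0.001, 0.005]
            + [round(0.01 * k, 2) for k in range(1, 10)]
            + [round(0.1 * k, 1) for k in range(1, 10)]
            + [1.0, 2.0])
    return grid


def profile_threshold(table, risk_model, cause, grid=None, refine=False,
                      **options):
    """Profile the deviance over a grid of threshold doses.

    At each grid value ``D_th`` is held fixed and all other free
    parameters are refit; the grid value with the smallest deviance
    wins (ties break toward the lowest dose).  With ``refine=True``
    (meant for the linear-threshold shape, where the kink makes a free
    threshold well behaved) the best grid point seeds one final fit
    with ``D_th`` free.

    Returns
    -------
    best_dth : float
    results : dict
        Mapping grid value -> :class:`PoissonRiskResults`; with
        ``refine=True`` the extra key ``"refined"`` holds the free-
        threshold fit.
    """
    if grid is None:
        grid = default_threshold_grid()
    grid = list(grid)
    if not grid or any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and ascending")
    if "D_th" not in risk_model.dose_response.params:
        raise ValueError(
            f"shape {risk_model.dose_response.shape!r} has no threshold")

    results = {}
    best_dth, best_dev = None, np.inf
    for dth in grid:
        spec = risk_model.copy()
        spec.dose_response.params["D_th"] = float(dth)
        if "D_th" in spec.dose_response.free:
            spec.dose_response.free.remove("D_th")
        res = fit(table, spec, cause, **options)
        results[dth] = res
        if res.converged and res.deviance < best_dev:
            best_dth, best_dev = dth, res.deviance
    if best_dth is None:
        raise RuntimeError("all grid fits failed to converge")

    if refine:
        spec = results[best_dth].risk_model.copy()
        if "D_th" not in spec.dose_response.free:
            spec.dose_response.free.append("D_th")
        res = fit(table, spec, cause, **options)
        if res.converged and res.deviance <= best_dev:
            results["refined"] = res
            best_dth = float(res.risk_model.dose_response.params["D_th"])
    return best_dth, results


def streamline_baseline(table, risk_model, cause, alpha=0.05,
                        protected=("intercept",), free_knot_candidates=(),
                        free_agex_knot_candidates=(), **options):
    """Backward elimination of baseline parameters, then knot freeing.

    Every free baseline coefficient (scalar terms and knot slope
    changes, minus ``protected``) is tested by fixing it at zero and
    refitting everything else; after each sweep the least significant
    parameter whose removal costs less than the chi-square critical
    value (3.84 at alpha = 0.05) is dropped, and sweeps repeat to a
    fixed point.  Then each candidate knot position (by index into the
    baseline's attained-age / age-at-exposure knots) is freed and kept
    only if it buys at least the critical value per added parameter.

    Returns
    -------
    reduced : RiskModel
        The streamlined specification with fitted values.
    audit : list of dict
        One record per test: phase, parameter, delta_dev, critical,
        decision.
    """
    critical = round(float(stats.chi2.ppf(1.0 - alpha, 1)), 2)
    current = risk_model.copy()
    audit = []
    res = fit(table, current, cause, **options)
    current.set_values(res.params)  # later refits start warm

    def eliminate_candidates(spec):
        names = []
        for n in spec.baseline.free_scalars:
            if n not in protected:
                names.append(f"bl.{n}")
        for i, k in enumerate(spec.baseline.knots):
            if k.free_slope:
                names.append(f"bl.knot{i}_slope")
        for i, k in enumerate(spec.baseline.agex_knots):
            if k.free_slope:
                names.append(f"bl.agex_knot{i}_slope")
        return names

    def remove(spec, name):
        # fix the parameter at its null value (0)
        term = name.split(".", 1)[1]
        if term in spec.baseline.SCALAR_TERMS:
            spec.baseline.exclude(term)
        elif term.startswith("agex_knot"):
            i = int(term[len("agex_knot"):].split("_")[0])
            spec.baseline.agex_knots[i].slope = 0.0
            spec.baseline.agex_knots[i].free_slope = False
        else:
            i = int(term[len("knot"):].split("_")[0])
            spec.baseline.knots[i].slope = 0.0
            spec.baseline.knots[i].free_slope = False

    # phase 1: backward elimination, least significant first
    while True:
        candidates = eliminate_candidates(current)
        if not candidates:
            break
        trials = []
        for name in candidates:
            trial = current.copy()
            remove(trial, name)
            trial_res = fit(table, trial, cause, **options)
            delta = trial_res.deviance - res.deviance
            trials.append((delta, name, trial, trial_res))
        trials.sort(key=lambda t: t[0])
        delta, name, trial, trial_res = trials[0]
        decision = "removed" if delta < critical else "retained"
        audit.append({"phase": "eliminate", "parameter": name,
                      "delta_dev": float(max(delta, 0.0)),
                      "critical": critical, "decision": decision})
        for d, n, _, _ in trials[1:]:
            audit.append({"phase": "eliminate", "parameter": n,
                          "delta_dev": float(max(d, 0.0)),
                          "critical": critical, "decision": "retained"})
        if decision == "removed":
            trial.set_values(trial_res.params)
            current, res = trial, trial_res
        else:
            break

    # phase 2: try freeing candidate knot positions
    for group_name, indices in (("knot", free_knot_candidates),
                                ("agex_knot", free_agex_knot_candidates)):
        for i in indices:
            trial = current.copy()
            knots = (trial.baseline.knots if group_name == "knot"
                     else trial.baseline.agex_knots)
            if knots[i].free_position:
                continue
            knots[i].free_position = True
            trial_res = fit(table, trial, cause, **options)
            delta = res.deviance - trial_res.deviance
            keep = delta >= critical
            audit.append({"phase": "free-knot",
                          "parameter": f"bl.{group_name}{i}_pos",
                          "delta_dev": float(max(delta, 0.0)),
                          "critical": critical,
                          "decision": "freed" if keep else "kept fixed"})
            if keep:
                trial.set_values(trial_res.params)
                current, res = trial, trial_res

    current.set_values(res.params)
    return current, audit
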