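"""Baseline (zero-dose) hazard models.

The baseline is log-linear: a piecewise-linear spline in ln(attained
age) with continuity at every knot (guaranteed by the truncated-basis
construction), additive city/sex intercept offsets and age-at-exposure
(birth-cohort) terms on the log scale.  Every term can be flagged free
(estimated) or fixed, and knot positions themselves may be freed; a
free knot enters the optimizer through a monotone logistic
reparameterization squashed between its neighbouring fixed knots (or
the age domain bounds), so knot ordering can never be violated during
a fit.

log h0(city, sex, a, e) =
    intercept
    + city * 1[Nagasaki] + sex * 1[female]
    + log_age * ln(a / 70)
    + sum_k knot{k}_slope * max(0, ln a - ln t_k)
    + agex * (e - 30) / 10
    + sum_j agex_knot{j}_slope * max(0, e - u_j) / 10

with t_k the attained-age knots (years) and u_j the age-at-exposure
knots (years).  The hazard h0 = exp(log h0) is in deaths per
person-year and strictly positive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

__all__ = ["Knot", "BaselineModel", "AGE_BOUNDS", "AGEX_BOUNDS"]

#: admissible range for free attained-age knots, years
AGE_BOUNDS = (18.0, 110.0)
#: admissible range for free age-at-exposure knots, years
AGEX_BOUNDS = (0.0, 80.0)


@dataclass
class Knot:
    """A spline knot: position in years, slope change across it, and
    free/fixed flags for each."""
    position: float
    slope: float = 0.0
    free_slope: bool = False
    free_position: bool = False


class BaselineModel:
    """Configurable log-linear baseline hazard.

    Parameters
    ----------
    intercept : float
        Log-hazard at the reference covariates (Hiroshima male,
        a = 70, e = 30), log(deaths per person-year).
    city, sex, agex : float or None
        Additive log-hazard coefficients (offset for Nagasaki, offset
        for female, slope per decade of ``e - 30``).  ``None`` excludes
        the term structurally.
    log_age : float or None
        Slope in ln(a/70) below the first knot.
    knots : sequence of Knot
        Attained-age knots, strictly increasing positions.
    agex_knots : sequence of Knot
        Age-at-exposure knots (slope changes per decade).
    free : iterable of str
        Names of scalar coefficients to estimate, from
        {"intercept", "city", "sex", "agex", "log_age"}.
    """

    SCALAR_TERMS = ("intercept", "city", "sex", "agex", "log_age")

    def __init__(self, intercept=0.0, city=None, sex=None, agex=None,
                 log_age=None, knots=(), agex_knots=(), free=()):
        self.values = {"intercept": float(intercept)}
        self.included = {"intercept": True}
        for name, val in (("city", city), ("sex", sex), ("agex", agex),
                          ("log_age", log_age)):
            self.included[name] = val is not None
            self.values[name] = float(val) if val is not None else 0.0

        self.knots = [Knot(**k) if isinstance(k, dict) else k for k in knots]
        self.agex_knots = [Knot(**k) if isinstance(k, dict) else k
                           for k in agex_knots]
        for group, bounds in ((self.knots, AGE_BOUNDS),
                              (self.agex_knots, AGEX_BOUNDS)):
            pos = [k.position for k in group]
            if any(np.diff(pos) <= 0):
                raise ValueError("knot positions must be strictly increasing")
            for k in group:
                if not bounds[0] <= k.position <= bounds[1]:
                    raise ValueError(
                        f"knot position {k.position} outside {bounds}")

        free = set(free)
        bad = free - set(self.SCALAR_TERMS)
        if bad:
            raise ValueError(f"unknown free terms {sorted(bad)}")
        for name in free:
            if not self.included[name]:
                raise ValueError(f"term {name!r} is excluded, cannot be free")
        self.free_scalars = [n for n in self.SCALAR_TERMS if n in free]

    # -- parameter plumbing -------------------------------------------
    def _knot_groups(self):
        yield "knot", self.knots, AGE_BOUNDS
        yield "agex_knot", self.agex_knots, AGEX_BOUNDS

    def free_parameters(self):
        """Ordered mapping name -> initial optimizer-scale value of
        every free parameter (free knot positions are logistic-
        transformed)."""
        out = {n: self.values[n] for n in self.free_scalars}
        for prefix, group, bounds in self._knot_groups():
            for i, k in enumerate(group):
                if k.free_slope:
                    out[f"{prefix}{i}_slope"] = k.slope
                if k.free_position:
                    lo, hi = self._position_window(group, i, bounds)
                    frac = np.clip((k.position - lo) / (hi - lo),
                                   1e-6, 1 - 1e-6)
                    out[f"{prefix}{i}_pos"] = float(logit(frac))
        return out

    @staticmethod
    def _position_window(group, i, bounds):
        """Neighbouring fixed-knot positions (or domain bounds) that
        bracket free knot i."""
        lo, hi = bounds
        for j in range(i - 1, -1, -1):
            if not group[j].free_position:
                lo = group[j].position
                break
        for j in range(i + 1, len(group)):
            if not group[j].free_position:
                hi = group[j].position
                break
        return lo, hi

    def _resolved_knots(self, group, bounds, prefix, values):
        """(positions, slopes) with any free-parameter overrides applied
        and positions sorted (adjacent free knots sharing a window are
        order-symmetric, so sorting is a pure relabelling)."""
        pos, slope = [], []
        for i, k in enumerate(group):
            p, s = k.position, k.slope
            if values:
                if f"{prefix}{i}_slope" in values:
                    s = values[f"{prefix}{i}_slope"]
                if f"{prefix}{i}_pos" in values:
                    lo, hi = self._position_window(group, i, bounds)
                    p = lo + (hi - lo) * expit(values[f"{prefix}{i}_pos"])
            pos.append(p)
            slope.append(s)
        order = np.argsort(np.asarray(pos, dtype=float), kind="stable")
        return ([pos[j] for j in order], [slope[j] for j in order])

    def knot_positions(self, values=None):
        """Attained-age knot positions in years after applying
        optimizer-scale overrides."""
        return self._resolved_knots(self.knots, AGE_BOUNDS, "knot",
                                    values or {})[0]

    # -- evaluation ----------------------------------------------------
    def log_hazard(self, city, sex, a, e, values=None):
        """Log baseline hazard, vectorised over cells and over
        parameter-value arrays in ``values``."""
        a = np.asarray(a, dtype=float)
        if np.any(a <= 0):
            raise ValueError("attained age must be > 0")
        e = np.asarray(e, dtype=float)
        v = dict(self.values)
        if values:
            for name in self.SCALAR_TERMS:
                if name in values:
                    v[name] = values[name]

        is_nagasaki = (np.asarray(city) == "nagasaki").astype(float)
        is_female = (np.asarray(sex) == "female").astype(float)

        lh = v["intercept"] + 0.0 * a
        if self.included["city"]:
            lh = lh + v["city"] * is_nagasaki
        if self.included["sex"]:
            lh = lh + v["sex"] * is_female
        if self.included["log_age"]:
            lh = lh + v["log_age"] * np.log(a / 70.0)
        if self.included["agex"]:
            lh = lh + v["agex"] * (e - 30.0) / 10.0

        pos, slope = self._resolved_knots(self.knots, AGE_BOUNDS, "knot",
                                          values or {})
        for p, s in zip(pos, slope):
            lh = lh + s * np.maximum(np.log(a) - np.log(p), 0.0)
        pos, slope = self._resolved_knots(self.agex_knots, AGEX_BOUNDS,
                                          "agex_knot", values or {})
        for p, s in zip(pos, slope):
            lh = lh + s * np.maximum(e - p, 0.0) / 10.0
        return lh

    def hazard(self, city, sex, a, e, values=None):
        """Baseline hazard h0 in deaths per person-year (> 0)."""
        return np.exp(self.log_hazard(city, sex, a, e, values))

    def set_values(self, values):
        """Write optimizer-scale values back into the model in place."""
        for name in self.SCALAR_TERMS:
            if name in values:
                self.values[name] = float(values[name])
        for prefix, group, bounds in self._knot_groups():
            for i, k in enumerate(group):
                if f"{prefix}{i}_slope" in values:
                    k.slope = float(values[f"{prefix}{i}_slope"])
                if f"{prefix}{i}_pos" in values:
                    lo, hi = self._position_window(group, i, bounds)
                    k.position = float(
                        lo + (hi - lo) * expit(values[f"{prefix}{i}_pos"]))

    def copy(self):
        bl = BaselineModel.__new__(BaselineModel)
        bl.values = dict(self.values)
        bl.included = dict(self.included)
        bl.knots = [Knot(k.position, k.slope, k.free_slope, k.free_position)
                    for k in self.knots]
        bl.agex_knots = [Knot(k.position, k.slope, k.free_slope,
                              k.free_position) for k in self.agex_knots]
        bl.free_scalars = list(self.free_scalars)
        return bl

    def exclude(self, name):
        """Structurally remove a scalar term (value 0, not estimated)."""
        if name not in self.SCALAR_TERMS or name == "intercept":
            raise ValueError(f"cannot exclude {name!r}")
        self.included[name] = False
        self.values[name] = 0.0
        if name in self.free_scalars:
            self.free_scalars.remove(name)

    def __repr__(self):
        terms = [n for n in self.SCALAR_TERMS if self.included[n]]
        return (f"BaselineModel(terms={terms}, knots="
                f"{[k.position for k in self.knots]})")
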