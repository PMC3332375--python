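"""Dose-effect modifiers.

The excess risk is modulated by sex, attained age and age at exposure
through the multiplicative factor

    eps(s, a, e) = exp(theta_s * 1[female]) * (a/70)^eta
                   * exp(gamma * (e - 30)/10)

the standard centring used for the atomic-bomb survivor cohort
(attained age relative to 70 years, age at exposure relative to 30
years, per decade).  With every term excluded eps is identically 1,
and eps > 0 everywhere.
"""

from __future__ import annotations

import numpy as np

__all__ = ["EffectModifier"]


class EffectModifier:
    """Multiplicative excess-risk modifier.

    Parameters
    ----------
    sex : float or None
        theta_s, log-factor applied for females (``None`` excludes).
    age_power : float or None
        eta, exponent on (a/70).
    agex : float or None
        gamma, log-factor per decade of (e - 30).
    free : iterable of str
        Subset of {"sex", "age_power", "agex"} to estimate.
    """

    TERMS = ("sex", "age_power", "agex")

    def __init__(self, sex=None, age_power=None, agex=None, free=()):
        vals = {"sex": sex, "age_power": age_power, "agex": agex}
        self.included = {n: vals[n] is not None for n in self.TERMS}
        self.values = {n: float(vals[n]) if vals[n] is not None else 0.0
                       for n in self.TERMS}
        free = set(free)
        bad = free - set(self.TERMS)
        if bad:
            raise ValueError(f"unknown modifier terms {sorted(bad)}")
        for n in free:
            if not self.included[n]:
                raise ValueError(f"modifier term {n!r} is excluded")
        self.free = [n for n in self.TERMS if n in free]

    def free_parameters(self):
        return {n: self.values[n] for n in self.free}

    def value(self, sex, a, e, values=None):
        """eps(s, a, e); vectorised over covariates and over parameter
        arrays in ``values``."""
        a = np.asarray(a, dtype=float)
        if np.any(a <= 0):
            raise ValueError("attained age must be > 0")
        e = np.asarray(e, dtype=float)
        v = dict(self.values)
        if values:
            for n in self.TERMS:
                if n in values:
                    v[n] = values[n]
        out = np.ones(np.broadcast(a, e, np.asarray(sex)).shape)
        if self.included["sex"]:
            is_female = (np.asarray(sex) == "female").astype(float)
            out = out * np.exp(v["sex"] * is_female)
        if self.included["age_power"]:
            out = out * (a / 70.0) ** v["age_power"]
        if self.included["agex"]:
            out = out * np.exp(v["agex"] * (e - 30.0) / 10.0)
        return out

    __call__ = value

    def set_values(self, values):
        for n in self.TERMS:
            if n in values:
                self.values[n] = float(values[n])

    def copy(self):
        m = EffectModifier.__new__(EffectModifier)
        m.included = dict(self.included)
        m.values = dict(self.values)
        m.free = list(self.free)
        return m

    def __repr__(self):
        terms = {n: self.values[n] for n in self.TERMS if self.included[n]}
        return f"EffectModifier({terms})"
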