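"""Hazard composition and risk evaluation.

A :class:`RiskModel` combines a baseline hazard h0 with a dose-response
shape and a dose-effect modifier under one of two transfer conventions:

* ERR (excess relative risk):  h = h0 * (1 + err(D) * eps(s, a, e))
* EAR (excess absolute risk):  h = h0 + ear(D) * eps(s, a, e)

Risk estimates are read off the hazard directly:

    ERR = h / h0 - 1,        EAR = h - h0

so an ERR-transfer model implies EAR = h0 * ERR (hence city/sex
dependent through the baseline), and an EAR-transfer model implies
ERR = EAR / h0.
"""

from __future__ import annotations

import numpy as np

from .baseline import BaselineModel
from .doseresponse import DoseResponse
from .modifiers import EffectModifier

__all__ = ["RiskModel", "EvaluationError", "group_conversion_factor"]


class EvaluationError(ValueError):
    """The model is inadmissible at the requested point (nonpositive
    hazard); signals inadmissible parameters during fitting."""


class RiskModel:
    """Full hazard model: transfer + baseline + dose-response + modifier.

    Parameters
    ----------
    transfer : {"ERR", "EAR"}
    baseline : BaselineModel
    dose_response : DoseResponse
    modifier : EffectModifier, optional
        Defaults to the identity modifier (no dose-effect modification).
    label : str, optional
        Human-readable label used in score tables and reports.
    """

    def __init__(self, transfer, baseline, dose_response, modifier=None,
                 label=None):
        transfer = transfer.upper()
        if transfer not in ("ERR", "EAR"):
            raise ValueError("transfer must be 'ERR' or 'EAR'")
        if not isinstance(baseline, BaselineModel):
            raise TypeError("baseline must be a BaselineModel")
        if not isinstance(dose_response, DoseResponse):
            raise TypeError("dose_response must be a DoseResponse")
        self.transfer = transfer
        self.baseline = baseline
        self.dose_response = dose_response
        self.modifier = modifier if modifier is not None else EffectModifier()
        self.label = label or f"{transfer}-{dose_response.shape}"

    # -- free-parameter bookkeeping -----------------------------------
    # Free parameters are exposed under prefixed names: "bl.<name>",
    # "dr.<name>", "mod.<name>".
    def free_parameters(self):
        out = {}
        for name, val in self.baseline.free_parameters().items():
            out[f"bl.{name}"] = val
        for name in self.dose_response.free:
            out[f"dr.{name}"] = self.dose_response.params[name]
        for name, val in self.modifier.free_parameters().items():
            out[f"mod.{name}"] = val
        return out

    @staticmethod
    def _split(values):
        bl, dr, mod = {}, {}, {}
        if values:
            for key, val in values.items():
                prefix, name = key.split(".", 1)
                {"bl": bl, "dr": dr, "mod": mod}[prefix][name] = val
        return bl, dr, mod

    def set_values(self, values):
        """Write prefixed parameter values back into the components."""
        bl, dr, mod = self._split(values)
        self.baseline.set_values(bl)
        for name, val in dr.items():
            self.dose_response.params[name] = float(val)
        self.modifier.set_values(mod)

    def copy(self):
        return RiskModel(self.transfer, self.baseline.copy(),
                         self.dose_response.copy(), self.modifier.copy(),
                         label=self.label)

    # -- evaluation ----------------------------------------------------
    def excess(self, sex, a, e, D, values=None):
        """err(D) * eps(s, a, e) (or ear * eps), vectorised."""
        bl, dr, mod = self._split(values)
        return (self.dose_response.evaluate(D, values=dr)
                * self.modifier.value(sex, a, e, values=mod))

    def hazard(self, city, sex, a, e, D, values=None, check=True):
        """Total hazard h in deaths per person-year.

        With ``check=True`` a nonpositive hazard anywhere raises
        :class:`EvaluationError`; ``check=False`` returns the raw values
        (used by the samplers, which mask and regenerate bad draws).
        """
        bl, dr, mod = self._split(values)
        h0 = self.baseline.hazard(city, sex, a, e, values=bl)
        exc = (self.dose_response.evaluate(D, values=dr)
               * self.modifier.value(sex, a, e, values=mod))
        if self.transfer == "ERR":
            h = h0 * (1.0 + exc)
        else:
            h = h0 + exc
        if check and np.any(np.asarray(h) <= 0):
            raise EvaluationError(
                f"nonpositive total hazard under {self.transfer} transfer")
        return h

    def risk(self, city, sex, a, e, D, values=None, check=True):
        """(ERR, EAR) at the given covariates: ERR = h/h0 - 1,
        EAR = h - h0 (per person-year)."""
        bl, dr, mod = self._split(values)
        h0 = self.baseline.hazard(city, sex, a, e, values=bl)
        h = self.hazard(city, sex, a, e, D, values=values, check=check)
        return h / h0 - 1.0, h - h0

    def __repr__(self):
        return (f"RiskModel({self.label!r}, transfer={self.transfer}, "
                f"shape={self.dose_response.shape!r})")


def group_conversion_factor(baseline, table, from_group, to_group):
    """Person-year-weighted baseline-hazard ratio between two strata
    groups, used to convert EAR (or ERR) estimates quoted for one
    city/sex group to another.

    ``from_group`` / ``to_group`` are mappings of cell fields to
    required values, e.g. ``{"city": "hiroshima", "sex": "male"}``; an
    omitted field averages over it (so ``{"sex": "male"}`` is the
    city-averaged male group).

    Returns ``wmean(h0 | to) / wmean(h0 | from)`` with person-year
    weights; equals 1 when the groups coincide or when the baseline
    does not depend on the distinguishing fields.
    """
    def weighted_mean(group):
        cells = [c for c in table
                 if all(getattr(c, f) == v for f, v in group.items())]
        if not cells:
            raise ValueError(f"no cells match group {group}")
        pyr = np.array([c.person_years for c in cells])
        h0 = np.array([float(baseline.hazard(c.city, c.sex, c.mean_age,
                                             c.mean_agex)) for c in cells])
        return float(np.sum(pyr * h0) / np.sum(pyr))

    if dict(from_group) == dict(to_group):
        return 1.0
    return weighted_mean(dict(to_group)) / weighted_mean(dict(from_group))
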