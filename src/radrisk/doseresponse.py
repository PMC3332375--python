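"""Candidate dose-response shapes for excess risk.

Eleven functional forms for the excess (relative or absolute) risk as a
function of weighted colon dose D in Gy.  Each returns a dimensionless
excess err(D) (or a per-person-year ear(D) when used in an EAR model);
the coefficients carry the corresponding units (per Gy for linear
slopes, dimensionless for step heights).

Shapes (field names in brackets):

==  =====================  ==========================================
id  name                   err(D)
==  =====================  ==========================================
1   lnt                    err * D
2   quadratic              c2 * err * D^2
3   linear-quadratic       err1 * D + c2 * err2 * D^2
4   linear-exponential     (err1 + err2 D) * exp(-err3 D^2)
5   linear-threshold       0 below D_th, err * (D - D_th) above
6   tanh-step              0.5 * scale * [tanh(tanh_slope (D - D_th)) + 1]
7   step-slope             0 below D_th, err * D above
8   step-slope-offset      0 below D_th, err1 + err2 (D - D_th) above
9   hormesis               0 below 5 mGy, err1 to D_th, err2 above
10  hormesis-slope         0 below 5 mGy, err1 to D_th,
                           err1 + err2 (D - D_th) above
11  categorical            err1..err4 on [0,D1), [D1,D2), [D2,D3), >=D3
==  =====================  ==========================================

``c2`` is the dose-squared adjustment for random dosimetry errors,
1.12 by default (1.15 as the revised alternative).  The smoothed step
(#6) replaces a hard step by a hyperbolic tangent so the threshold can
be estimated rather than assumed; with the default slope of 1e5 per Gy
it is numerically indistinguishable from a hard step more than ~0.1 mGy
away from D_th.  Both hormesis-like shapes return exactly zero below a
fixed 5 mGy floor.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DoseResponse", "SHAPES", "ConfigurationError",
           "HORMESIS_FLOOR", "DOSE2_ADJUSTMENTS"]

#: fixed low-dose floor of the hormesis-like shapes, Gy
HORMESIS_FLOOR = 0.005

#: admissible dose-squared adjustment constants
DOSE2_ADJUSTMENTS = (1.12, 1.15)


class ConfigurationError(ValueError):
    """Shape/parameter mismatch in a dose-response specification."""


def _step(D, edge):
    # indicator D >= edge, broadcasting over either argument
    return np.where(np.asarray(D) >= edge, 1.0, 0.0)


# --- shape formulas ----------------------------------------------------
# Each entry: (shape id, parameter names, structural constant names,
# vectorised formula).  Formulas must be pure numpy so parameter values
# given as arrays (e.g. LHS draws) broadcast against a scalar dose.

def _f_lnt(D, p, c):
    return p["err"] * D


def _f_quadratic(D, p, c):
    return c["dose2_adjustment"] * p["err"] * D ** 2


def _f_linquad(D, p, c):
    return p["err1"] * D + c["dose2_adjustment"] * p["err2"] * D ** 2


def _f_linexp(D, p, c):
    return (p["err1"] + p["err2"] * D) * np.exp(-p["err3"] * D ** 2)


def _f_threshold(D, p, c):
    return p["err"] * np.maximum(np.asarray(D) - p["D_th"], 0.0)


def _f_tanh_step(D, p, c):
    return 0.5 * p["scale"] * (
        np.tanh(c["tanh_slope"] * (np.asarray(D) - p["D_th"])) + 1.0)


def _f_step_slope(D, p, c):
    return p["err"] * D * _step(D, p["D_th"])


def _f_step_slope_offset(D, p, c):
    return (p["err1"] + p["err2"] * (np.asarray(D) - p["D_th"])) * _step(
        D, p["D_th"])


def _f_hormesis(D, p, c):
    above_floor = _step(D, HORMESIS_FLOOR)
    return above_floor * np.where(np.asarray(D) >= p["D_th"],
                                  p["err2"], p["err1"])


def _f_hormesis_slope(D, p, c):
    above_floor = _step(D, HORMESIS_FLOOR)
    above_th = _step(D, p["D_th"])
    return above_floor * (
        p["err1"] + above_th * p["err2"] * (np.asarray(D) - p["D_th"]))


def _f_categorical(D, p, c):
    D = np.asarray(D)
    out = np.where(D < p["D1"], p["err1"],
                   np.where(D < p["D2"], p["err2"],
                            np.where(D < p["D3"], p["err3"], p["err4"])))
    return out


SHAPES = {
    "lnt": (1, ("err",), (), _f_lnt),
    "quadratic": (2, ("err",), ("dose2_adjustment",), _f_quadratic),
    "linear-quadratic": (3, ("err1", "err2"), ("dose2_adjustment",),
                         _f_linquad),
    "linear-exponential": (4, ("err1", "err2", "err3"), (), _f_linexp),
    "linear-threshold": (5, ("err", "D_th"), (), _f_threshold),
    "tanh-step": (6, ("scale", "D_th"), ("tanh_slope",), _f_tanh_step),
    "step-slope": (7, ("err", "D_th"), (), _f_step_slope),
    "step-slope-offset": (8, ("err1", "err2", "D_th"), (),
                          _f_step_slope_offset),
    "hormesis": (9, ("err1", "err2", "D_th"), (), _f_hormesis),
    "hormesis-slope": (10, ("err1", "err2", "D_th"), (), _f_hormesis_slope),
    "categorical": (11, ("err1", "err2", "err3", "err4", "D1", "D2", "D3"),
                    (), _f_categorical),
}

_SHAPE_BY_ID = {v[0]: k for k, v in SHAPES.items()}

_DEFAULT_CONSTANTS = {"dose2_adjustment": 1.12, "tanh_slope": 1.0e5}


class DoseResponse:
    """A parameterised dose-response shape.

    Parameters
    ----------
    shape : str or int
        Shape name (e.g. ``"lnt"``, ``"tanh-step"``) or numeric id 1-11.
    free : set of str, optional
        Names of parameters the fitter may adjust; default: none.
    dose2_adjustment : float, optional
        Multiplier on the dose-squared coefficient (1.12 default, 1.15
        allowed) for shapes 2 and 3.
    tanh_slope : float, optional
        Slope of the smoothed step, per Gy (default 1e5; held fixed
        during fitting unless listed in ``free`` -- the default
        treatment keeps it a structural constant).
    **params
        Initial/fixed values for the shape's parameters.

    Examples
    --------
    >>> dr = DoseResponse("lnt", err=0.124)
    >>> float(dr.evaluate(0.2))
    0.0248
    """

    def __init__(self, shape, free=(), **params):
        if isinstance(shape, int):
            if shape not in _SHAPE_BY_ID:
                raise ConfigurationError(f"unknown shape id {shape}")
            shape = _SHAPE_BY_ID[shape]
        if shape not in SHAPES:
            raise ConfigurationError(f"unknown shape {shape!r}")
        self.shape = shape
        self.shape_id, names, const_names, self._formula = SHAPES[shape]

        self.constants = {}
        for cname in const_names:
            val = params.pop(cname, _DEFAULT_CONSTANTS[cname])
            self.constants[cname] = float(val)
        if "dose2_adjustment" in self.constants and \
                self.constants["dose2_adjustment"] not in DOSE2_ADJUSTMENTS:
            raise ConfigurationError(
                "dose2_adjustment must be one of "
                f"{DOSE2_ADJUSTMENTS}, got {self.constants['dose2_adjustment']}")
        if "tanh_slope" in self.constants and \
                not self.constants["tanh_slope"] > 0:
            raise ConfigurationError("tanh_slope must be > 0")

        unknown = set(params) - set(names)
        if unknown:
            raise ConfigurationError(
                f"shape {shape!r} does not take parameters {sorted(unknown)}")
        self.params = {n: float(params.get(n, 0.0)) for n in names}
        self._validate(self.params)

        free = set(free)
        bad = free - set(names)
        if bad:
            raise ConfigurationError(
                f"free parameters {sorted(bad)} not in shape {shape!r}")
        self.free = [n for n in names if n in free]

    def _validate(self, p):
        if "D_th" in p and p["D_th"] < 0:
            raise ConfigurationError("D_th must be >= 0")
        if self.shape == "categorical":
            if not (p["D1"] < p["D2"] < p["D3"]):
                raise ConfigurationError("need D1 < D2 < D3")

    # -- evaluation ----------------------------------------------------
    def evaluate(self, D, values=None):
        """err(D) (or ear(D)) at dose ``D`` in Gy.

        ``values`` optionally overrides parameter values; entries may be
        arrays (they broadcast against ``D``), which is how sampled
        parameter vectors are pushed through in one vectorised call.
        """
        D = np.asarray(D, dtype=float)
        if np.any(D < 0):
            raise ValueError("dose must be >= 0")
        p = dict(self.params)
        if values:
            p.update(values)
        return self._formula(D, p, self.constants)

    __call__ = evaluate

    def copy(self, **updates):
        dr = DoseResponse.__new__(DoseResponse)
        dr.shape = self.shape
        dr.shape_id = self.shape_id
        dr._formula = self._formula
        dr.constants = dict(self.constants)
        dr.params = dict(self.params)
        dr.params.update(updates)
        dr.free = list(self.free)
        return dr

    def __repr__(self):
        pars = ", ".join(f"{k}={v:g}{'*' if k in self.free else ''}"
                         for k, v in self.params.items())
        return f"DoseResponse({self.shape!r}, {pars})"
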