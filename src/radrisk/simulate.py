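"""Synthetic LSS-like cohort generator.

Builds grouped person-year tables with a known true hazard so every
stage of the pipeline (fitting, streamlining, threshold profiling,
model selection, MMI) can be exercised and validated without the
restricted cohort file.  The generator emulates the structure of the
real data: strata defined by city, sex, age-at-exposure band,
attained-age band, calendar period and dose category; person-year
totals at the cohort scale (1.2 million person-years by default);
a dose distribution heavily concentrated at low doses; and Poisson
death counts with mean h_true(cell) * person_years.

Person-year allocation is deterministic (product of marginal weights,
restricted to feasible strata where the attained age exceeds the age
at exposure by at least the follow-up lag); only the death counts and
the small jitter on cell means are stochastic, each drawn from its own
substream of the configured seed so toggling one randomness source
does not shift another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .baseline import BaselineModel
from .cohort import PersonYearCell, PersonYearTable
from .doseresponse import DoseResponse
from .model import RiskModel
from .modifiers import EffectModifier

__all__ = ["SyntheticConfig", "generate_table", "expected_deaths",
           "resolve_true_model"]

#: minimum gap between attained age and age at exposure, years
#: (follow-up in the emulated cohort starts two decades after exposure)
FOLLOWUP_LAG = 23.0


@dataclass
class SyntheticConfig:
    """Statistical contract of the generator.

    Defaults reproduce the study conditions the pipeline is meant for:
    ~1.2e6 person-years, ~4,000 deaths per endpoint, and exposure
    concentrated at low doses.
    """

    cities: tuple = ("hiroshima", "nagasaki")
    city_weights: tuple = (0.65, 0.35)
    sexes: tuple = ("male", "female")
    sex_weights: tuple = (0.38, 0.62)
    #: (lo, hi) age-at-exposure bands, years
    agex_bands: tuple = ((0, 10), (10, 20), (20, 30), (30, 40), (40, 50))
    agex_weights: tuple = (0.25, 0.25, 0.20, 0.15, 0.15)
    #: (lo, hi) attained-age bands, years
    age_bands: tuple = ((40, 50), (50, 60), (60, 70), (70, 80), (80, 90))
    age_weights: tuple = (0.15, 0.25, 0.25, 0.20, 0.15)
    n_periods: int = 2
    #: representative mean weighted colon dose per category, Gy
    dose_means: tuple = (0.0025, 0.03, 0.2, 0.75, 1.5, 2.5)
    dose_weights: tuple = (0.55, 0.25, 0.12, 0.05, 0.02, 0.01)
    total_person_years: float = 1.2e6
    #: calibration target for expected deaths per cause under the
    #: default true model
    target_deaths: float = 4000.0
    #: relative (uniform) jitter on cell mean doses, and absolute jitter
    #: in years on cell mean ages -- emulates the person-year-weighted
    #: means of real grouped data varying around category representatives
    dose_jitter: float = 0.05
    age_jitter: float = 1.0
    causes: tuple = ("cvd",)
    #: true RiskModel; None selects the calibrated default (ERR-LNT,
    #: err = 0.2 per Gy, log-linear baseline rising with ln attained age)
    true_model: RiskModel | None = None
    seed: int = 0

    def __post_init__(self):
        d = np.asarray(self.dose_means, float)
        if np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise ValueError("dose_means must be non-negative, ascending")
        for w in (self.city_weights, self.sex_weights, self.agex_weights,
                  self.age_weights, self.dose_weights):
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError("allocation weights must sum to 1")


def _grid(config):
    """Deterministic strata grid: list of dicts with labels, category
    indices, band midpoints and person-year allocation."""
    rows = []
    weight_sum = 0.0
    for ci, city in enumerate(config.cities):
        for si, sex in enumerate(config.sexes):
            for xi, (xlo, xhi) in enumerate(config.agex_bands):
                for ai, (alo, ahi) in enumerate(config.age_bands):
                    agex_mid = 0.5 * (xlo + xhi)
                    age_mid = 0.5 * (alo + ahi)
                    if age_mid - agex_mid < FOLLOWUP_LAG:
                        continue
                    for pi in range(config.n_periods):
                        for di, dmean in enumerate(config.dose_means):
                            w = (config.city_weights[ci]
                                 * config.sex_weights[si]
                                 * config.agex_weights[xi]
                                 * config.age_weights[ai]
                                 * (1.0 / config.n_periods)
                                 * config.dose_weights[di])
                            rows.append({
                                "city": city, "sex": sex, "agex_cat": xi,
                                "age_cat": ai, "period_cat": pi,
                                "dose_cat": di, "agex_mid": agex_mid,
                                "age_mid": age_mid, "dose_mean": dmean,
                                "weight": w})
                            weight_sum += w
    for r in rows:
        r["person_years"] = (config.total_person_years
                             * r["weight"] / weight_sum)
    return rows


def resolve_true_model(config):
    """The configured true model, or the calibrated default.

    The default truth is an ERR-LNT model (err = 0.2 per Gy, no
    dose-effect modifiers) over a log-linear baseline rising with
    attained age (slope 5 on ln a) and a female log-offset of -0.3;
    the intercept is set deterministically from the strata grid so the
    expected deaths per cause equal ``config.target_deaths``.
    """
    if config.true_model is not None:
        return config.true_model
    baseline = BaselineModel(intercept=0.0, log_age=5.0, sex=-0.3)
    model = RiskModel("ERR", baseline, DoseResponse("lnt", err=0.2),
                      EffectModifier(), label="true-err-lnt")
    rows = _grid(config)
    city = np.array([r["city"] for r in rows])
    sex = np.array([r["sex"] for r in rows])
    a = np.array([r["age_mid"] for r in rows])
    e = np.array([r["agex_mid"] for r in rows])
    D = np.array([r["dose_mean"] for r in rows])
    pyr = np.array([r["person_years"] for r in rows])
    lam = model.hazard(city, sex, a, e, D) * pyr
    baseline.values["intercept"] = float(
        np.log(config.target_deaths / lam.sum()))
    return model


def generate_table(config):
    """Generate a grouped person-year table with known truth.

    Returns
    -------
    table : PersonYearTable
    truth : dict
        The true model, its parameter values, the seed, and the
        aggregate expected deaths per cause.
    """
    model = resolve_true_model(config)
    rows = _grid(config)

    ss = np.random.SeedSequence(config.seed)
    age_stream, dose_stream, death_stream = [
        np.random.default_rng(s) for s in ss.spawn(3)]

    cells = []
    expected_total = 0.0
    for r in rows:
        age = r["age_mid"] + config.age_jitter * age_stream.uniform(-1, 1)
        agex = r["agex_mid"] + config.age_jitter * age_stream.uniform(-1, 1)
        agex = min(agex, age - FOLLOWUP_LAG)
        dose = r["dose_mean"] * (
            1.0 + config.dose_jitter * dose_stream.uniform(-1, 1))
        lam = float(model.hazard(r["city"], r["sex"], age, agex, dose)
                    * r["person_years"])
        expected_total += lam
        deaths = {c: int(death_stream.poisson(lam)) for c in config.causes}
        cells.append(PersonYearCell(
            city=r["city"], sex=r["sex"], agex_cat=r["agex_cat"],
            age_cat=r["age_cat"], period_cat=r["period_cat"],
            dose_cat=r["dose_cat"], mean_age=float(age),
            mean_agex=float(agex), mean_dose=float(max(dose, 0.0)),
            person_years=float(r["person_years"]), deaths=deaths))

    if expected_total < 1.0:
        warnings.warn("aggregate expected deaths below 1; fits will be "
                      "unstable", stacklevel=2)

    truth = {
        "seed": config.seed,
        "label": model.label,
        "transfer": model.transfer,
        "shape": model.dose_response.shape,
        "dose_response": dict(model.dose_response.params),
        "baseline": dict(model.baseline.values),
        "modifier": dict(model.modifier.values),
        "expected_deaths": expected_total,
    }
    table = PersonYearTable(
        cells, causes=list(config.causes),
        metadata={"synthetic": True, "seed": config.seed,
                  "generator": "radrisk.simulate"})
    return table, truth


def expected_deaths(config, cell):
    """Poisson mean of the generator for one cell: h_true * person_years
    (evaluated at the cell's stored means, matching the draw)."""
    model = resolve_true_model(config)
    return float(model.hazard(cell.city, cell.sex, cell.mean_age,
                              cell.mean_agex, cell.mean_dose)
                 * cell.person_years)


def with_true_model(config, model, **updates):
    """Convenience: a copy of ``config`` with a different truth."""
    return replace(config, true_model=model, **updates)
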