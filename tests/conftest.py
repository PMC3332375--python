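import numpy as np
import pytest

from radrisk import (BaselineModel, DoseResponse, EffectModifier,
                     PersonYearCell, PersonYearTable, RiskModel,
                     SyntheticConfig, generate_table)


def make_cell(city="hiroshima", sex="male", agex_cat=0, age_cat=0,
              period_cat=0, dose_cat=0, mean_age=70.0, mean_agex=30.0,
              mean_dose=0.0, person_years=1000.0, deaths=None):
    return PersonYearCell(city=city, sex=sex, agex_cat=agex_cat,
                          age_cat=age_cat, period_cat=period_cat,
                          dose_cat=dose_cat, mean_age=mean_age,
                          mean_agex=mean_agex, mean_dose=mean_dose,
                          person_years=person_years,
                          deaths=deaths or {"cvd": 0})


@pytest.fixture
def tiny_table():
    """Three-cell table with hand-checkable totals."""
    cells = [
        make_cell(dose_cat=0, mean_dose=0.0, person_years=1000.0,
                  deaths={"cvd": 2}),
        make_cell(dose_cat=1, mean_dose=0.5, person_years=2000.0,
                  deaths={"cvd": 5}),
        make_cell(sex="female", dose_cat=1, mean_dose=0.5,
                  person_years=1500.0, deaths={"cvd": 3}),
    ]
    return PersonYearTable(cells, causes=["cvd"])


@pytest.fixture(scope="session")
def default_table():
    """One synthetic cohort at the default scale (seed 1)."""
    table, truth = generate_table(SyntheticConfig(seed=1))
    return table, truth


def lnt_spec(err_start=0.1, intercept=-5.7):
    """An ERR-LNT fitting specification matching the default generator
    truth's structure (free intercept, ln-age slope, sex offset, err)."""
    bl = BaselineModel(intercept=intercept, log_age=4.0, sex=0.0,
                       free=("intercept", "log_age", "sex"))
    return RiskModel("ERR", bl, DoseResponse("lnt", err=err_start,
                                             free={"err"}),
                     EffectModifier())


def true_model(transfer, shape, baseline_values=None, modifier=None,
               **dr_params):
    """Build an exact truth model for the generator (nothing free)."""
    bv = dict(intercept=-5.68, log_age=5.0, sex=-0.3)
    bv.update(baseline_values or {})
    bl = BaselineModel(**bv)
    return RiskModel(transfer, bl, DoseResponse(shape, **dr_params),
                     modifier or EffectModifier(), label=f"true-{shape}")


#: dose-category layout dense enough to localise a threshold near 0.6 Gy
#: (the coarse default leaves 0.24-0.6 Gy without observations); the
#: category means are placed so the 5% jitter never crosses a 0.1-Gy
#: profiling grid line
DENSE_DOSE = dict(
    dose_means=(0.0025, 0.03, 0.1, 0.25, 0.45, 0.55, 0.65, 0.85, 1.25,
                2.0),
    dose_weights=(0.42, 0.20, 0.11, 0.08, 0.06, 0.045, 0.035, 0.025,
                  0.015, 0.01),
)
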