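"""Grouped person-year mortality tables.

The data model mirrors the grouped cohort files used in radiation
epidemiology: each record ("cell") is a stratum defined by city, sex and
category indices for age at exposure, attained age, calendar period and
dose, and carries person-year-weighted mean covariates (attained age,
age at exposure, weighted colon dose in Gy), accumulated person-years
and death counts per cause.  All modelling downstream evaluates hazards
at the cell means, so category indices are opaque labels.

Canonical file format: CSV with one header row and fixed column names
``city, sex, agexcat, agecat, periodcat, dosecat, mean_age, mean_agex,
mean_dose_gy, pyr, deaths_<cause>`` (one ``deaths_`` column per cause).
Column names can be overridden through the ``columns`` mapping accepted
by :func:`read_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PersonYearCell",
    "PersonYearTable",
    "SchemaError",
    "ValidationError",
    "read_table",
    "write_table",
    "stratify_totals",
]

CITIES = ("hiroshima", "nagasaki")
SEXES = ("male", "female")

#: canonical column names of the CSV dialect
CANONICAL_COLUMNS = {
    "city": "city",
    "sex": "sex",
    "agexcat": "agexcat",
    "agecat": "agecat",
    "periodcat": "periodcat",
    "dosecat": "dosecat",
    "mean_age": "mean_age",
    "mean_agex": "mean_agex",
    "mean_dose": "mean_dose_gy",
    "person_years": "pyr",
}


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ValidationError(ValueError):
    """A row or cell violates a table invariant."""


@dataclass(frozen=True)
class PersonYearCell:
    """One stratum of a grouped person-year table.

    Parameters
    ----------
    city, sex : str
        Stratum labels; ``city`` in {"hiroshima", "nagasaki"}, ``sex``
        in {"male", "female"}.
    agex_cat, age_cat, period_cat, dose_cat : int
        Opaque category indices (age at exposure, attained age,
        calendar period, dose).
    mean_age, mean_agex : float
        Person-year-weighted mean attained age / age at exposure, years.
    mean_dose : float
        Person-year-weighted mean weighted colon dose, Gy (neutron
        component weighted upstream).
    person_years : float
        Accumulated person-years at risk, > 0.
    deaths : dict
        Mapping cause label -> non-negative integer death count.
    """

    city: str
    sex: str
    agex_cat: int
    age_cat: int
    period_cat: int
    dose_cat: int
    mean_age: float
    mean_agex: float
    mean_dose: float
    person_years: float
    deaths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.city not in CITIES:
            raise ValidationError(f"unknown city {self.city!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if not self.person_years > 0:
            raise ValidationError(
                f"person_years must be > 0, got {self.person_years}")
        if self.mean_dose < 0:
            raise ValidationError(f"mean_dose must be >= 0, got {self.mean_dose}")
        if self.mean_agex > self.mean_age:
            raise ValidationError(
                f"mean_agex ({self.mean_agex}) exceeds mean_age ({self.mean_age})")
        for cause, d in self.deaths.items():
            if d < 0 or d != int(d):
                raise ValidationError(
                    f"death count for {cause!r} must be a non-negative "
                    f"integer, got {d}")

    @property
    def key(self):
        return (self.city, self.sex, self.agex_cat, self.age_cat,
                self.period_cat, self.dose_cat)


class PersonYearTable:
    """Ordered collection of :class:`PersonYearCell` with cause labels.

    Invariants: stratum keys are unique; total person-years equal the
    sum over cells (held by construction).
    """

    def __init__(self, cells, causes=None, metadata=None):
        self.cells = list(cells)
        if not self.cells:
            raise ValidationError("table must contain at least one cell")
        keys = [c.key for c in self.cells]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValidationError(f"duplicate stratum key {dup}")
        if causes is None:
            causes = sorted({c for cell in self.cells for c in cell.deaths})
        self.causes = list(causes)
        self.metadata = dict(metadata or {})

    def __len__(self):
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    @property
    def total_person_years(self):
        return float(sum(c.person_years for c in self.cells))

    def total_deaths(self, cause):
        return int(sum(c.deaths.get(cause, 0) for c in self.cells))

    # -- array views used by the fitting machinery ---------------------
    def arrays(self, cause):
        """Return (city, sex, mean_age, mean_agex, mean_dose, pyr, deaths)
        as numpy arrays over cells, in table order."""
        city = np.array([c.city for c in self.cells])
        sex = np.array([c.sex for c in self.cells])
        a = np.array([c.mean_age for c in self.cells], dtype=float)
        e = np.array([c.mean_agex for c in self.cells], dtype=float)
        d = np.array([c.mean_dose for c in self.cells], dtype=float)
        pyr = np.array([c.person_years for c in self.cells], dtype=float)
        deaths = np.array([c.deaths.get(cause, 0) for c in self.cells],
                          dtype=float)
        return city, sex, a, e, d, pyr, deaths

    def to_frame(self):
        cols = CANONICAL_COLUMNS
        rows = []
        for c in self.cells:
            row = {
                cols["city"]: c.city,
                cols["sex"]: c.sex,
                cols["agexcat"]: c.agex_cat,
                cols["agecat"]: c.age_cat,
                cols["periodcat"]: c.period_cat,
                cols["dosecat"]: c.dose_cat,
                cols["mean_age"]: c.mean_age,
                cols["mean_agex"]: c.mean_agex,
                cols["mean_dose"]: c.mean_dose,
                cols["person_years"]: c.person_years,
            }
            for cause in self.causes:
                row[f"deaths_{cause}"] = c.deaths.get(cause, 0)
            rows.append(row)
        return pd.DataFrame(rows)


def _resolve_columns(columns):
    cols = dict(CANONICAL_COLUMNS)
    if columns:
        unknown = set(columns) - set(cols)
        if unknown:
            raise SchemaError(f"unknown column overrides: {sorted(unknown)}")
        cols.update(columns)
    return cols


def read_table(path, columns=None, causes=None):
    """Read a person-year table from the canonical CSV dialect.

    Parameters
    ----------
    path : path-like
        CSV file with one header row.
    columns : dict, optional
        Overrides for the canonical column names (keys from
        ``CANONICAL_COLUMNS``).
    causes : list of str, optional
        Restrict to these causes; default: every ``deaths_<cause>``
        column found in the header.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        If a row violates a cell invariant; the message names the
        0-based row index.
    """
    cols = _resolve_columns(columns)
    df = pd.read_csv(path)
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if causes is None:
        causes = [c[len("deaths_"):] for c in df.columns
                  if c.startswith("deaths_")]
    if not causes:
        raise SchemaError("no deaths_<cause> column found")
    for cause in causes:
        if f"deaths_{cause}" not in df.columns:
            raise SchemaError(f"missing column deaths_{cause}")

    cells = []
    for i, row in df.iterrows():
        try:
            cells.append(PersonYearCell(
                city=str(row[cols["city"]]).lower(),
                sex=str(row[cols["sex"]]).lower(),
                agex_cat=int(row[cols["agexcat"]]),
                age_cat=int(row[cols["agecat"]]),
                period_cat=int(row[cols["periodcat"]]),
                dose_cat=int(row[cols["dosecat"]]),
                mean_age=float(row[cols["mean_age"]]),
                mean_agex=float(row[cols["mean_agex"]]),
                mean_dose=float(row[cols["mean_dose"]]),
                person_years=float(row[cols["person_years"]]),
                deaths={c: int(row[f"deaths_{c}"]) for c in causes},
            ))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return PersonYearTable(cells, causes=causes)


def write_table(table, path):
    """Write a table in the canonical CSV dialect (round-trips with
    :func:`read_table`)."""
    table.to_frame().to_csv(path, index=False)


def stratify_totals(table, dose_bins, age_bins, cause,
                    right_closed=False):
    """Aggregate person-years and deaths over a (dose x attained-age) grid.

    Cells are assigned by their person-year-weighted means.  Intervals
    are half-open ``[lo, hi)`` by default; ``right_closed=True`` switches
    to ``(lo, hi]`` (the convention used in printed stratified tables
    such as "0.1 < D <= 0.5").

    Parameters
    ----------
    dose_bins, age_bins : sequence of float
        Strictly increasing bin boundaries covering every cell mean.
    cause : str
        Cause label for the death counts.

    Returns
    -------
    pandas.DataFrame
        Index (dose_bin, age_bin) as interval labels, columns
        ``person_years`` and ``deaths``.  Group totals conserve the
        table totals exactly.
    """
    dose_bins = np.asarray(dose_bins, dtype=float)
    age_bins = np.asarray(age_bins, dtype=float)
    for name, bins in (("dose", dose_bins), ("age", age_bins)):
        if len(bins) < 2 or np.any(np.diff(bins) <= 0):
            raise ValueError(f"{name}_bins must be strictly increasing "
                             "with at least two boundaries")

    def locate(x, bins, label, cell):
        side = "right" if right_closed else "left"
        # np.searchsorted with side='right' on [lo, hi) convention:
        # index i such that bins[i] <= x < bins[i+1]
        if right_closed:
            i = int(np.searchsorted(bins, x, side="left")) - 1
            if x == bins[0]:
                i = 0
        else:
            i = int(np.searchsorted(bins, x, side="right")) - 1
        if i < 0 or i >= len(bins) - 1 or (
                not right_closed and x >= bins[-1]) or (
                right_closed and x > bins[-1]):
            raise ValueError(
                f"cell {cell.key} {label} {x} outside bins "
                f"[{bins[0]}, {bins[-1]}]")
        return i

    acc = {}
    for cell in table:
        i = locate(cell.mean_dose, dose_bins, "mean_dose", cell)
        j = locate(cell.mean_age, age_bins, "mean_age", cell)
        pyr, d = acc.get((i, j), (0.0, 0))
        acc[(i, j)] = (pyr + cell.person_years,
                       d + cell.deaths.get(cause, 0))

    def interval(bins, i):
        lo, hi = bins[i], bins[i + 1]
        return f"({lo}, {hi}]" if right_closed else f"[{lo}, {hi})"

    rows = []
    for i in range(len(dose_bins) - 1):
        for j in range(len(age_bins) - 1):
            pyr, d = acc.get((i, j), (0.0, 0))
            rows.append({"dose_bin": interval(dose_bins, i),
                         "age_bin": interval(age_bins, j),
                         "person_years": pyr, "deaths": d})
    return pd.DataFrame(rows).set_index(["dose_bin", "age_bin"])
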