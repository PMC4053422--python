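"""Grid containers for cause-specific mortality data.

Everything in this package operates on complete rectangular grids for one
sex at a time: age groups down the rows, consecutive calendar years across
the columns.  The containers here hold death counts with their mid-year
population exposures (:class:`MortalitySurface`), central death rates
(:class:`RateSurface`), projected future populations
(:class:`PopulationProjection`) and forecast death probabilities
(:class:`RateForecast`), together with CSV readers and writers for the
long-format tables national statistics offices publish.

Rate/probability convention
---------------------------
The central death rate is ``m = deaths / exposure`` (person-years).  The
death probability within a one-year cell is derived under a constant hazard
within the interval, ``q = 1 - exp(-m)``, so ``0 <= q < 1`` and ``q <= m``
always hold.  The Lee-Carter side of the package models ``log m`` while the
Bayesian age-period-cohort side models ``logit q``; this single conversion
bridges the two.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "AgeGroupScheme",
    "MortalitySurface",
    "RateSurface",
    "PopulationProjection",
    "RateForecast",
    "central_rates",
    "read_surface",
    "write_surface",
    "read_projection",
    "write_projection",
    "read_forecast",
    "write_forecast",
]

REQUIRED_SURFACE_COLUMNS = ("sex", "age_group", "year", "deaths", "population")
REQUIRED_PROJECTION_COLUMNS = ("sex", "age_group", "year", "population")

_OPEN_RE = re.compile(r"^(\d+)\+$")
_BAND_RE = re.compile(r"^(\d+)[-–](\d+)$")


class DataError(ValueError):
    """An input table or grid violates the completeness/positivity contract."""


@dataclass(frozen=True)
class AgeGroupScheme:
    """Ordered age bands of common width, optionally open-ended at the top.

    Bands are closed-open intervals ``[lower, lower + width)``; the top band
    may instead be open-ended ("85+").  The default configuration used
    throughout the documentation is six ten-year bands from 35-44 to 85+.
    """

    labels: tuple[str, ...]
    lower_bounds: tuple[int, ...]
    width: int
    open_ended_top: bool = True

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.lower_bounds):
            raise DataError("labels and lower_bounds must have equal length")
        if len(self.labels) < 1:
            raise DataError("age scheme needs at least one band")
        lb = np.asarray(self.lower_bounds)
        if not np.all(np.diff(lb) > 0):
            raise DataError("age band lower bounds must be strictly increasing")
        if self.width <= 0:
            raise DataError("band width must be a positive integer")
        if len(lb) > 1 and not np.all(np.diff(lb) == self.width):
            raise DataError(
                "all closed age bands must share the common width "
                f"{self.width} (lower bounds {self.lower_bounds})"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def default(cls) -> "AgeGroupScheme":
        """Six ten-year bands 35-44 ... 85+, the configuration used in docs."""
        return cls(
            labels=("35-44", "45-54", "55-64", "65-74", "75-84", "85+"),
            lower_bounds=(35, 45, 55, 65, 75, 85),
            width=10,
        )

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "AgeGroupScheme":
        """Parse labels like ``"35-44"`` / ``"85+"`` into a scheme.

        Labels are sorted by lower bound; at most one open-ended band is
        allowed and it must sit at the top.
        """
        parsed: list[tuple[int, bool, str]] = []
        for lab in labels:
            lab = str(lab).strip()
            m = _OPEN_RE.match(lab)
            if m:
                parsed.append((int(m.group(1)), True, lab))
                continue
            m = _BAND_RE.match(lab)
            if m:
                lo, hi = int(m.group(1)), int(m.group(2))
                if hi <= lo:
                    raise DataError(f"unknown age label {lab!r}")
                parsed.append((lo, False, lab))
                continue
            raise DataError(f"unknown age label {lab!r}")
        parsed.sort()
        open_flags = [p[1] for p in parsed]
        if any(open_flags[:-1]):
            raise DataError("only the top age band may be open-ended")
        widths = set()
        for lo, is_open, lab in parsed:
            if not is_open:
                hi = int(_BAND_RE.match(lab).group(2))
                widths.add(hi - lo + 1)
        if len(widths) > 1:
            raise DataError(f"age bands have mixed widths: {sorted(widths)}")
        width = widths.pop() if widths else 1
        return cls(
            labels=tuple(p[2] for p in parsed),
            lower_bounds=tuple(p[0] for p in parsed),
            width=width,
            open_ended_top=bool(open_flags and open_flags[-1]),
        )


def _check_years(years: np.ndarray) -> np.ndarray:
    years = np.asarray(years, dtype=int)
    if years.ndim != 1 or years.size < 1:
        raise DataError("years must be a non-empty 1-D sequence")
    if years.size > 1 and not np.all(np.diff(years) == 1):
        raise DataError("years must be consecutive integers")
    return years


@dataclass(frozen=True)
class MortalitySurface:
    """Death counts and person-year exposures on an age x year grid, one sex.

    Invariants enforced on construction: integer deaths ``>= 0``, exposures
    ``> 0``, deaths never exceed exposures, and the grid is complete.
    """

    sex: str
    ages: AgeGroupScheme
    years: np.ndarray
    deaths: np.ndarray
    exposures: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", _check_years(self.years))
        deaths = np.asarray(self.deaths)
        exposures = np.asarray(self.exposures, dtype=float)
        if deaths.shape != (self.ages.n, self.years.size):
            raise DataError(
                f"deaths shape {deaths.shape} does not match grid "
                f"({self.ages.n}, {self.years.size})"
            )
        if exposures.shape != deaths.shape:
            raise DataError("exposures shape does not match deaths")
        if not np.all(np.isfinite(exposures)) or np.any(exposures <= 0):
            raise DataError("nonpositive exposure in surface")
        if np.any(np.asarray(deaths, dtype=float) < 0):
            raise DataError("negative death count in surface")
        if not np.allclose(deaths, np.round(np.asarray(deaths, dtype=float))):
            raise DataError("death counts must be integers")
        deaths = np.round(np.asarray(deaths, dtype=float)).astype(np.int64)
        if np.any(deaths > exposures):
            raise DataError("death count exceeds exposure")
        object.__setattr__(self, "deaths", deaths)
        object.__setattr__(self, "exposures", exposures)

    @property
    def n_ages(self) -> int:
        return self.ages.n

    @property
    def n_years(self) -> int:
        return self.years.size

    @property
    def last_year(self) -> int:
        return int(self.years[-1])

    def rates(self) -> "RateSurface":
        return central_rates(self)


@dataclass(frozen=True)
class RateSurface:
    """Central death rates on the same grid; probabilities derived on demand."""

    sex: str
    ages: AgeGroupScheme
    years: np.ndarray
    m: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", _check_years(self.years))
        m = np.asarray(self.m, dtype=float)
        if m.shape != (self.ages.n, self.years.size):
            raise DataError("rate matrix shape does not match grid")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise DataError("central rates must be finite and >= 0")
        object.__setattr__(self, "m", m)

    @property
    def q(self) -> np.ndarray:
        """Death probabilities ``q = 1 - exp(-m)`` (constant-hazard convention)."""
        return -np.expm1(-self.m)


@dataclass(frozen=True)
class PopulationProjection:
    """Projected mid-year populations for future years, same age scheme."""

    sex: str
    ages: AgeGroupScheme
    years: np.ndarray
    population: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", _check_years(self.years))
        pop = np.asarray(self.population, dtype=float)
        if pop.shape != (self.ages.n, self.years.size):
            raise DataError("projection shape does not match grid")
        if not np.all(np.isfinite(pop)) or np.any(pop <= 0):
            raise DataError("projected populations must be > 0")
        object.__setattr__(self, "population", pop)


@dataclass(frozen=True)
class RateForecast:
    """Forecast death probabilities per cell with 2.5/97.5 percentile bounds.

    ``point``, ``lower`` and ``upper`` are (n_ages, horizon) probability
    matrices; ``draws``, when retained, is (n_draws, n_ages, horizon) and is
    what the scenario machinery uses to propagate uncertainty into death
    counts.  ``rates()`` converts back to central rates via
    ``m = -log(1 - q)``.
    """

    sex: str
    ages: AgeGroupScheme
    years: np.ndarray
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    draws: np.ndarray | None = None
    model: str = "forecast"

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", _check_years(self.years))
        shape = (self.ages.n, self.years.size)
        for name in ("point", "lower", "upper"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise DataError(f"forecast {name} shape {arr.shape} != {shape}")
            if not np.all(np.isfinite(arr)):
                raise DataError(f"forecast {name} contains non-finite values")
            if np.any(arr < 0) or np.any(arr >= 1):
                raise DataError(f"forecast {name} must lie in [0, 1)")
            object.__setattr__(self, name, arr)
        if np.any(self.lower > self.point + 1e-12) or np.any(
            self.point > self.upper + 1e-12
        ):
            raise DataError("forecast bounds must satisfy lower <= point <= upper")
        if self.draws is not None:
            draws = np.asarray(self.draws, dtype=float)
            if draws.ndim != 3 or draws.shape[1:] != shape:
                raise DataError("forecast draws must have shape (n_draws,) + grid")
            object.__setattr__(self, "draws", draws)

    @property
    def horizon(self) -> int:
        return self.years.size

    def rates(self, which: str = "point") -> np.ndarray:
        return -np.log1p(-np.asarray(getattr(self, which), dtype=float))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, lab in enumerate(self.ages.labels):
            for t, year in enumerate(self.years):
                rows.append(
                    {
                        "sex": self.sex,
                        "age_group": lab,
                        "year": int(year),
                        "quantity": "death_probability",
                        "estimate": self.point[i, t],
                        "lower": self.lower[i, t],
                        "upper": self.upper[i, t],
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sex: str | None = None) -> "RateForecast":
        need = {"sex", "age_group", "year", "estimate", "lower", "upper"}
        missing = need - set(df.columns)
        if missing:
            raise DataError(f"forecast table missing columns {sorted(missing)}")
        if sex is None:
            sexes = df["sex"].unique()
            if len(sexes) != 1:
                raise DataError("forecast table holds several sexes; pass sex=")
            sex = str(sexes[0])
        sub = df[df["sex"] == sex]
        ages = AgeGroupScheme.from_labels(sub["age_group"].unique())
        years = _check_years(np.sort(sub["year"].unique()))
        mats = {}
        for col in ("estimate", "lower", "upper"):
            pivot = sub.pivot_table(
                index="age_group", columns="year", values=col, aggfunc="first"
            )
            pivot = pivot.reindex(index=list(ages.labels), columns=list(years))
            if pivot.isna().any().any():
                raise DataError("forecast table has missing cells")
            mats[col] = pivot.to_numpy(dtype=float)
        return cls(
            sex=sex,
            ages=ages,
            years=years,
            point=mats["estimate"],
            lower=mats["lower"],
            upper=mats["upper"],
        )


def central_rates(surface: MortalitySurface) -> RateSurface:
    """Central death rates ``m[i, j] = deaths / exposure`` per cell."""
    return RateSurface(
        sex=surface.sex,
        ages=surface.ages,
        years=surface.years,
        m=surface.deaths / surface.exposures,
    )


def _grid_from_long(
    df: pd.DataFrame,
    sex: str,
    value_columns: Sequence[str],
    ages: AgeGroupScheme | None,
    path: str,
) -> tuple[AgeGroupScheme, np.ndarray, dict[str, np.ndarray]]:
    sub = df[df["sex"].astype(str) == sex]
    if sub.empty:
        raise DataError(f"{path}: no rows for sex {sex!r}")
    labels = sub["age_group"].astype(str).unique()
    scheme = ages if ages is not None else AgeGroupScheme.from_labels(labels)
    unknown = set(labels) - set(scheme.labels)
    if unknown:
        raise DataError(f"{path}: unknown age label {sorted(unknown)[0]!r}")
    years = _check_years(np.sort(sub["year"].unique()))
    dup = sub.duplicated(subset=["age_group", "year"], keep=False)
    if dup.any():
        row = sub[dup].iloc[0]
        raise DataError(
            f"{path}: duplicate cell (age_group={row['age_group']!r}, "
            f"year={int(row['year'])})"
        )
    mats: dict[str, np.ndarray] = {}
    for col in value_columns:
        pivot = sub.pivot_table(
            index="age_group", columns="year", values=col, aggfunc="first"
        ).reindex(index=list(scheme.labels), columns=list(years))
        if pivot.isna().any().any():
            ii, jj = np.argwhere(pivot.isna().to_numpy())[0]
            raise DataError(
                f"{path}: missing cell (age_group={scheme.labels[ii]!r}, "
                f"year={int(years[jj])})"
            )
        mats[col] = pivot.to_numpy(dtype=float)
    return scheme, years, mats


def read_surface(
    path, sex: str, ages: AgeGroupScheme | None = None
) -> MortalitySurface:
    """Read a long-format deaths/population CSV into a complete surface.

    The file must have columns ``sex, age_group, year, deaths, population``
    with one row per cell; rows for other sexes are ignored.  Any missing or
    duplicate cell, negative count, nonpositive exposure or unknown age
    label raises :class:`DataError` naming the offending cell.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(REQUIRED_SURFACE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    scheme, years, mats = _grid_from_long(
        df, sex, ("deaths", "population"), ages, str(path)
    )
    deaths, pop = mats["deaths"], mats["population"]
    if np.any(deaths < 0):
        i, j = np.argwhere(deaths < 0)[0]
        raise DataError(
            f"{path}: negative count (age_group={scheme.labels[i]!r}, "
            f"year={int(years[j])})"
        )
    if np.any(pop <= 0):
        i, j = np.argwhere(pop <= 0)[0]
        raise DataError(
            f"{path}: nonpositive exposure (age_group={scheme.labels[i]!r}, "
            f"year={int(years[j])})"
        )
    return MortalitySurface(
        sex=sex, ages=scheme, years=years, deaths=deaths, exposures=pop
    )


def write_surface(surface: MortalitySurface, path, header: str | None = None) -> None:
    rows = []
    for i, lab in enumerate(surface.ages.labels):
        for j, year in enumerate(surface.years):
            rows.append(
                {
                    "sex": surface.sex,
                    "age_group": lab,
                    "year": int(year),
                    "deaths": int(surface.deaths[i, j]),
                    "population": surface.exposures[i, j],
                }
            )
    _write_csv(pd.DataFrame(rows), path, header)


def read_projection(
    path, sex: str, ages: AgeGroupScheme | None = None
) -> PopulationProjection:
    """Read a long-format projected-population CSV (sex, age_group, year, population)."""
    df = pd.read_csv(path, comment="#")
    missing = set(REQUIRED_PROJECTION_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    scheme, years, mats = _grid_from_long(df, sex, ("population",), ages, str(path))
    return PopulationProjection(
        sex=sex, ages=scheme, years=years, population=mats["population"]
    )


def write_projection(
    proj: PopulationProjection, path, header: str | None = None
) -> None:
    rows = []
    for i, lab in enumerate(proj.ages.labels):
        for t, year in enumerate(proj.years):
            rows.append(
                {
                    "sex": proj.sex,
                    "age_group": lab,
                    "year": int(year),
                    "population": proj.population[i, t],
                }
            )
    _write_csv(pd.DataFrame(rows), path, header)


def write_forecast(obj, path, header: str | None = None) -> None:
    """Write a :class:`RateForecast` or scenario result as long-format CSV.

    Any object with a ``to_frame()`` method producing the standard columns
    (sex, age_group, year, quantity, estimate, lower, upper) is accepted.
    Retained draws are not serialised; the point estimate and interval
    bounds round-trip through :func:`read_forecast`.
    """
    _write_csv(obj.to_frame(), path, header)


def read_forecast(path, sex: str | None = None) -> RateForecast:
    df = pd.read_csv(path, comment="#")
    return RateForecast.from_frame(df, sex=sex)


def _write_csv(df: pd.DataFrame, path, header: str | None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, index=False)
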