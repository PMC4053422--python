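"""Death-count projections under contrasting trend assumptions.

Scenario A is the conventional counterfactual: the last observed death
rates persist unchanged and are multiplied by the projected population.
Scenario B applies a model forecast of declining rates to the same
projection.  Deaths per cell default to ``q * N`` (probability times
persons); the rate-based alternative ``m * N`` — which differs at order
``m^2`` — is available via ``measure="rate"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data import (
    AgeGroupScheme,
    DataError,
    MortalitySurface,
    PopulationProjection,
    RateForecast,
    central_rates,
)

__all__ = [
    "ScenarioResult",
    "FrozenRateForecaster",
    "scenario_constant",
    "scenario_forecast",
    "percent_change",
    "percent_change_combined",
]


@dataclass(frozen=True)
class ScenarioResult:
    """Projected death counts per cell and year with uncertainty bounds.

    ``totals`` is always the column sum of the point estimate; total bounds
    come from summing each retained draw, not from summing cell bounds.
    ``observed_years``/``observed_totals`` carry the historical totals used
    as the reference for percent changes.
    """

    scenario: str
    sex: str
    ages: AgeGroupScheme
    years: np.ndarray
    deaths: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    draws: np.ndarray | None = None
    observed_years: np.ndarray | None = None
    observed_totals: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("deaths", "lower", "upper"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.ages.n, len(self.years)):
                raise DataError(f"scenario {name} shape does not match grid")
            object.__setattr__(self, name, arr)
        if np.any(self.lower > self.deaths + 1e-9) or np.any(
            self.deaths > self.upper + 1e-9
        ):
            raise DataError("scenario bounds must satisfy lower <= point <= upper")

    @property
    def totals(self) -> np.ndarray:
        return self.deaths.sum(axis=0)

    def total_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        if self.draws is None:
            return self.totals, self.totals
        tot = self.draws.sum(axis=1)
        return (
            np.percentile(tot, 2.5, axis=0),
            np.percentile(tot, 97.5, axis=0),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, lab in enumerate(self.ages.labels):
            for t, year in enumerate(self.years):
                rows.append(
                    {
                        "sex": self.sex,
                        "age_group": lab,
                        "year": int(year),
                        "quantity": "deaths",
                        "estimate": self.deaths[i, t],
                        "lower": self.lower[i, t],
                        "upper": self.upper[i, t],
                    }
                )
        return pd.DataFrame(rows)


class FrozenRateForecaster(BaseEstimator):
    """Scenario-A assumption as an estimator: rates frozen at the last year.

    Useful as a baseline in model comparisons; its forecast fed to
    :func:`scenario_forecast` coincides cell-by-cell with
    :func:`scenario_constant`.
    """

    def fit(self, X: MortalitySurface, y=None) -> "FrozenRateForecaster":
        rates = central_rates(X)
        self.q_last_ = rates.q[:, -1].copy()
        self.ages_ = X.ages
        self.years_ = X.years
        self.sex_ = X.sex
        return self

    def forecast(self, horizon: int, seed: int | None = None) -> RateForecast:
        check_is_fitted(self, "q_last_")
        point = np.repeat(self.q_last_[:, None], horizon, axis=1)
        return RateForecast(
            sex=self.sex_,
            ages=self.ages_,
            years=np.arange(self.years_[-1] + 1, self.years_[-1] + 1 + horizon),
            point=point,
            lower=point.copy(),
            upper=point.copy(),
            model="frozen-rate",
        )

    predict = forecast


def _death_matrix(q: np.ndarray, pop: np.ndarray, measure: str) -> np.ndarray:
    if measure == "probability":
        return q * pop
    if measure == "rate":
        return -np.log1p(-q) * pop
    raise ValueError("measure must be 'probability' or 'rate'")


def _check_alignment(ages_a: AgeGroupScheme, ages_b: AgeGroupScheme) -> None:
    if ages_a != ages_b:
        raise DataError("age schemes do not match between inputs")


def scenario_constant(
    surface: MortalitySurface,
    proj: PopulationProjection,
    measure: str = "probability",
    n_sims: int = 1000,
    seed: int | None = None,
) -> ScenarioResult:
    """Scenario A: last-observed rates applied to the projected population.

    Uncertainty, when ``n_sims > 0``, is binomial variation of counts
    around the frozen rates — a construction of this package, documented as
    such since the origin of published scenario-A intervals is generally
    unstated.
    """
    _check_alignment(surface.ages, proj.ages)
    if int(proj.years[0]) != surface.last_year + 1:
        raise DataError(
            "projection must start the year after the last observed year "
            f"({surface.last_year + 1}, got {int(proj.years[0])})"
        )
    rates = central_rates(surface)
    q_last = rates.q[:, -1]
    point = _death_matrix(q_last[:, None], proj.population, measure)
    if n_sims > 0:
        rng = np.random.default_rng(seed)
        npop = np.rint(proj.population).astype(np.int64)
        draws = rng.binomial(
            npop[None, :, :], q_last[None, :, None], size=(n_sims,) + point.shape
        ).astype(float)
        lower, upper = np.percentile(draws, [2.5, 97.5], axis=0)
        lower = np.minimum(lower, point)
        upper = np.maximum(upper, point)
    else:
        draws = None
        lower = point.copy()
        upper = point.copy()
    return ScenarioResult(
        scenario="A (constant rates)",
        sex=surface.sex,
        ages=surface.ages,
        years=proj.years.copy(),
        deaths=point,
        lower=lower,
        upper=upper,
        draws=draws,
        observed_years=surface.years.copy(),
        observed_totals=surface.deaths.sum(axis=0).astype(float),
    )


def scenario_forecast(
    forecast: RateForecast,
    proj: PopulationProjection,
    observed: MortalitySurface | None = None,
    measure: str = "probability",
    label: str = "B (forecast rates)",
) -> ScenarioResult:
    """Scenario B: forecast probabilities applied to the projected population.

    Uses the forecast's retained draws, when present, to propagate
    uncertainty into death counts and totals.  ``observed`` supplies the
    historical totals that percent changes are measured against.
    """
    _check_alignment(forecast.ages, proj.ages)
    if forecast.years.size != proj.years.size or np.any(
        forecast.years != proj.years
    ):
        raise DataError("forecast and projection year grids do not match")
    point = _death_matrix(forecast.point, proj.population, measure)
    if forecast.draws is not None:
        draws = _death_matrix(forecast.draws, proj.population[None, :, :], measure)
        lower, upper = np.percentile(draws, [2.5, 97.5], axis=0)
        lower = np.minimum(lower, point)
        upper = np.maximum(upper, point)
    else:
        draws = None
        lower = _death_matrix(forecast.lower, proj.population, measure)
        upper = _death_matrix(forecast.upper, proj.population, measure)
    return ScenarioResult(
        scenario=label,
        sex=forecast.sex,
        ages=forecast.ages,
        years=proj.years.copy(),
        deaths=point,
        lower=lower,
        upper=upper,
        draws=draws,
        observed_years=observed.years.copy() if observed is not None else None,
        observed_totals=(
            observed.deaths.sum(axis=0).astype(float)
            if observed is not None
            else None
        ),
    )


def _reference_total(result: ScenarioResult, reference_year: int | None) -> float:
    if result.observed_totals is None:
        raise DataError("scenario result carries no observed reference totals")
    years = result.observed_years
    if reference_year is None:
        reference_year = int(years[-1])
    match = np.flatnonzero(years == reference_year)
    if match.size == 0:
        raise DataError(f"reference year {reference_year} not in observed data")
    ref = float(result.observed_totals[match[0]])
    if ref == 0:
        raise DataError("reference-year total is zero")
    return ref


def percent_change(
    result: ScenarioResult, reference_year: int | None = None
) -> pd.DataFrame:
    """Percent change of yearly total deaths versus a reference year.

    ``100 * (total_t - total_ref) / total_ref`` per projected year, with
    2.5/97.5 percentile bounds propagated draw-by-draw when draws were
    retained.  The reference defaults to the last observed year.
    """
    ref = _reference_total(result, reference_year)
    pct = 100.0 * (result.totals - ref) / ref
    if result.draws is not None:
        tot = result.draws.sum(axis=1)
        pct_draws = 100.0 * (tot - ref) / ref
        lower = np.minimum(np.percentile(pct_draws, 2.5, axis=0), pct)
        upper = np.maximum(np.percentile(pct_draws, 97.5, axis=0), pct)
    else:
        lower = pct.copy()
        upper = pct.copy()
    return pd.DataFrame(
        {
            "sex": result.sex,
            "scenario": result.scenario,
            "year": [int(y) for y in result.years],
            "percent_change": pct,
            "lower": lower,
            "upper": upper,
        }
    )


def percent_change_combined(
    results: list[ScenarioResult], reference_year: int | None = None
) -> pd.DataFrame:
    """Percent change of totals pooled over several results (e.g. both sexes)."""
    if not results:
        raise ValueError("need at least one scenario result")
    years = results[0].years
    for r in results[1:]:
        if r.years.size != years.size or np.any(r.years != years):
            raise DataError("scenario results cover different year grids")
    ref = sum(_reference_total(r, reference_year) for r in results)
    totals = sum(r.totals for r in results)
    pct = 100.0 * (totals - ref) / ref
    if all(r.draws is not None for r in results):
        nd = min(r.draws.shape[0] for r in results)
        tot = sum(r.draws[:nd].sum(axis=1) for r in results)
        pct_draws = 100.0 * (tot - ref) / ref
        lower = np.minimum(np.percentile(pct_draws, 2.5, axis=0), pct)
        upper = np.maximum(np.percentile(pct_draws, 97.5, axis=0), pct)
    else:
        lower = pct.copy()
        upper = pct.copy()
    return pd.DataFrame(
        {
            "sex": "combined",
            "scenario": results[0].scenario,
            "year": [int(y) for y in years],
            "percent_change": pct,
            "lower": lower,
            "upper": upper,
        }
    )
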