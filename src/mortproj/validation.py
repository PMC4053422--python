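"""Hold-out forecast validation and model comparison by MAPE.

Models are fitted on an early window, their forecasts compared with the
held-out later window, and accuracy summarised as the mean absolute
percent error of rates per age stratum.  The overall figure is the
unweighted mean across strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .data import (
    DataError,
    MortalitySurface,
    RateForecast,
    RateSurface,
    central_rates,
)

__all__ = ["ValidationReport", "holdout_split", "mape", "compare_models"]


@dataclass
class ValidationReport:
    """MAPE per (model, sex, age group), per-year profiles and winners."""

    by_stratum: pd.DataFrame
    by_year: pd.DataFrame
    overall: dict
    split: tuple
    n_excluded: int = 0
    winner: str | None = None
    winner_by_stratum: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return self.by_stratum.copy()


def holdout_split(
    surface: MortalitySurface, split_year: int
) -> tuple[MortalitySurface, MortalitySurface]:
    """Partition a surface by year: train covers years <= split_year.

    The split year must lie strictly inside the observed range so both
    halves are non-empty; recombining the halves restores the original.
    """
    years = surface.years
    if split_year < int(years[0]) or split_year >= int(years[-1]):
        raise DataError(
            f"split year {split_year} not strictly inside {int(years[0])}-"
            f"{int(years[-1])}"
        )
    mask = years <= split_year
    def _sub(m):
        return MortalitySurface(
            sex=surface.sex,
            ages=surface.ages,
            years=years[m],
            deaths=surface.deaths[:, m],
            exposures=surface.exposures[:, m],
        )
    return _sub(mask), _sub(~mask)


def mape(
    observed: MortalitySurface | RateSurface,
    predicted: RateForecast,
    model: str | None = None,
    on: str = "rate",
) -> ValidationReport:
    """Mean absolute percent error between observed and forecast values.

    Per stratum, ``MAPE = (100 / T) * sum_t |obs_t - pred_t| / obs_t`` over
    the forecast years; cells with a zero observed value are excluded and
    counted in ``n_excluded``.  ``on="rate"`` (default) compares central
    rates, ``on="count"`` compares death counts (requires a
    :class:`MortalitySurface`).
    """
    if isinstance(observed, MortalitySurface):
        obs_rates = central_rates(observed)
        obs_surface = observed
    elif isinstance(observed, RateSurface):
        obs_rates = observed
        obs_surface = None
    else:
        raise TypeError("observed must be a MortalitySurface or RateSurface")
    if observed.ages != predicted.ages:
        raise DataError("age schemes of observation and forecast differ")
    idx = np.flatnonzero(np.isin(obs_rates.years, predicted.years))
    if idx.size != predicted.years.size:
        raise DataError("forecast years are not all covered by the observations")

    if on == "rate":
        obs = obs_rates.m[:, idx]
        pred = predicted.rates()
    elif on == "count":
        if obs_surface is None:
            raise DataError("count-based MAPE needs a MortalitySurface")
        obs = obs_surface.deaths[:, idx].astype(float)
        pred = predicted.point * obs_surface.exposures[:, idx]
    else:
        raise ValueError("on must be 'rate' or 'count'")

    valid = obs > 0
    n_excluded = int(np.sum(~valid))
    ape = np.full(obs.shape, np.nan)
    ape[valid] = 100.0 * np.abs(obs[valid] - pred[valid]) / obs[valid]

    name = model if model is not None else predicted.model
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-excluded strata
        stratum_vals = np.nanmean(ape, axis=1)
        year_vals = np.nanmean(ape, axis=0)
    by_stratum = pd.DataFrame(
        {
            "model": name,
            "sex": predicted.sex,
            "age_group": list(predicted.ages.labels),
            "mape": stratum_vals,
        }
    )
    by_year = pd.DataFrame(
        {
            "model": name,
            "year": [int(y) for y in predicted.years],
            "mape": year_vals,
        }
    )
    overall = {name: float(np.nanmean(stratum_vals))}
    return ValidationReport(
        by_stratum=by_stratum,
        by_year=by_year,
        overall=overall,
        split=(int(predicted.years[0]) - 1, tuple(int(y) for y in predicted.years)),
        n_excluded=n_excluded,
    )


def compare_models(
    surface: MortalitySurface,
    models,
    split_year: int,
    seed: int | None = None,
    on: str = "rate",
) -> ValidationReport:
    """Fit each model on the training window and rank them by hold-out MAPE.

    ``models`` is an ordered sequence of ``(name, estimator)`` pairs; each
    estimator must provide ``fit(surface)`` and ``forecast(horizon, seed)``.
    Estimators are cloned before fitting.  Ties are broken by the declared
    order.  Fit failures are reported per model, not raised.
    """
    models = list(models)
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    train, test = holdout_split(surface, split_year)
    horizon = test.n_years
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(models))]

    reports = []
    errors = {}
    for (name, est), model_seed in zip(models, child_seeds):
        try:
            fitted = clone(est)
            if "seed" in fitted.get_params():
                fitted.set_params(seed=model_seed)
            fitted.fit(train)
            forecast = fitted.forecast(horizon, seed=model_seed)
            reports.append(mape(test, forecast, model=name, on=on))
        except Exception as exc:  # propagate per model, keep the comparison alive
            errors[name] = f"{type(exc).__name__}: {exc}"
    if not reports:
        raise DataError(f"all model fits failed: {errors}")

    by_stratum = pd.concat([r.by_stratum for r in reports], ignore_index=True)
    by_year = pd.concat([r.by_year for r in reports], ignore_index=True)
    overall = {}
    for r in reports:
        overall.update(r.overall)
    order = [r.by_stratum["model"].iloc[0] for r in reports]

    winners = []
    for lab in surface.ages.labels:
        sub = by_stratum[by_stratum["age_group"] == lab]
        vals = {row["model"]: row["mape"] for _, row in sub.iterrows()}
        best = min(order, key=lambda nm: (round(vals[nm], 12), order.index(nm)))
        winners.append({"age_group": lab, "winner": best, "mape": vals[best]})
    winner_overall = min(
        order, key=lambda nm: (round(overall[nm], 12), order.index(nm))
    )

    report = ValidationReport(
        by_stratum=by_stratum,
        by_year=by_year,
        overall=overall,
        split=(split_year, tuple(int(y) for y in test.years)),
        n_excluded=sum(r.n_excluded for r in reports),
        winner=winner_overall,
        winner_by_stratum=pd.DataFrame(winners),
    )
    if errors:
        report.overall.update({f"{k} (failed)": v for k, v in errors.items()})
    return report
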