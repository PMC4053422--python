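"""Lee-Carter mortality forecasting.

The model is ``log m[x, t] = a_x + b_x k_t + e_{xt}``: a single mortality
index ``k_t`` drives the time dynamics, ``a_x`` is the mean log rate by age
and ``b_x`` the age-specific sensitivity to the index.  Identification uses
the standard normalisation ``sum_x b_x = 1`` and ``sum_t k_t = 0``.  The
index is forecast as a random walk with drift (ARIMA(0,1,0) with constant),
the canonical choice.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data import DataError, MortalitySurface, RateForecast, RateSurface

__all__ = ["LeeCarter", "fit_lee_carter", "forecast_lee_carter"]


class LeeCarter(BaseEstimator):
    """Lee-Carter estimator with random-walk-with-drift index forecasting.

    Parameters
    ----------
    zero_adjust : float or None
        Added to zero death counts before logging (surfaces only).  Real
        national data rarely contain empty cells but synthetic data may;
        ``None`` raises on zero cells instead.
    adjust_k : bool
        Apply the second-stage re-estimation of ``k_t``: year by year,
        ``k_t`` is moved so that predicted total deaths given the exposures
        match the observed totals.  Requires a :class:`MortalitySurface`;
        skipped (with ``adjustment_ = "none"``) when fitting a bare
        :class:`RateSurface`.
    jump_off : {"observed", "fitted"}
        Whether forecasts start from the last observed log rates or from the
        fitted ``a + b k_J``.

    Attributes
    ----------
    a_, b_, k_ : ndarray
        Fitted age baseline, age loadings and (adjusted) mortality index.
    k_raw_ : ndarray
        The index from the SVD stage, before the second-stage adjustment.
    drift_ : float
        ``(k_J - k_1) / (J - 1)``, the per-year change of the index.
    sigma_ : float
        Innovation standard deviation of the random walk.
    residuals_ : ndarray
        ``log m - (a + b k)`` on the fitted grid.
    """

    def __init__(
        self,
        zero_adjust: float | None = 0.5,
        adjust_k: bool = True,
        jump_off: str = "observed",
    ):
        self.zero_adjust = zero_adjust
        self.adjust_k = adjust_k
        self.jump_off = jump_off

    def fit(self, X: MortalitySurface | RateSurface, y=None) -> "LeeCarter":
        if self.jump_off not in ("observed", "fitted"):
            raise ValueError("jump_off must be 'observed' or 'fitted'")
        if isinstance(X, MortalitySurface):
            deaths = X.deaths.astype(float)
            if self.zero_adjust is not None:
                deaths = np.where(deaths == 0, deaths + self.zero_adjust, deaths)
            m = deaths / X.exposures
            surface = X
        elif isinstance(X, RateSurface):
            m = X.m.copy()
            surface = None
        else:
            raise TypeError("fit expects a MortalitySurface or RateSurface")
        if np.any(m <= 0):
            raise DataError(
                "nonpositive rate encountered and no zero-adjustment policy"
            )

        logm = np.log(m)
        I, J = logm.shape
        a = logm.mean(axis=1)
        Z = logm - a[:, None]
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        if S[0] < 1e-12:
            # no time variation at all: flat index, uniform loadings
            b = np.full(I, 1.0 / I)
            k = np.zeros(J)
        else:
            b = U[:, 0]
            k = S[0] * Vt[0]
            scale = b.sum()
            if abs(scale) < 1e-12:
                raise DataError("degenerate age loadings (sum b = 0)")
            b = b / scale
            k = k * scale
            a = a + b * k.mean()
            k = k - k.mean()
        self.k_raw_ = k.copy()

        adjustment = "none"
        if self.adjust_k and surface is not None and S[0] >= 1e-12:
            k = np.array(
                [
                    _match_total_deaths(
                        a, b, surface.exposures[:, t], surface.deaths[:, t].sum(), k[t]
                    )
                    for t in range(J)
                ]
            )
            a = a + b * k.mean()
            k = k - k.mean()
            adjustment = "match-total-deaths"

        self.a_ = a
        self.b_ = b
        self.k_ = k
        self.drift_ = float((k[-1] - k[0]) / (J - 1)) if J > 1 else 0.0
        diffs = np.diff(k)
        if diffs.size > 1:
            self.sigma_ = float(
                np.sqrt(np.sum((diffs - self.drift_) ** 2) / (diffs.size - 1))
            )
        else:
            self.sigma_ = 0.0
        self.fitted_logm_ = a[:, None] + np.outer(b, k)
        self.residuals_ = logm - self.fitted_logm_
        self.adjustment_ = adjustment
        self.last_observed_logm_ = logm[:, -1]
        self.ages_ = X.ages
        self.years_ = X.years
        self.sex_ = X.sex
        return self

    def forecast(
        self,
        horizon: int,
        n_sims: int = 1000,
        seed: int | None = None,
        include_draws: bool = False,
    ) -> RateForecast:
        """Forecast rates ``horizon`` years ahead.

        The point forecast follows the deterministic drift path of the
        index; interval bounds are the 2.5/97.5 percentiles over ``n_sims``
        simulated random-walk paths.  Central rates are converted to death
        probabilities ``q = 1 - exp(-m)`` for the returned forecast.
        """
        check_is_fitted(self, "k_")
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        rng = np.random.default_rng(seed)
        h = np.arange(1, horizon + 1, dtype=float)
        if self.jump_off == "observed" and self.last_observed_logm_ is not None:
            jump = self.last_observed_logm_
        else:
            jump = self.fitted_logm_[:, -1]

        point_logm = jump[:, None] + np.outer(self.b_, h * self.drift_)
        point_q = -np.expm1(-np.exp(point_logm))

        if n_sims > 0 and self.sigma_ > 0:
            steps = self.drift_ + rng.normal(0.0, self.sigma_, size=(n_sims, horizon))
            k_inc = np.cumsum(steps, axis=1)  # k_{J+h} - k_J per path
            logm_draws = (
                jump[None, :, None] + self.b_[None, :, None] * k_inc[:, None, :]
            )
            q_draws = -np.expm1(-np.exp(logm_draws))
            lower, upper = np.percentile(q_draws, [2.5, 97.5], axis=0)
            lower = np.minimum(lower, point_q)
            upper = np.maximum(upper, point_q)
        else:
            q_draws = None
            lower = point_q.copy()
            upper = point_q.copy()

        return RateForecast(
            sex=self.sex_,
            ages=self.ages_,
            years=np.arange(self.years_[-1] + 1, self.years_[-1] + 1 + horizon),
            point=point_q,
            lower=lower,
            upper=upper,
            draws=q_draws if include_draws else None,
            model="lee-carter",
        )


def _match_total_deaths(
    a: np.ndarray, b: np.ndarray, N: np.ndarray, observed: float, k0: float
) -> float:
    """Solve sum_i N_i exp(a_i + b_i kappa) = observed total for kappa."""

    def g(kappa: float) -> float:
        # log-scale for overflow safety
        return float(logsumexp(np.log(N) + a + b * kappa) - np.log(observed))

    width = 1.0
    while width < 1e6:
        lo, hi = k0 - width, k0 + width
        if g(lo) * g(hi) <= 0:
            return brentq(g, lo, hi, xtol=1e-12)
        width *= 2.0
    # mixed-sign loadings on degenerate surfaces may leave no exact root;
    # take the closest achievable total instead
    res = minimize_scalar(
        lambda kappa: g(kappa) ** 2, bounds=(k0 - 64.0, k0 + 64.0),
        method="bounded",
    )
    return float(res.x)


def fit_lee_carter(X: MortalitySurface | RateSurface, **params) -> LeeCarter:
    """Fit a :class:`LeeCarter` model; keyword arguments set its parameters."""
    return LeeCarter(**params).fit(X)


def forecast_lee_carter(
    fit: LeeCarter,
    horizon: int,
    n_sims: int = 1000,
    seed: int | None = None,
    include_draws: bool = False,
) -> RateForecast:
    return fit.forecast(horizon, n_sims=n_sims, seed=seed, include_draws=include_draws)
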