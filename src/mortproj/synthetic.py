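"""Synthetic mortality surfaces and population projections.

The generator emulates the statistical structure of national
coronary-heart-disease mortality series: death risk rising roughly
exponentially with age, a sustained multiplicative period decline that may
decelerate, small smooth birth-cohort effects, optional cell-level
overdispersion, and a projected population whose density shifts towards the
oldest ages.  Counts are binomial by default, matching the Bayesian
age-period-cohort likelihood; a Poisson option serves Lee-Carter tests.

The cell structure is ``logit q[i, j] = mu + theta_i + phi_j + psi_k
(+ z_ij)`` with the cohort index ``k = C(I - i) + j``, exactly the grid the
Bayesian model uses, so parameter-recovery tests align one-to-one.  The
generating effects are returned alongside the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .bapc import cohort_index_map
from .data import AgeGroupScheme, MortalitySurface, PopulationProjection, RateSurface

__all__ = [
    "SimulationConfig",
    "simulate_surface",
    "simulate_projection",
    "simulate_lee_carter_surface",
    "lee_carter_rate_surface",
]

#: Default age-specific yearly growth of the projected population.  The old-age
#: values compound over a 19-year horizon to roughly +35% (65-74), +50% (75-84)
#: and +89% (85+), the magnitude of ageing projected for England & Wales.
DEFAULT_AGEING_RATE = (0.002, 0.002, 0.005, 0.0159, 0.0216, 0.0341)

#: Default baseline logit death probabilities by age band, increasing roughly
#: one logit unit per decade of age — an exponential age schedule.
DEFAULT_BASELINE_LOGIT = (-7.4, -5.8, -4.7, -3.9, -3.2, -2.4)

#: Default mid-year populations per sex by age band (persons), shrinking with
#: age as in a real national population.
DEFAULT_POPULATION_BASE = (3.5e6, 3.2e6, 2.8e6, 2.0e6, 1.2e6, 3.0e5)


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of the synthetic mortality world.

    The defaults mirror the desk-scale geometry used throughout the
    documentation: six ten-year age bands observed over 33 years
    (1979-2011 analogue) with a 19-year projection horizon (2012-2030
    analogue), a period decline of 4% per year in the log-odds with a mild
    deceleration, and small cohort effects.
    """

    n_ages: int = 6
    n_periods: int = 33
    band_width: int = 10
    horizon: int = 19
    start_year: int = 1979
    sex: str = "male"
    baseline_logit: Sequence[float] = DEFAULT_BASELINE_LOGIT
    drift: float = -0.04
    deceleration: float = 0.0005
    cohort_sd: float = 0.05
    overdispersion_sd: float = 0.0
    population_base: float | Sequence[float] = DEFAULT_POPULATION_BASE
    ageing_rate: float | Sequence[float] = DEFAULT_AGEING_RATE
    count_model: str = "binomial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ages < 3 or self.n_periods < 3:
            raise ValueError("need at least 3 age groups and 3 periods")
        base = np.asarray(self.baseline_logit, dtype=float)
        if base.size != self.n_ages:
            raise ValueError("baseline_logit length must equal n_ages")
        if not np.all(np.diff(base) > 0):
            raise ValueError("baseline_logit must be strictly increasing in age")
        if np.any(self._population_base() <= 0):
            raise ValueError("population_base must be > 0")
        if self.count_model not in ("binomial", "poisson"):
            raise ValueError("count_model must be 'binomial' or 'poisson'")
        if self.band_width < 1 or self.horizon < 1:
            raise ValueError("band_width and horizon must be >= 1")

    def _population_base(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.population_base, dtype=float), (self.n_ages,)
        ).copy()

    def _ageing_rate(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.ageing_rate, dtype=float), (self.n_ages,)
        ).copy()

    def age_scheme(self) -> AgeGroupScheme:
        lowers = tuple(35 + self.band_width * i for i in range(self.n_ages))
        labels = tuple(
            f"{lo}-{lo + self.band_width - 1}" for lo in lowers[:-1]
        ) + (f"{lowers[-1]}+",)
        return AgeGroupScheme(
            labels=labels, lower_bounds=lowers, width=self.band_width
        )

    def with_(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


def simulate_surface(
    cfg: SimulationConfig,
) -> tuple[MortalitySurface, dict[str, np.ndarray]]:
    """Generate a mortality surface plus the generating ("true") effects.

    The period trend is ``phi_j = drift * u + deceleration * (u^2 - mean)``
    in centred period time ``u``, so ``drift`` is the average yearly change
    of the log-odds; a positive ``deceleration`` flattens the decline late
    in the window.  Cohort effects are a second-order random-walk draw,
    detrended and rescaled to ``cohort_sd``, so they carry curvature but no
    linear component (which would be indistinguishable from period trend).
    Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    I, J, C = cfg.n_ages, cfg.n_periods, cfg.band_width
    kmap = cohort_index_map(I, J, C)
    n_cohorts = C * (I - 1) + J

    base = np.asarray(cfg.baseline_logit, dtype=float)
    mu = float(base.mean())
    theta = base - mu

    u = np.arange(J, dtype=float)
    u -= u.mean()
    phi = cfg.drift * u + cfg.deceleration * (u**2 - np.mean(u**2))
    phi -= phi.mean()

    if cfg.cohort_sd > 0:
        raw = np.cumsum(np.cumsum(rng.standard_normal(n_cohorts)))
        kk = np.arange(n_cohorts, dtype=float)
        kk -= kk.mean()
        raw = raw - raw.mean() - (raw @ kk) / (kk @ kk) * kk
        sd = raw.std()
        psi = cfg.cohort_sd * raw / sd if sd > 0 else np.zeros(n_cohorts)
    else:
        psi = np.zeros(n_cohorts)

    if cfg.overdispersion_sd > 0:
        z = rng.normal(0.0, cfg.overdispersion_sd, size=(I, J))
    else:
        z = np.zeros((I, J))

    eta = mu + theta[:, None] + phi[None, :] + psi[kmap] + z
    q = expit(eta)
    if not (np.all(q > 0.0) and np.all(q < 1.0)):
        raise ValueError("configuration produces death probabilities outside (0, 1)")

    exposures = np.rint(
        np.broadcast_to(cfg._population_base()[:, None], (I, J))
    ).astype(np.int64)
    if cfg.count_model == "binomial":
        deaths = rng.binomial(exposures, q)
    else:
        m = -np.log1p(-q)
        deaths = np.minimum(rng.poisson(exposures * m), exposures)

    surface = MortalitySurface(
        sex=cfg.sex,
        ages=cfg.age_scheme(),
        years=np.arange(cfg.start_year, cfg.start_year + J),
        deaths=deaths,
        exposures=exposures.astype(float),
    )
    truth = {
        "mu": mu,
        "theta": theta,
        "phi": phi,
        "psi": psi,
        "z": z,
        "eta": eta,
        "q": q,
        "cohort_map": kmap,
    }
    return surface, truth


def simulate_projection(cfg: SimulationConfig) -> PopulationProjection:
    """Project the last observed population forward with age-specific growth.

    ``N[i, t] = base_i * (1 + g_i)^t`` for ``t = 1..horizon`` years past the
    observed window; with larger growth at old ages the old-age population
    share strictly increases, emulating population ageing.
    """
    base = cfg._population_base()
    g = cfg._ageing_rate()
    t = np.arange(1, cfg.horizon + 1, dtype=float)
    pop = base[:, None] * (1.0 + g[:, None]) ** t[None, :]
    first = cfg.start_year + cfg.n_periods
    return PopulationProjection(
        sex=cfg.sex,
        ages=cfg.age_scheme(),
        years=np.arange(first, first + cfg.horizon),
        population=pop,
    )


def lee_carter_rate_surface(
    a: np.ndarray,
    b: np.ndarray,
    k: np.ndarray,
    start_year: int = 1979,
    sex: str = "male",
) -> RateSurface:
    """Noiseless rate surface with exactly the structure ``log m = a + b k``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    k = np.asarray(k, dtype=float)
    m = np.exp(a[:, None] + np.outer(b, k))
    lowers = tuple(35 + 10 * i for i in range(a.size))
    labels = tuple(f"{lo}-{lo + 9}" for lo in lowers[:-1]) + (f"{lowers[-1]}+",)
    ages = AgeGroupScheme(labels=labels, lower_bounds=lowers, width=10)
    return RateSurface(
        sex=sex, ages=ages, years=np.arange(start_year, start_year + k.size), m=m
    )


def simulate_lee_carter_surface(
    a: np.ndarray,
    b: np.ndarray,
    k: np.ndarray,
    exposure: float,
    start_year: int = 1979,
    sex: str = "male",
    seed: int = 0,
) -> tuple[MortalitySurface, dict[str, np.ndarray]]:
    """Poisson counts around ``log m = a + b k`` at a common cell exposure."""
    rates = lee_carter_rate_surface(a, b, k, start_year=start_year, sex=sex)
    rng = np.random.default_rng(seed)
    N = np.full(rates.m.shape, float(exposure))
    deaths = np.minimum(rng.poisson(N * rates.m), N).astype(np.int64)
    surface = MortalitySurface(
        sex=sex, ages=rates.ages, years=rates.years, deaths=deaths, exposures=N
    )
    truth = {
        "a": np.asarray(a, float),
        "b": np.asarray(b, float),
        "k": np.asarray(k, float),
        "m": rates.m,
    }
    return surface, truth
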