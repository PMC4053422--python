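"""Bayesian age-period-cohort (APC) modelling of death probabilities.

Model
-----
Deaths in age group ``i`` (1..I, youngest first) and period ``j`` (1..J) are
binomial given the mid-year population::

    D[i, j] ~ Binomial(N[i, j], q[i, j])
    logit q[i, j] = mu + theta_i + phi_j + psi_k (+ z_ij)

with the cohort index ``k = C(I - i) + j`` where ``C`` is the width of the
age bands in periods; the observed window carries ``K = C(I - 1) + J``
cohort parameters.  Age, period and cohort blocks receive intrinsic
Gaussian random-walk smoothing priors of first or second order with Gamma
hyperpriors on their precisions; the optional heterogeneity field ``z`` is
i.i.d. Gaussian with its own precision and absorbs overdispersion beyond
the APC structure.

Identifiability
---------------
The likelihood only identifies the linear predictor: constants can move
between ``mu`` and the blocks, and a linear trend can move jointly between
the period and cohort blocks (with a compensating linear term in age).
Draws are therefore reported in a canonical gauge — every block sums to
zero and the cohort block carries no linear component, the inseparable
linear trend being assigned to the period block.  Forecasts operate on the
identified predictor: prediction canonicalises the draws first, which makes
it invariant to whatever gauge has been applied to the chains.

Sampling
--------
Metropolis-within-Gibbs: adaptive random-walk Metropolis on the effect
blocks (components of a block further apart than the prior order are
conditionally independent given the rest, so each block is updated in
``order + 1`` vectorised "colour" sweeps), Gamma Gibbs steps for the
precisions, and exact translations along the likelihood- and
prior-invariant directions to pin the gauge during the run.  Step sizes
adapt towards ~40% acceptance during burn-in and are frozen afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data import AgeGroupScheme, MortalitySurface, RateForecast

__all__ = [
    "BAPCModelSpec",
    "BAPCPosterior",
    "BayesianAPC",
    "cohort_index",
    "cohort_index_map",
    "fit_bapc",
    "predict_bapc",
    "dic",
    "DICResult",
    "decompose_effects",
    "rw_penalty",
]

_ORDER = {"rw1": 1, "rw2": 2}


def cohort_index(i, j, *, n_ages: int, n_periods: int, band_width: int):
    """Cohort index ``k = C(I - i) + j`` for 1-based age ``i`` and period ``j``.

    The youngest age group is ``i = 1``; the most recent birth cohort
    (youngest age, last period) gets the largest index ``K = C(I-1) + J``.
    Accepts scalars or arrays; raises on out-of-range indices.
    """
    i = np.asarray(i)
    j = np.asarray(j)
    if np.any(i < 1) or np.any(i > n_ages):
        raise ValueError(f"age index out of range 1..{n_ages}")
    if np.any(j < 1) or np.any(j > n_periods):
        raise ValueError(f"period index out of range 1..{n_periods}")
    k = band_width * (n_ages - i) + j
    return k if k.ndim else int(k)


def cohort_index_map(n_ages: int, n_periods: int, band_width: int) -> np.ndarray:
    """0-based cohort index per grid cell (row 0 = youngest age group)."""
    i = np.arange(n_ages)[:, None]
    j = np.arange(n_periods)[None, :]
    return band_width * (n_ages - 1 - i) + j


def rw_penalty(n: int, order: int) -> np.ndarray:
    """Structure matrix ``R = D'D`` of an order-``order`` random walk on n points."""
    if n <= order:
        raise ValueError(f"random walk of order {order} needs > {order} points")
    Dm = np.diff(np.eye(n), n=order, axis=0)
    return Dm.T @ Dm


@dataclass(frozen=True)
class BAPCModelSpec:
    """Priors, heterogeneity switch and chain settings for the APC model.

    Precisions get ``Gamma(tau_shape, tau_rate)`` hyperpriors (shape/rate
    parametrisation); the weakly-informative default ``Gamma(1, 5e-5)``
    leaves the degree of smoothing to the data.  ``fixed_tau`` pins chosen
    block precisions (keys among ``"age", "period", "cohort", "het"``)
    instead of sampling them, which the test-suite's exactness checks use.
    ``include_cohort=False`` reduces the model to age-period only.
    """

    age_prior: str = "rw2"
    period_prior: str = "rw2"
    cohort_prior: str = "rw2"
    heterogeneity: bool = False
    include_cohort: bool = True
    tau_shape: float = 1.0
    tau_rate: float = 5e-5
    het_tau_shape: float = 1.0
    het_tau_rate: float = 5e-5
    chains: int = 2
    iterations: int = 8000
    burnin: int = 3000
    thin: int = 5
    seed: int = 0
    fixed_tau: dict | None = None

    def __post_init__(self) -> None:
        for name in (self.age_prior, self.period_prior, self.cohort_prior):
            if name not in _ORDER:
                raise ValueError(f"prior must be 'rw1' or 'rw2', got {name!r}")
        if not (self.iterations > self.burnin >= 0):
            raise ValueError("need iterations > burnin >= 0")
        if self.thin < 1 or self.chains < 1:
            raise ValueError("thin and chains must be >= 1")
        for v in (
            self.tau_shape,
            self.tau_rate,
            self.het_tau_shape,
            self.het_tau_rate,
        ):
            if v <= 0:
                raise ValueError("hyperparameters must be > 0")

    @property
    def n_stored(self) -> int:
        per_chain = (self.iterations - self.burnin + self.thin - 1) // self.thin
        return per_chain * self.chains


@dataclass
class BAPCPosterior:
    """MCMC draws of the APC model, stored in the canonical gauge."""

    spec: BAPCModelSpec
    sex: str
    ages: AgeGroupScheme
    years: np.ndarray
    band_width: int
    deaths: np.ndarray
    exposures: np.ndarray
    mu: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    psi: np.ndarray | None
    z: np.ndarray | None
    tau: dict
    deviance: np.ndarray
    acceptance: dict
    n_chains: int

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]

    @property
    def n_cohorts(self) -> int:
        I, J = self.deaths.shape
        return self.band_width * (I - 1) + J

    def linear_predictor(self) -> np.ndarray:
        """Per-draw linear predictor eta, shape (n_draws, I, J)."""
        I, J = self.deaths.shape
        eta = (
            self.mu[:, None, None]
            + self.theta[:, :, None]
            + self.phi[:, None, :]
        )
        if self.psi is not None:
            kmap = cohort_index_map(I, J, self.band_width)
            eta = eta + self.psi[:, kmap]
        if self.z is not None:
            eta = eta + self.z
        return eta

    def probabilities(self) -> np.ndarray:
        return expit(self.linear_predictor())


# ---------------------------------------------------------------------------
# gauge handling


def _as2d(x):
    x = np.asarray(x, dtype=float)
    return x[None, :] if x.ndim == 1 else x


def apply_gauge(
    mu,
    theta,
    phi,
    psi,
    band_width: int,
    zero_linear: str = "cohort",
):
    """Project draws onto an identifiability gauge; the linear predictor is
    left exactly unchanged.

    ``zero_linear="cohort"`` (the canonical gauge) centres every block and
    removes the cohort block's linear component, reassigning it to the
    period block (and the compensating age-linear term to the age block).
    ``zero_linear="age"`` instead removes the age block's linear component,
    pushing it into the period and cohort blocks.  Both maps are idempotent
    and map a whole equivalence class of the likelihood to one
    representative.
    """
    scalar = np.asarray(mu).ndim == 0
    mu = np.atleast_1d(np.asarray(mu, dtype=float)).copy()
    theta = _as2d(theta).copy()
    phi = _as2d(phi).copy()
    psi = _as2d(psi).copy() if psi is not None else None
    C = band_width
    I = theta.shape[1]
    J = phi.shape[1]

    def _center():
        nonlocal mu, theta, phi, psi
        mu = mu + theta.mean(axis=1) + phi.mean(axis=1)
        theta = theta - theta.mean(axis=1, keepdims=True)
        phi = phi - phi.mean(axis=1, keepdims=True)
        if psi is not None:
            mu = mu + psi.mean(axis=1)
            psi = psi - psi.mean(axis=1, keepdims=True)

    _center()
    if psi is None:
        if zero_linear == "age":
            raise ValueError("age gauge needs a cohort block to absorb the trend")
        out = (mu, theta, phi, None)
        return tuple(a[0] if (scalar and a is not None and hasattr(a, "ndim")) else a for a in out) if scalar else out

    K = psi.shape[1]
    kk = np.arange(1, K + 1, dtype=float)
    jj = np.arange(1, J + 1, dtype=float)
    ii = np.arange(1, I + 1, dtype=float)

    if zero_linear == "cohort":
        v = kk - kk.mean()
        beta = (psi @ v) / (v @ v)
        psi = psi - beta[:, None] * v[None, :]
        # compensate: + beta * (k - kbar) = beta*C*(I-i) + beta*j - beta*kbar
        theta = theta + beta[:, None] * C * (I - ii)[None, :]
        phi = phi + beta[:, None] * jj[None, :]
        mu = mu - beta * kk.mean()
    elif zero_linear == "age":
        w = ii - ii.mean()
        alpha = (theta @ w) / (w @ w)
        theta = theta - alpha[:, None] * w[None, :]
        # compensate: + alpha*(i - ibar) = (alpha/C)j - (alpha/C)k + alpha(I - ibar)
        phi = phi + (alpha / C)[:, None] * jj[None, :]
        psi = psi - (alpha / C)[:, None] * kk[None, :]
        mu = mu + alpha * (I - ii.mean())
    else:
        raise ValueError("zero_linear must be 'cohort' or 'age'")
    _center()

    if scalar:
        return mu[0], theta[0], phi[0], psi[0]
    return mu, theta, phi, psi


# ---------------------------------------------------------------------------
# sampler


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _colors(n: int, order: int) -> list[np.ndarray]:
    step = order + 1
    return [np.arange(c, n, step) for c in range(step)]


def _run_chain(D, N, band_width, spec: BAPCModelSpec, rng: np.random.Generator):
    I, J = D.shape
    C = band_width
    include_cohort = spec.include_cohort
    orders = {
        "age": _ORDER[spec.age_prior],
        "period": _ORDER[spec.period_prior],
        "cohort": _ORDER[spec.cohort_prior],
    }
    kmap = cohort_index_map(I, J, C) if include_cohort else None
    K = C * (I - 1) + J if include_cohort else 0

    fixed_tau = dict(spec.fixed_tau or {})

    # initial state from the empirical logit
    eta0 = np.log((D + 0.5) / (N - D + 0.5))
    mu = float(eta0.mean())
    theta = eta0.mean(axis=1) - mu
    phi = eta0.mean(axis=0) - mu
    resid = eta0 - (mu + theta[:, None] + phi[None, :])
    if include_cohort:
        counts = np.bincount(kmap.ravel(), minlength=K).astype(float)
        psi = np.bincount(kmap.ravel(), resid.ravel(), minlength=K) / counts
        psi -= psi.mean()
    else:
        psi = None
    z = np.zeros((I, J)) if spec.heterogeneity else None

    blocks = {"age": (theta, orders["age"]), "period": (phi, orders["period"])}
    if include_cohort:
        blocks["cohort"] = (psi, orders["cohort"])
    R = {name: rw_penalty(x.size, o) for name, (x, o) in blocks.items()}
    Rdiag = {name: np.diag(Rm).copy() for name, Rm in R.items()}
    colors = {name: _colors(x.size, o) for name, (x, o) in blocks.items()}
    rank = {name: x.size - o for name, (x, o) in blocks.items()}

    tau = {name: fixed_tau.get(name, 100.0) for name in blocks}
    if spec.heterogeneity:
        tau["het"] = fixed_tau.get("het", 100.0)

    # step-size initialisation from the empirical Fisher information
    q0 = expit(eta0)
    info = N * q0 * (1.0 - q0)
    scales = {
        "mu": 2.4 / np.sqrt(info.sum() + 1.0),
        "age": 2.4 / np.sqrt(info.sum(axis=1).mean() + 1.0),
        "period": 2.4 / np.sqrt(info.sum(axis=0).mean() + 1.0),
    }
    if include_cohort:
        kinfo = np.bincount(kmap.ravel(), info.ravel(), minlength=K)
        scales["cohort"] = 2.4 / np.sqrt(kinfo.mean() + 1.0)
    if spec.heterogeneity:
        scales["het"] = 2.4 / np.sqrt(info.mean() + 1.0)

    eta = mu + theta[:, None] + phi[None, :]
    if include_cohort:
        eta = eta + psi[kmap]
    if z is not None:
        eta = eta + z
    sp = _softplus(eta)

    Dsum = float(D.sum())
    logC = float(np.sum(gammaln(N + 1.0) - gammaln(D + 1.0) - gammaln(N - D + 1.0)))

    all_rw2 = include_cohort and all(o == 2 for o in orders.values())

    n_keep = (spec.iterations - spec.burnin + spec.thin - 1) // spec.thin
    store = {
        "mu": np.empty(n_keep),
        "theta": np.empty((n_keep, I)),
        "phi": np.empty((n_keep, J)),
        "psi": np.empty((n_keep, K)) if include_cohort else None,
        "z": np.empty((n_keep, I, J)) if spec.heterogeneity else None,
        "tau": {name: np.empty(n_keep) for name in tau},
        "deviance": np.empty(n_keep),
    }

    prop_count = {key: 0 for key in scales}
    acc_count = {key: 0 for key in scales}
    total_prop = {key: 0 for key in scales}
    total_acc = {key: 0 for key in scales}

    block_state = {"age": theta, "period": phi}
    if include_cohort:
        block_state["cohort"] = psi

    idx_store = 0
    for it in range(spec.iterations):
        # --- intercept ---
        d = scales["mu"] * rng.standard_normal()
        dll = d * Dsum - float(np.sum(N * (_softplus(eta + d) - sp)))
        prop_count["mu"] += 1
        if np.log(rng.random()) < dll:
            acc_count["mu"] += 1
            mu += d
            eta = eta + d
            sp = _softplus(eta)

        # --- effect blocks, colourised parallel single-site Metropolis ---
        for name in block_state:
            x = block_state[name]
            n = x.size
            Rm = R[name]
            Rx = Rm @ x
            t = tau[name]
            for idx in colors[name]:
                step = scales[name] * rng.standard_normal(idx.size)
                delta = np.zeros(n)
                delta[idx] = step
                if name == "age":
                    deta = np.repeat(delta[:, None], J, axis=1)
                elif name == "period":
                    deta = np.repeat(delta[None, :], I, axis=0)
                else:
                    deta = delta[kmap]
                eta_new = eta + deta
                sp_new = _softplus(eta_new)
                cells = D * deta - N * (sp_new - sp)
                if name == "age":
                    dll_comp = cells.sum(axis=1)
                elif name == "period":
                    dll_comp = cells.sum(axis=0)
                else:
                    dll_comp = np.bincount(kmap.ravel(), cells.ravel(), minlength=n)
                dlp = -0.5 * t * (delta**2 * Rdiag[name] + 2.0 * delta * Rx)
                logr = dll_comp[idx] + dlp[idx]
                acc = np.log(rng.random(idx.size)) < logr
                prop_count[name] += idx.size
                n_acc = int(acc.sum())
                if n_acc:
                    acc_count[name] += n_acc
                    accepted = idx[acc]
                    x[accepted] += step[acc]
                    delta_acc = np.zeros(n)
                    delta_acc[accepted] = step[acc]
                    if name == "age":
                        eta = eta + delta_acc[:, None]
                    elif name == "period":
                        eta = eta + delta_acc[None, :]
                    else:
                        eta = eta + delta_acc[kmap]
                    sp = _softplus(eta)
                    Rx = Rm @ x

        # --- heterogeneity field ---
        if z is not None:
            dz = scales["het"] * rng.standard_normal((I, J))
            eta_new = eta + dz
            sp_new = _softplus(eta_new)
            logr = D * dz - N * (sp_new - sp) - 0.5 * tau["het"] * (
                2.0 * z * dz + dz**2
            )
            accm = np.log(rng.random((I, J))) < logr
            prop_count["het"] += z.size
            acc_count["het"] += int(accm.sum())
            z = np.where(accm, z + dz, z)
            eta = np.where(accm, eta_new, eta)
            sp = np.where(accm, sp_new, sp)

        # --- precisions (Gibbs) ---
        for name in block_state:
            if name in fixed_tau:
                continue
            x = block_state[name]
            quad = float(x @ R[name] @ x)
            tau[name] = rng.gamma(
                spec.tau_shape + 0.5 * rank[name],
                1.0 / (spec.tau_rate + 0.5 * quad),
            )
        if z is not None and "het" not in fixed_tau:
            tau["het"] = rng.gamma(
                spec.het_tau_shape + 0.5 * z.size,
                1.0 / (spec.het_tau_rate + 0.5 * float(np.sum(z**2))),
            )

        # --- gauge translations (exact invariances of the target) ---
        shift = theta.mean() + phi.mean()
        theta -= theta.mean()
        phi -= phi.mean()
        if include_cohort:
            shift += psi.mean()
            psi -= psi.mean()
        mu += shift
        if all_rw2:
            # joint linear translation: prior and likelihood both invariant
            kk = np.arange(1, K + 1, dtype=float)
            v = kk - kk.mean()
            beta = float(psi @ v) / float(v @ v)
            if beta != 0.0:
                psi -= beta * v
                ii = np.arange(1, I + 1, dtype=float)
                theta += beta * C * (I - ii)
                phi += beta * np.arange(1, J + 1, dtype=float)
                mu -= beta * kk.mean()
                mu += theta.mean() + phi.mean()
                theta -= theta.mean()
                phi -= phi.mean()

        # --- adaptation during burn-in ---
        if it < spec.burnin and (it + 1) % 50 == 0:
            for key in scales:
                if prop_count[key]:
                    rate = acc_count[key] / prop_count[key]
                    scales[key] *= float(np.exp(1.2 * (rate - 0.4)))
                    scales[key] = float(np.clip(scales[key], 1e-7, 10.0))
                total_prop[key] += prop_count[key]
                total_acc[key] += acc_count[key]
                prop_count[key] = 0
                acc_count[key] = 0

        # periodic refresh against float drift in the cached predictor
        if (it + 1) % 500 == 0:
            eta = mu + theta[:, None] + phi[None, :]
            if include_cohort:
                eta = eta + psi[kmap]
            if z is not None:
                eta = eta + z
            sp = _softplus(eta)

        # --- storage ---
        if it >= spec.burnin and (it - spec.burnin) % spec.thin == 0:
            store["mu"][idx_store] = mu
            store["theta"][idx_store] = theta
            store["phi"][idx_store] = phi
            if include_cohort:
                store["psi"][idx_store] = psi
            if z is not None:
                store["z"][idx_store] = z
            for name in tau:
                store["tau"][name][idx_store] = tau[name]
            store["deviance"][idx_store] = -2.0 * (
                logC + float(np.sum(D * eta - N * sp))
            )
            idx_store += 1

    for key in scales:
        total_prop[key] += prop_count[key]
        total_acc[key] += acc_count[key]
    store["acceptance"] = {
        key: (total_acc[key] / total_prop[key]) if total_prop[key] else np.nan
        for key in scales
    }
    return store


def fit_bapc(
    surface: MortalitySurface, spec: BAPCModelSpec | None = None, **overrides
) -> BAPCPosterior:
    """Fit the Bayesian APC model by MCMC; reproducible given ``spec.seed``.

    Chains run independently from seeds spawned off ``spec.seed`` and their
    retained draws are concatenated.  Stored draws are projected to the
    canonical gauge (sum-to-zero blocks, cohort linear component assigned
    to period), which leaves every draw's linear predictor unchanged.
    """
    if spec is None:
        spec = BAPCModelSpec(**overrides)
    elif overrides:
        spec = replace(spec, **overrides)
    D = surface.deaths.astype(float)
    N = surface.exposures
    C = surface.ages.width

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    runs = [
        _run_chain(D, N, C, spec, np.random.default_rng(s)) for s in seeds
    ]

    def _cat(key):
        if runs[0][key] is None:
            return None
        return np.concatenate([r[key] for r in runs], axis=0)

    mu = _cat("mu")
    theta = _cat("theta")
    phi = _cat("phi")
    psi = _cat("psi")
    z = _cat("z")
    tau = {
        name: np.concatenate([r["tau"][name] for r in runs])
        for name in runs[0]["tau"]
    }
    deviance = _cat("deviance")
    acceptance = {
        key: float(np.nanmean([r["acceptance"][key] for r in runs]))
        for key in runs[0]["acceptance"]
    }

    if spec.include_cohort:
        mu, theta, phi, psi = apply_gauge(
            mu, theta, phi, psi, C, zero_linear="cohort"
        )
    else:
        mu = mu + theta.mean(axis=1) + phi.mean(axis=1)
        theta = theta - theta.mean(axis=1, keepdims=True)
        phi = phi - phi.mean(axis=1, keepdims=True)

    return BAPCPosterior(
        spec=spec,
        sex=surface.sex,
        ages=surface.ages,
        years=surface.years,
        band_width=C,
        deaths=surface.deaths.copy(),
        exposures=surface.exposures.copy(),
        mu=mu,
        theta=theta,
        phi=phi,
        psi=psi,
        z=z,
        tau=tau,
        deviance=deviance,
        acceptance=acceptance,
        n_chains=spec.chains,
    )


# ---------------------------------------------------------------------------
# prediction


def _extrapolate_rw(
    values: np.ndarray, order: int, sd: np.ndarray, horizon: int, rng
) -> np.ndarray:
    """Sample RW predictive paths ``horizon`` steps past the observed window.

    ``values`` is (n_draws, n) and ``sd`` the per-draw innovation standard
    deviation.  An order-2 walk's predictive mean continues the local
    linear trend ``2 x_n - x_{n-1}``; an order-1 walk continues the last
    level.  Passing a zero ``sd`` gives the predictive mean path exactly.
    """
    nd = values.shape[0]
    out = np.empty((nd, horizon))
    prev = values[:, -1].copy()
    prev2 = values[:, -2].copy() if order == 2 else None
    for h in range(horizon):
        eps = sd * rng.standard_normal(nd)
        if order == 2:
            new = 2.0 * prev - prev2 + eps
            prev2 = prev
        else:
            new = prev + eps
        prev = new
        out[:, h] = new
    return out


def predict_bapc(
    post: BAPCPosterior, horizon: int, seed: int | None = None
) -> RateForecast:
    """Trend-continuing forecast of death probabilities, per retained draw.

    For every draw the period (and cohort) blocks are extended ``horizon``
    steps from their random-walk predictive distributions with that draw's
    innovation precision; future heterogeneity, when the model includes it,
    is drawn from its prior.  Draws are canonicalised first, so the result
    does not depend on any identifiability gauge applied to the chains.
    Cell summaries are the posterior mean and the 2.5/97.5 percentiles.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    spec = post.spec
    I, J = post.deaths.shape
    C = post.band_width
    rng = np.random.default_rng(seed)

    if post.psi is not None:
        mu, theta, phi, psi = apply_gauge(
            post.mu, post.theta, post.phi, post.psi, C, zero_linear="cohort"
        )
    else:
        mu = post.mu + post.theta.mean(axis=1) + post.phi.mean(axis=1)
        theta = post.theta - post.theta.mean(axis=1, keepdims=True)
        phi = post.phi - post.phi.mean(axis=1, keepdims=True)
        psi = None

    nd = mu.shape[0]
    sd_phi = 1.0 / np.sqrt(post.tau["period"])
    phi_fut = _extrapolate_rw(phi, _ORDER[spec.period_prior], sd_phi, horizon, rng)

    eta_f = mu[:, None, None] + theta[:, :, None] + phi_fut[:, None, :]
    if psi is not None:
        K = psi.shape[1]
        sd_psi = 1.0 / np.sqrt(post.tau["cohort"])
        psi_fut = _extrapolate_rw(
            psi, _ORDER[spec.cohort_prior], sd_psi, horizon, rng
        )
        psi_all = np.concatenate([psi, psi_fut], axis=1)
        i0 = np.arange(I)[:, None]
        h0 = np.arange(horizon)[None, :]
        k0f = C * (I - 1 - i0) + J + h0  # 0-based future cohort index
        eta_f = eta_f + psi_all[:, k0f]
    if spec.heterogeneity and post.z is not None:
        sd_z = 1.0 / np.sqrt(post.tau["het"])
        eta_f = eta_f + sd_z[:, None, None] * rng.standard_normal((nd, I, horizon))

    q = expit(eta_f)
    point = q.mean(axis=0)
    lower, upper = np.percentile(q, [2.5, 97.5], axis=0)
    lower = np.minimum(lower, point)
    upper = np.maximum(upper, point)
    return RateForecast(
        sex=post.sex,
        ages=post.ages,
        years=np.arange(post.years[-1] + 1, post.years[-1] + 1 + horizon),
        point=point,
        lower=lower,
        upper=upper,
        draws=q,
        model="bapc",
    )


# ---------------------------------------------------------------------------
# model comparison and effect decomposition


class DICResult(NamedTuple):
    dic: float
    p_d: float
    mean_deviance: float


def _deviance(eta: np.ndarray, D: np.ndarray, N: np.ndarray) -> float:
    logC = float(np.sum(gammaln(N + 1.0) - gammaln(D + 1.0) - gammaln(N - D + 1.0)))
    return -2.0 * (logC + float(np.sum(D * eta - N * _softplus(eta))))

def dic(post: BAPCPosterior) -> DICResult:
    """Deviance information criterion ``DIC = Dbar + pD``.

    ``Dbar`` is the posterior mean deviance (binomial, full constants) and
    ``pD = Dbar - D(eta_bar)`` with the deviance re-evaluated at the
    posterior mean of the cell-level linear predictor.  Smaller DIC
    indicates a better supported, more parsimonious model.
    """
    if post.n_draws < 2:
        raise ValueError("DIC needs at least 2 retained draws")
    dbar = float(post.deviance.mean())
    eta_bar = post.linear_predictor().mean(axis=0)
    dhat = _deviance(eta_bar, post.deaths.astype(float), post.exposures)
    return DICResult(dic=2.0 * dbar - dhat, p_d=dbar - dhat, mean_deviance=dbar)


def decompose_effects(post: BAPCPosterior, gauge: str = "cohort") -> dict:
    """Summarise age/period/cohort effects under an explicit gauge.

    Applies the requested gauge (``"cohort"``: cohort block detrended, the
    canonical choice; ``"age"``: age block detrended) to every draw and
    reports per-element posterior summaries plus each block's share of the
    across-cell variance of the linear predictor.  The gauge changes the
    decomposition, never the fitted probabilities.
    """
    I, J = post.deaths.shape
    if post.psi is not None:
        mu, theta, phi, psi = apply_gauge(
            post.mu, post.theta, post.phi, post.psi, post.band_width,
            zero_linear=gauge,
        )
    else:
        mu, theta, phi, psi = post.mu, post.theta, post.phi, None

    contrib = {"age": np.var(theta, axis=1), "period": np.var(phi, axis=1)}
    if psi is not None:
        kmap = cohort_index_map(I, J, post.band_width)
        contrib["cohort"] = np.var(psi[:, kmap.ravel()], axis=1)
    if post.z is not None:
        contrib["heterogeneity"] = np.var(
            post.z.reshape(post.n_draws, -1), axis=1
        )
    total = sum(contrib.values())
    shares = {name: float(np.mean(c / total)) for name, c in contrib.items()}

    def _summary(x, labels):
        return pd.DataFrame(
            {
                "label": labels,
                "mean": x.mean(axis=0),
                "sd": x.std(axis=0),
                "lower": np.percentile(x, 2.5, axis=0),
                "upper": np.percentile(x, 97.5, axis=0),
            }
        )

    out = {
        "gauge": gauge,
        "mu": {"mean": float(mu.mean()), "sd": float(mu.std())},
        "age": _summary(theta, list(post.ages.labels)),
        "period": _summary(phi, [int(y) for y in post.years]),
        "variance_shares": shares,
    }
    if psi is not None:
        out["cohort"] = _summary(psi, list(range(1, psi.shape[1] + 1)))
    return out


# ---------------------------------------------------------------------------
# estimator facade


class BayesianAPC(BaseEstimator):
    """sklearn-style estimator facade over :func:`fit_bapc`/:func:`predict_bapc`.

    Constructor arguments mirror :class:`BAPCModelSpec`; ``fit`` expects a
    :class:`~mortproj.data.MortalitySurface` and exposes the posterior as
    ``posterior_``.
    """

    def __init__(
        self,
        age_prior: str = "rw2",
        period_prior: str = "rw2",
        cohort_prior: str = "rw2",
        heterogeneity: bool = False,
        include_cohort: bool = True,
        tau_shape: float = 1.0,
        tau_rate: float = 5e-5,
        het_tau_shape: float = 1.0,
        het_tau_rate: float = 5e-5,
        chains: int = 2,
        iterations: int = 8000,
        burnin: int = 3000,
        thin: int = 5,
        seed: int = 0,
        fixed_tau: dict | None = None,
    ):
        self.age_prior = age_prior
        self.period_prior = period_prior
        self.cohort_prior = cohort_prior
        self.heterogeneity = heterogeneity
        self.include_cohort = include_cohort
        self.tau_shape = tau_shape
        self.tau_rate = tau_rate
        self.het_tau_shape = het_tau_shape
        self.het_tau_rate = het_tau_rate
        self.chains = chains
        self.iterations = iterations
        self.burnin = burnin
        self.thin = thin
        self.seed = seed
        self.fixed_tau = fixed_tau

    def _spec(self) -> BAPCModelSpec:
        return BAPCModelSpec(**self.get_params())

    def fit(self, X: MortalitySurface, y=None) -> "BayesianAPC":
        self.posterior_ = fit_bapc(X, self._spec())
        return self

    def forecast(self, horizon: int, seed: int | None = None) -> RateForecast:
        check_is_fitted(self, "posterior_")
        return predict_bapc(self.posterior_, horizon, seed=seed)

    # alias so the estimator reads naturally in sklearn idiom
    predict = forecast

    def dic(self) -> DICResult:
        check_is_fitted(self, "posterior_")
        return dic(self.posterior_)

    def decompose(self, gauge: str = "cohort") -> dict:
        check_is_fitted(self, "posterior_")
        return decompose_effects(self.posterior_, gauge=gauge)
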