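"""Bayesian latent-process Poisson models of yearly abundance trends.

Yearly counts aggregated within a location (or the whole region) are
modelled as ``y_t ~ Poisson(exp(eta_t))`` with three alternative latent
processes on the log mean ``eta_t = mu + u_t``:

* AR1 — stationary first-order autoregression,
  ``u_t = rho u_{t-1} + eps_t``, ``eps_t ~ N(0, 1/tau)``;
* RW1 — first-order random walk, ``u_t - u_{t-1} ~ N(0, 1/tau)``;
* RW2 — second-order random walk, ``u_t - 2 u_{t-1} + u_{t-2} ~ N(0,
  1/tau)``, which favours locally linear latent trends.

The intrinsic RW1/RW2 priors are made identifiable by a sum-to-zero
constraint on the structured part (and, for RW2, an explicit slope with a
vague prior standing in for the flat null-space direction), so the overall
level lives in ``mu``.  Missing survey years are latent states with no
observation term.  Sampling is a seeded adaptive Metropolis chain over a
whitened parameterisation; per-observation log-likelihood draws feed the
WAIC/CPO comparison, and the chosen model minimises the WAIC + LCPO rank
sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .model_eval import cpo, waic
from .samplers import (AdaptiveMVN, AdaptiveScalar, PcnScale,
                       metropolis_accept)

MODEL_TYPES = ("AR1", "RW1", "RW2")
#: count of process hyperparameters, the tie-break in model comparison
HYPER_COUNT = {"RW1": 1, "AR1": 2, "RW2": 2}
MIN_YEARS = {"AR1": 3, "RW1": 3, "RW2": 4}


@dataclass(frozen=True)
class CountSeries:
    """Yearly aggregated counts for one location (or 'all') and life stage."""

    label: str
    life_stage: str
    years: tuple[int, ...]
    counts: tuple[int, ...]
    effort: tuple[int, ...]           # number of censuses per year

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    @property
    def gaps(self) -> tuple[int, ...]:
        if not self.years:
            return ()
        full = range(self.years[0], self.years[-1] + 1)
        return tuple(y for y in full if y not in self.years)


@dataclass
class TrendFit:
    model_type: str
    series: CountSeries
    years_latent: tuple[int, ...]      # contiguous year range of the latent
    fitted: pd.DataFrame               # year, post_mean, q2.5, q97.5 (of exp eta)
    draws: dict[str, np.ndarray]       # eta (S,T), mu, tau, rho/slope
    loglik: np.ndarray                 # (S, n observed years)
    waic: float
    p_waic: float
    lcpo: float
    seed: int
    accept_rate: float = 0.0


def aggregate_counts(records: pd.DataFrame, group: str = "location",
                     life_stage: str = "juvenile",
                     label: str | None = None) -> list[CountSeries] | CountSeries:
    """Aggregate census counts into yearly series.

    ``group='location'`` returns one series per location;
    ``group='all'`` pools every location into a single region-wide series.
    Years with no censuses are simply absent (the latent process bridges
    the gap).  Input record order never matters.
    """
    df = records[records["life_stage"] == life_stage]
    if group == "all":
        grouped = df.groupby("year")["count"]
        years = tuple(int(y) for y in grouped.sum().index)
        return CountSeries(label=label or "all", life_stage=life_stage,
                           years=years,
                           counts=tuple(int(c) for c in grouped.sum()),
                           effort=tuple(int(c) for c in grouped.size()))
    if group != "location":
        raise ValueError("group must be 'location' or 'all'")
    out = []
    for loc, sub in df.groupby("location"):
        grouped = sub.groupby("year")["count"]
        out.append(CountSeries(
            label=str(loc), life_stage=life_stage,
            years=tuple(int(y) for y in grouped.sum().index),
            counts=tuple(int(c) for c in grouped.sum()),
            effort=tuple(int(c) for c in grouped.size())))
    return out


@dataclass(frozen=True)
class GuardReport:
    excluded: bool
    reasons: tuple[str, ...]
    dropped_years: tuple[int, ...]


def series_guard(series: CountSeries, min_total: int = 10,
                 drop_years: Iterable[int] = ()) -> tuple[CountSeries, GuardReport]:
    """Exclusion rules for low-information series.

    A series whose total count falls below ``min_total`` is marked excluded
    (too few individuals to support a trend, as with a location that
    yielded a single juvenile); explicitly listed years are removed, the
    remedy for years with too few censuses.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    drop = set(int(y) for y in drop_years)
    keep = [i for i, y in enumerate(series.years) if y not in drop]
    filtered = CountSeries(
        label=series.label, life_stage=series.life_stage,
        years=tuple(series.years[i] for i in keep),
        counts=tuple(series.counts[i] for i in keep),
        effort=tuple(series.effort[i] for i in keep))
    reasons = []
    dropped = tuple(sorted(set(series.years) & drop))
    if dropped:
        reasons.append(f"year(s) {list(dropped)} removed by request")
    if filtered.total < min_total:
        reasons.append(f"low total count ({filtered.total} < {min_total})")
    excluded = filtered.total < min_total
    return filtered, GuardReport(excluded=excluded, reasons=tuple(reasons),
                                 dropped_years=dropped)


# ---------------------------------------------------------------------------
# Latent-process machinery
# ---------------------------------------------------------------------------

def _structure_basis(T: int, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-basis of the RW structure matrix restricted to its row space.

    Returns ``(V, lam)`` with ``V`` of shape (T, T-order) and positive
    eigenvalues ``lam``; the null space (constant, and linear for order 2)
    is excluded, which enforces the sum-to-zero constraint.
    """
    D = np.diff(np.eye(T), n=order, axis=0)
    R = D.T @ D
    lam, V = np.linalg.eigh(R)
    keep = lam > 1e-8
    return V[:, keep], lam[keep]


def _unpack(model_type: str, theta: np.ndarray, T: int,
            V: np.ndarray | None, lam: np.ndarray | None,
            t_lin: np.ndarray | None):
    """theta -> (mu, u, tau, extra) for each latent model."""
    mu = theta[0]
    log_tau = theta[1]
    tau = np.exp(log_tau)
    if model_type == "AR1":
        z_rho = theta[2]
        rho = np.tanh(z_rho / 2.0)          # logit((rho+1)/2) ~ N(0,1)
        e = theta[3:]
        u = np.empty(T)
        u[0] = e[0] / np.sqrt(tau * (1.0 - rho ** 2))
        sd = 1.0 / np.sqrt(tau)
        for t in range(1, T):
            u[t] = rho * u[t - 1] + sd * e[t]
        return mu, u, tau, {"rho": rho, "white": e}
    if model_type == "RW1":
        z = theta[2:]
        u = V @ (z / np.sqrt(tau * lam))
        return mu, u, tau, {"white": z}
    if model_type == "RW2":
        slope = theta[2]
        z = theta[3:]
        u = slope * t_lin + V @ (z / np.sqrt(tau * lam))
        return mu, u, tau, {"slope": slope, "white": z}
    raise ValueError(f"unknown model_type {model_type!r}")


def _poisson_ll(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return y * eta - np.exp(eta) - gammaln(y + 1.0)


def fit_trend(series: CountSeries, model_type: str, seed: int = 0,
              draws: int = 1200, warmup: int = 4000,
              thin: int = 3) -> TrendFit:
    """Fit one latent-process Poisson trend model to a yearly count series."""
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model_type {model_type!r}; "
                         f"choose from {MODEL_TYPES}")
    n_obs = len(series.years)
    if n_obs < MIN_YEARS[model_type]:
        raise ValueError(f"{model_type} needs at least "
                         f"{MIN_YEARS[model_type]} observed years, "
                         f"got {n_obs}")
    y0, y1 = series.years[0], series.years[-1]
    years_latent = tuple(range(y0, y1 + 1))
    T = len(years_latent)
    obs_pos = np.array([y - y0 for y in series.years])
    y = np.asarray(series.counts, dtype=float)

    V = lam = t_lin = None
    if model_type in ("RW1", "RW2"):
        V, lam = _structure_basis(T, 1 if model_type == "RW1" else 2)
    if model_type == "RW2":
        t_raw = np.arange(T, dtype=float)
        t_lin = (t_raw - t_raw.mean())
        t_lin = t_lin / np.sqrt(np.sum(t_lin ** 2))

    dim_white = {"AR1": T, "RW1": T - 1, "RW2": T - 2}[model_type]
    dim = 2 + dim_white + (1 if model_type in ("AR1", "RW2") else 0)

    def logpost(theta):
        mu, u, tau, extra = _unpack(model_type, theta, T, V, lam, t_lin)
        eta = mu + u
        ll = _poisson_ll(y, eta[obs_pos]).sum()
        lp = -0.5 * (mu / 10.0) ** 2                     # mu ~ N(0, 100)
        log_tau = theta[1]
        lp += log_tau - 0.01 * tau                       # tau ~ Gamma(1, .01)
        lp += -0.5 * np.sum(extra["white"] ** 2)         # whitened states
        if model_type == "AR1":
            lp += -0.5 * theta[2] ** 2                   # z_rho ~ N(0, 1)
        if model_type == "RW2":
            lp += -0.5 * (extra["slope"] / 10.0) ** 2    # vague slope prior
        return ll + lp

    def ar1_quadform(u, rho):
        # u' K(rho) u for the stationary AR1 precision (unit innovation var)
        return float((1 - rho ** 2) * u[0] ** 2
                     + np.sum((u[1:] - rho * u[:-1]) ** 2))

    def rewhiten(theta, u, tau, rho=None):
        """Refresh the whitened coordinates after a centred hyper update."""
        if model_type == "AR1":
            e = np.empty(T)
            e[0] = u[0] * np.sqrt(tau * (1 - rho ** 2))
            e[1:] = (u[1:] - rho * u[:-1]) * np.sqrt(tau)
            theta[3:] = e
        elif model_type == "RW1":
            theta[2:] = np.sqrt(tau * lam) * (V.T @ u)
        else:
            slope = float(t_lin @ u)
            theta[2] = slope
            theta[3:] = np.sqrt(tau * lam) * (V.T @ (u - slope * t_lin))
        return theta

    a0, b0 = 1.0, 0.01          # tau ~ Gamma(1, 0.01)
    rank = {"AR1": T, "RW1": T - 1, "RW2": T - 2}[model_type]

    # initialise the latent path at the (interpolated) observed log counts:
    # starting at u = 0 puts tau | u in a funnel it cannot escape
    log_obs = np.log(y + 0.5)
    u_init = np.interp(np.arange(T), obs_pos, log_obs)
    mu0 = float(u_init.mean())
    u_init = u_init - mu0
    if model_type == "AR1":
        resid = u_init[1:] - 0.5 * u_init[:-1]
    else:
        resid = np.diff(u_init, n=1 if model_type == "RW1" else 2)
    tau0 = float(np.clip(1.0 / max(np.var(resid), 1e-3), 0.1, 100.0))
    x = np.zeros(dim)
    x[0] = mu0
    x[1] = np.log(tau0)
    x = rewhiten(x, u_init, tau0,
                 rho=np.tanh(x[2] / 2.0) if model_type == "AR1" else None)
    rng = np.random.default_rng(seed)
    prop = AdaptiveMVN(dim, init_scale=0.05)
    prop_rho = AdaptiveScalar(0.5)
    pcn = PcnScale(0.3)
    white_sl = slice(3, None) if model_type in ("AR1", "RW2") else slice(2, None)
    lp = logpost(x)
    total = warmup + draws * thin
    chain = []
    accepts = 0
    for it in range(total):
        if it == warmup:
            prop.freeze()
            prop_rho.freeze()

        # 1. non-centred adaptive Metropolis over the whole vector
        x_new = prop.propose(x, rng)
        lp_new = logpost(x_new)
        lr = lp_new - lp
        a = float(np.exp(min(lr, 0.0))) if np.isfinite(lr) else 0.0
        if np.isfinite(lp_new) and metropolis_accept(lr, rng):
            x, lp = x_new, lp_new
            accepts += it >= warmup
        prop.update(x, a)

        # 1b. pCN refresh of the whitened coordinates (standard-normal
        #     prior cancels; acceptance is the likelihood ratio alone)
        x_new = x.copy()
        b = pcn.beta
        x_new[white_sl] = (np.sqrt(1 - b ** 2) * x[white_sl]
                          + b * rng.standard_normal(dim_white))
        lp_new = logpost(x_new)
        # Hastings ratio of the pCN proposal cancels the N(0, I) prior
        lr = (lp_new - lp
              + 0.5 * (np.sum(x_new[white_sl] ** 2) - np.sum(x[white_sl] ** 2)))
        a = float(np.exp(min(lr, 0.0))) if np.isfinite(lr) else 0.0
        if np.isfinite(lp_new) and metropolis_accept(lr, rng):
            x, lp = x_new, lp_new
        pcn.update(a)
        if it == warmup - 1:
            pcn.frozen = True

        # 2. centred (interweaved) hyper updates given the latent path:
        #    conjugate Gibbs for tau, scalar MH for the AR1 correlation
        mu, u, tau, extra = _unpack(model_type, x, T, V, lam, t_lin)
        if model_type == "AR1":
            rho = extra["rho"]
            S = ar1_quadform(u, rho)
            tau = rng.gamma(a0 + rank / 2.0, 1.0 / (b0 + S / 2.0))
            x[1] = np.log(tau)

            z_old = x[2]
            z_new = prop_rho.propose_scalar(z_old, rng)

            def rho_lp(z):
                r = np.tanh(z / 2.0)
                return (0.5 * np.log1p(-r ** 2)
                        - 0.5 * tau * ar1_quadform(u, r) - 0.5 * z ** 2)
            lr = rho_lp(z_new) - rho_lp(z_old)
            a = float(np.exp(min(lr, 0.0)))
            if metropolis_accept(lr, rng):
                x[2] = z_new
                rho = np.tanh(z_new / 2.0)
            prop_rho.update_scalar(x[2], a)
            x = rewhiten(x, u, tau, rho)
        else:
            order = 1 if model_type == "RW1" else 2
            S = float(np.sum(np.diff(u, n=order) ** 2))
            tau = rng.gamma(a0 + rank / 2.0, 1.0 / (b0 + S / 2.0))
            x[1] = np.log(tau)
            x = rewhiten(x, u, tau)
        lp = logpost(x)

        if it >= warmup and (it - warmup) % thin == 0:
            chain.append(x.copy())
    chain = np.asarray(chain)
    rate = accepts / max(draws * thin, 1)

    S = chain.shape[0]
    eta_draws = np.empty((S, T))
    rho_draws = np.empty(S) if model_type == "AR1" else None
    slope_draws = np.empty(S) if model_type == "RW2" else None
    ll_draws = np.empty((S, n_obs))
    mu_draws, tau_draws = np.empty(S), np.empty(S)
    for s in range(S):
        mu, u, tau, extra = _unpack(model_type, chain[s], T, V, lam, t_lin)
        eta_draws[s] = mu + u
        mu_draws[s], tau_draws[s] = mu, tau
        if rho_draws is not None:
            rho_draws[s] = extra["rho"]
        if slope_draws is not None:
            slope_draws[s] = extra["slope"]
        ll_draws[s] = _poisson_ll(y, eta_draws[s][obs_pos])

    lam_draws = np.exp(eta_draws)
    q = np.quantile(lam_draws, [0.025, 0.975], axis=0)
    fitted = pd.DataFrame({
        "year": years_latent,
        "post_mean": lam_draws.mean(axis=0),
        "q2.5": q[0],
        "q97.5": q[1],
        "observed": [yv in series.years for yv in years_latent],
    })
    w, p_w = waic(ll_draws)
    _, lcpo = cpo(ll_draws)
    d = {"eta": eta_draws, "mu": mu_draws, "tau": tau_draws}
    if rho_draws is not None:
        d["rho"] = rho_draws
    if slope_draws is not None:
        d["slope"] = slope_draws
    return TrendFit(model_type=model_type, series=series,
                    years_latent=years_latent, fitted=fitted, draws=d,
                    loglik=ll_draws, waic=w, p_waic=p_w, lcpo=lcpo,
                    seed=seed, accept_rate=rate)


@dataclass
class TrendComparison:
    fits: dict[str, TrendFit]
    table: pd.DataFrame            # model, waic, lcpo, rank_sum, chosen
    chosen: str


#: information-criterion difference treated as "equivalent support"
WAIC_EQUIVALENCE = 2.0


def compare_trends(series: CountSeries, seed: int = 0,
                   draws: int = 1200, warmup: int = 4000,
                   thin: int = 3,
                   equivalence: float = WAIC_EQUIVALENCE) -> TrendComparison:
    """Fit every admissible latent model; choose the best, most parsimonious.

    Models are ranked by WAIC and LCPO (minimal rank sum).  Models whose
    WAIC lies within ``equivalence`` units of the rank-sum winner's (and
    LCPO within the per-observation equivalent) carry indistinguishable
    support, and among those the one with fewest process hyperparameters
    wins (RW1 before AR1/RW2), ties then resolved by the rank order.
    Models whose minimum series length is not met are skipped.
    """
    fits = {}
    for i, mt in enumerate(MODEL_TYPES):
        if len(series.years) >= MIN_YEARS[mt]:
            fits[mt] = fit_trend(series, mt, seed=seed + i, draws=draws,
                                 warmup=warmup, thin=thin)
    if not fits:
        raise ValueError("series too short for every latent model")
    tab = pd.DataFrame([{
        "model": mt, "waic": f.waic, "lcpo": f.lcpo,
        "n_hyper": HYPER_COUNT[mt],
    } for mt, f in fits.items()])
    tab["rank_sum"] = (tab["waic"].rank(method="min")
                       + tab["lcpo"].rank(method="min"))
    tab = tab.sort_values(["rank_sum", "n_hyper", "waic"],
                          kind="mergesort").reset_index(drop=True)
    best = tab.iloc[0]
    n_obs = len(series.years)
    equiv = tab[(tab["waic"] <= best["waic"] + equivalence)
                & (tab["lcpo"] <= best["lcpo"] + equivalence / (2 * n_obs))]
    chosen = equiv.sort_values(["n_hyper"], kind="mergesort").iloc[0]["model"]
    tab["chosen"] = tab["model"] == chosen
    return TrendComparison(fits=fits, table=tab, chosen=chosen)


def trend_direction(fit: TrendFit, from_year: int, to_year: int,
                    declining_threshold: float = 0.9,
                    increasing_threshold: float = 0.1) -> tuple[str, float]:
    """Posterior direction of the latent trend between two years.

    Returns ``(label, p_decline)`` where ``p_decline`` is the posterior
    probability that the latent log mean at ``to_year`` is below that at
    ``from_year``; declining if >= ``declining_threshold``, increasing if
    <= ``increasing_threshold``, flat otherwise.
    """
    for yname, yv in (("from_year", from_year), ("to_year", to_year)):
        if yv not in fit.years_latent:
            raise ValueError(f"{yname} {yv} outside the fitted range "
                             f"{fit.years_latent[0]}–{fit.years_latent[-1]}")
    i = fit.years_latent.index(from_year)
    j = fit.years_latent.index(to_year)
    eta = fit.draws["eta"]
    p_decline = float(np.mean(eta[:, j] < eta[:, i]))
    if p_decline >= declining_threshold:
        return "declining", p_decline
    if p_decline <= increasing_threshold:
        return "increasing", p_decline
    return "flat", p_decline
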