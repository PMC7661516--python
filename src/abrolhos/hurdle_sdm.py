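"""Two-stage Bayesian hurdle spatio-temporal model for juvenile densities.

Visual-census densities of juvenile parrotfish are strongly zero-inflated,
so occurrence and abundance are modelled separately (a hurdle, or delta,
model):

* stage 1 — presence/absence of juveniles per census, Bernoulli with a
  logit link;
* stage 2 — the strictly positive densities, Gamma with a log link on the
  mean, fitted only to censuses where the species occurred.

Both stages share the same linear-predictor structure with independent
parameters: standardized benthic + environmental covariates (vague
``N(0, 100)`` priors on coefficients), a year factor (first year as
reference), an observer random effect, and a spatially structured Matérn
random field on site coordinates that absorbs residual spatial
autocorrelation.  The field is static and shared across years; temporal
structure enters through the year factor.

Inference is a seeded adaptive Metropolis-within-Gibbs sampler: a joint
adaptive random-walk block for the fixed effects, vectorised per-level
updates for the observer effects, preconditioned Crank–Nicolson updates
for the latent field, and scalar adaptive updates for the hyperparameters.
The posterior is the contract, not the algorithm; per-observation
log-likelihood draws are retained for WAIC/CPO.

The combined prediction is the delta-model expectation
``E[density] = Pr(presence) * E[density | presence]``; both components are
also reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import spatial
from .samplers import (AdaptiveMVN, AdaptiveScalar, PcnScale, RmScale,
                       metropolis_accept, pcn_propose, summarise_draws)
from .spatial import SpatialFieldParams


@dataclass(frozen=True)
class Hyperpriors:
    """Hyperpriors for the random-effect and field parameters.

    Half-Normal scales for the observer and field standard deviations,
    log-Normal for the practical range (km), Gamma(shape, rate) for the
    Gamma-stage shape parameter.
    """

    obs_sd_scale: float = 2.0
    field_sd_scale: float = 2.0
    field_range_log_mean: float = math.log(20.0)
    field_range_log_sd: float = 1.0
    shape_a: float = 2.0
    shape_rate: float = 0.5


@dataclass(frozen=True)
class HurdleSpec:
    """Structure of both hurdle stages (terms share names across stages)."""

    terms: tuple[str, ...]
    include_observer_effect: bool = True
    include_year_factor: bool = True
    include_spatial_field: bool = True
    prior_fixed_sd: float = 10.0          # N(0, 100) on fixed effects
    hyper: Hyperpriors = field(default_factory=Hyperpriors)

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))

    def without_term(self, term: str) -> "HurdleSpec":
        if term not in self.terms:
            raise ValueError(f"term {term!r} not in spec")
        return replace(self, terms=tuple(t for t in self.terms if t != term))


@dataclass
class DesignInfo:
    """Design-matrix builder with frozen training-set transforms."""

    terms: tuple[str, ...]
    colnames: list[str]
    center: dict[str, float]
    scale: dict[str, float]
    binary: frozenset[str]
    years: tuple[int, ...]            # ordered; first is the reference level
    include_year_factor: bool

    def _base_column(self, df: pd.DataFrame, name: str) -> np.ndarray:
        if name not in df.columns:
            raise KeyError(f"covariate {name!r} absent from table")
        col = df[name].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(col))
        if len(bad):
            site = df.iloc[bad[0]].get("site_id", f"row {bad[0]}")
            raise ValueError(f"missing value for covariate {name!r} at "
                             f"site {site}")
        if name in self.binary:
            return col
        return (col - self.center[name]) / self.scale[name]

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        """Design matrix for new rows under the stored transforms."""
        cols = [np.ones(len(df))]
        for term in self.terms:
            if ":" in term:
                a, b = term.split(":")
                cols.append(self._base_column(df, a) * self._base_column(df, b))
            else:
                cols.append(self._base_column(df, term))
        if self.include_year_factor:
            years = df["year"].to_numpy()
            for yr in self.years[1:]:
                cols.append((years == yr).astype(float))
        return np.column_stack(cols)


def build_design(covariate_rows: pd.DataFrame, spec: HurdleSpec,
                 years: Sequence[int] | None = None) -> tuple[np.ndarray, DesignInfo]:
    """Design matrix and reusable transform info from training rows.

    Continuous covariates are centred and scaled by the training rows'
    statistics; binary (0/1) covariates are left untouched.  The year
    factor is dummy-coded with the first year as reference.  Interaction
    terms ``a:b`` are products of the transformed base columns.
    """
    base_names = sorted({n for t in spec.terms for n in t.split(":")})
    center, scale, binary = {}, {}, set()
    for name in base_names:
        if name not in covariate_rows.columns:
            raise KeyError(f"covariate {name!r} absent from table")
        col = covariate_rows[name].to_numpy(dtype=float)
        if np.isin(col[np.isfinite(col)], (0.0, 1.0)).all():
            binary.add(name)
            continue
        center[name] = float(np.nanmean(col))
        s = float(np.nanstd(col))
        scale[name] = s if s > 0 else 1.0
    if spec.include_year_factor:
        if years is None:
            if "year" not in covariate_rows.columns:
                raise ValueError("year factor requested but no years given")
            years = sorted(covariate_rows["year"].unique())
        years = tuple(int(y) for y in years)
    else:
        years = ()
    colnames = ["intercept"] + list(spec.terms) + \
        [f"year_{y}" for y in years[1:]]
    info = DesignInfo(terms=spec.terms, colnames=colnames, center=center,
                      scale=scale, binary=frozenset(binary), years=years,
                      include_year_factor=spec.include_year_factor)
    return info.matrix(covariate_rows), info


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # log p(y | eta) with logit link, stable at large |eta|
    return y * eta - np.logaddexp(0.0, eta)


def _gamma_ll(y: np.ndarray, eta: np.ndarray, shape: float) -> np.ndarray:
    # Gamma with log link on the mean: rate = shape / mu
    log_mu = eta
    return (shape * (np.log(shape) - log_mu) + (shape - 1.0) * np.log(y)
            - shape * y * np.exp(-log_mu) - gammaln(shape))


# ---------------------------------------------------------------------------
# Single-stage sampler
# ---------------------------------------------------------------------------

@dataclass
class StageFit:
    """Posterior draws and summaries for one hurdle stage."""

    family: str
    summary: pd.DataFrame
    draws: dict[str, np.ndarray]
    loglik: np.ndarray                 # (draws, observations)
    colnames: list[str]
    observer_levels: tuple[str, ...]
    site_ids: tuple[str, ...]
    accept: dict[str, float]
    seed: int

    def field_params_posterior_mean(self) -> SpatialFieldParams | None:
        if "sigma_w" not in self.draws:
            return None
        return SpatialFieldParams(
            marginal_sd=float(np.mean(self.draws["sigma_w"])),
            range_km=float(np.mean(self.draws["range_w"])))


def _fit_stage(family: str, y: np.ndarray, X: np.ndarray,
               colnames: list[str], spec: HurdleSpec,
               site_idx: np.ndarray | None = None,
               coords: np.ndarray | None = None,
               obs_idx: np.ndarray | None = None,
               n_observers: int = 0,
               seed: int = 0, draws: int = 800, warmup: int = 1000,
               thin: int = 2,
               site_ids: tuple[str, ...] = (),
               observer_levels: tuple[str, ...] = ()) -> StageFit:
    """Adaptive Metropolis-within-Gibbs for one stage of the hurdle model."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    hp = spec.hyper
    use_obs = spec.include_observer_effect and n_observers > 0
    use_field = spec.include_spatial_field and coords is not None
    is_gamma = family == "gamma"

    beta = np.zeros(p)
    if not is_gamma:
        # start the intercept at the empirical logit
        frac = np.clip(y.mean(), 1e-3, 1 - 1e-3)
        beta[0] = np.log(frac / (1 - frac))
    else:
        beta[0] = float(np.log(y.mean()))
    u = np.zeros(n_observers)
    log_sig_obs = np.log(0.5)
    w = np.zeros(len(coords)) if use_field else None
    log_sig_w, log_rho_w = np.log(0.5), np.log(15.0)
    log_shape = 0.0

    xb = X @ beta
    uo = u[obs_idx] if use_obs else 0.0
    wv = w[site_idx] if use_field else 0.0

    def loglik(eta):
        if is_gamma:
            return _gamma_ll(y, eta, np.exp(log_shape))
        return _bernoulli_ll(y, eta)

    def chol_field():
        return spatial.chol_cov(
            coords, SpatialFieldParams(np.exp(log_sig_w), np.exp(log_rho_w)))

    L_w = chol_field() if use_field else None

    prop_beta = AdaptiveMVN(p, init_scale=0.1)
    prop_obs_scale = RmScale(0.3)             # shared step for level updates
    prop_sig_obs = AdaptiveScalar(0.3)
    prop_hyper = AdaptiveMVN(2, init_scale=0.2)
    prop_shape = AdaptiveScalar(0.2)
    pcn = PcnScale(0.2)

    beta_var = spec.prior_fixed_sd ** 2
    ll_cur = loglik(xb + uo + wv)
    acc = {"beta": 0, "field": 0, "hyper": 0}
    total = warmup + draws * thin
    kept = {k: [] for k in ("beta", "sigma_obs", "u_obs", "w", "sigma_w",
                            "range_w", "shape")}
    kept_ll = []

    def halfnormal_lp(s, scale):
        return -0.5 * (s / scale) ** 2

    for it in range(total):
        if it == warmup:
            for pr in (prop_beta, prop_sig_obs, prop_hyper, prop_shape):
                pr.freeze()
            prop_obs_scale.freeze()
            pcn.frozen = True

        # --- fixed effects block
        beta_new = prop_beta.propose(beta, rng)
        xb_new = X @ beta_new
        ll_new = loglik(xb_new + uo + wv)
        lr = (ll_new.sum() - ll_cur.sum()
              + (beta @ beta - beta_new @ beta_new) / (2 * beta_var))
        a = float(np.exp(min(lr, 0.0)))
        if metropolis_accept(lr, rng):
            beta, xb, ll_cur = beta_new, xb_new, ll_new
            acc["beta"] += it >= warmup
        prop_beta.update(beta, a)

        # --- observer effects (levels partition rows: vectorised MH)
        if use_obs:
            step = prop_obs_scale.scale
            u_new = u + step * rng.standard_normal(n_observers)
            ll_new = loglik(xb + u_new[obs_idx] + wv)
            d_lik = np.bincount(obs_idx, weights=ll_new - ll_cur,
                                minlength=n_observers)
            sig2 = np.exp(2 * log_sig_obs)
            d_prior = (u ** 2 - u_new ** 2) / (2 * sig2)
            lr_lev = d_lik + d_prior
            accept_lev = np.log(rng.random(n_observers)) < lr_lev
            if accept_lev.any():
                u = np.where(accept_lev, u_new, u)
                uo = u[obs_idx]
                ll_cur = loglik(xb + uo + wv)
            prop_obs_scale.update(
                float(np.mean(np.exp(np.minimum(lr_lev, 0.0)))))

            # --- observer sd
            ls_new = prop_sig_obs.propose_scalar(log_sig_obs, rng)
            def u_lp(ls):
                s2 = np.exp(2 * ls)
                return (-0.5 * np.sum(u ** 2) / s2 - n_observers * ls
                        + halfnormal_lp(np.exp(ls), hp.obs_sd_scale) + ls)
            lr = u_lp(ls_new) - u_lp(log_sig_obs)
            a = float(np.exp(min(lr, 0.0)))
            if metropolis_accept(lr, rng):
                log_sig_obs = ls_new
            prop_sig_obs.update_scalar(log_sig_obs, a)

        # --- spatial field (pCN: prior cancels)
        if use_field:
            w_new = pcn_propose(w, L_w, pcn.beta, rng)
            ll_new = loglik(xb + uo + w_new[site_idx])
            lr = ll_new.sum() - ll_cur.sum()
            a = float(np.exp(min(lr, 0.0)))
            if metropolis_accept(lr, rng):
                w, wv, ll_cur = w_new, w_new[site_idx], ll_new
                acc["field"] += it >= warmup
            pcn.update(a)

            # --- field hyperparameters (sd, range) given w
            th = np.array([log_sig_w, log_rho_w])
            th_new = prop_hyper.propose(th, rng)

            def hyper_lp(t, L):
                lsw, lrh = t
                return (spatial.gaussian_logpdf(w, L)
                        + halfnormal_lp(np.exp(lsw), hp.field_sd_scale) + lsw
                        - 0.5 * ((lrh - hp.field_range_log_mean)
                                 / hp.field_range_log_sd) ** 2)

            try:
                L_new = spatial.chol_cov(
                    coords, SpatialFieldParams(np.exp(th_new[0]),
                                               np.exp(th_new[1])))
                lr = hyper_lp(th_new, L_new) - hyper_lp(th, L_w)
            except (np.linalg.LinAlgError, ValueError):
                lr, L_new = -np.inf, None
            a = float(np.exp(min(lr, 0.0))) if np.isfinite(lr) else 0.0
            if np.isfinite(lr) and metropolis_accept(lr, rng):
                log_sig_w, log_rho_w = th_new
                L_w = L_new
                acc["hyper"] += it >= warmup
            prop_hyper.update(np.array([log_sig_w, log_rho_w]), a)

        # --- Gamma shape
        if is_gamma:
            ls_new = prop_shape.propose_scalar(log_shape, rng)
            eta = xb + uo + wv
            ll_new = _gamma_ll(y, eta, np.exp(ls_new))

            def shape_lp(ls, ll):
                sh = np.exp(ls)
                return (ll.sum() + (hp.shape_a - 1) * ls - hp.shape_rate * sh
                        + ls)
            lr = shape_lp(ls_new, ll_new) - shape_lp(log_shape, ll_cur)
            a = float(np.exp(min(lr, 0.0)))
            if metropolis_accept(lr, rng):
                log_shape, ll_cur = ls_new, ll_new
            prop_shape.update_scalar(log_shape, a)

        if it >= warmup and (it - warmup) % thin == 0:
            kept["beta"].append(beta.copy())
            if use_obs:
                kept["sigma_obs"].append(np.exp(log_sig_obs))
                kept["u_obs"].append(u.copy())
            if use_field:
                kept["w"].append(w.copy())
                kept["sigma_w"].append(np.exp(log_sig_w))
                kept["range_w"].append(np.exp(log_rho_w))
            if is_gamma:
                kept["shape"].append(np.exp(log_shape))
            kept_ll.append(ll_cur.copy())

    draws_out = {k: np.asarray(v) for k, v in kept.items() if len(v)}
    loglik_mat = np.asarray(kept_ll)

    names = list(colnames)
    mats = [draws_out["beta"]]
    for key, label in (("sigma_obs", "sigma_obs"), ("sigma_w", "sigma_w"),
                       ("range_w", "range_w"), ("shape", "shape")):
        if key in draws_out:
            names.append(label)
            mats.append(draws_out[key][:, None])
    summary = summarise_draws(np.hstack(mats), names)
    accept = {k: v / max(draws * thin, 1) for k, v in acc.items()}
    return StageFit(family=family, summary=summary, draws=draws_out,
                    loglik=loglik_mat, colnames=list(colnames),
                    observer_levels=tuple(observer_levels),
                    site_ids=tuple(site_ids), accept=accept, seed=seed)


def fit_presence(y_presence: np.ndarray, X: np.ndarray, colnames: list[str],
                 spec: HurdleSpec, **kwargs) -> StageFit:
    """Stage 1: Bernoulli-logit occurrence model."""
    y = np.asarray(y_presence, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("presence response must be 0/1")
    if y.min() == y.max():
        raise ValueError("all-presence or all-absence response: the "
                         "occurrence model is undefined (separation)")
    return _fit_stage("bernoulli", y, X, colnames, spec, **kwargs)


def fit_density(y_density: np.ndarray, X: np.ndarray, colnames: list[str],
                spec: HurdleSpec, **kwargs) -> StageFit:
    """Stage 2: Gamma log-link model of the strictly positive densities."""
    y = np.asarray(y_density, dtype=float)
    if np.any(y <= 0):
        raise ValueError("density responses must be strictly positive")
    return _fit_stage("gamma", y, X, colnames, spec, **kwargs)


# ---------------------------------------------------------------------------
# Orchestration over survey tables
# ---------------------------------------------------------------------------

@dataclass
class HurdleFit:
    """Both stages of the hurdle model plus everything needed to predict."""

    spec: HurdleSpec
    presence: StageFit
    density: StageFit
    design: DesignInfo
    data: pd.DataFrame                 # canonical-sorted merged table
    covariates: pd.DataFrame
    site_ids: tuple[str, ...]
    site_coords: np.ndarray
    observed_density: np.ndarray
    seed: int

    def fitted_expected_density(self) -> np.ndarray:
        """Posterior-mean p * posterior-mean mu at the fitted censuses.

        Predictions are population-level: the observer effect, which is a
        zero-mean nuisance, is set to its prior mean.
        """
        X = self.design.matrix(self.data)
        site_idx = self._site_index(self.data)
        return (self._posterior_mean_p(X, site_idx)
                * self._posterior_mean_mu(X, site_idx))

    # -- helpers -----------------------------------------------------------
    def _site_index(self, df: pd.DataFrame) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.site_ids)}
        return np.array([lookup.get(str(s), -1) for s in df["site_id"]])

    def _posterior_mean_p(self, X, site_idx) -> np.ndarray:
        eta = self._eta_draws(self.presence, X, site_idx)
        return np.mean(1.0 / (1.0 + np.exp(-eta)), axis=1)

    def _posterior_mean_mu(self, X, site_idx) -> np.ndarray:
        eta = self._eta_draws(self.density, X, site_idx)
        return np.mean(np.exp(eta), axis=1)

    def _eta_draws(self, stage: StageFit, X: np.ndarray,
                   site_idx: np.ndarray | None) -> np.ndarray:
        eta = X @ stage.draws["beta"].T          # (n, S)
        if "w" in stage.draws and site_idx is not None:
            w = stage.draws["w"]                 # (S, n_sites)
            inside = site_idx >= 0
            if inside.any():
                eta[inside] += w.T[site_idx[inside], :]
        return eta


def _canonical_sort(df: pd.DataFrame) -> pd.DataFrame:
    """Canonical record order so the posterior is invariant to input order."""
    keys = ["site_id", "year", "observer_id", "count"]
    if "density" in df.columns:
        keys.append("density")
    return df.sort_values(keys, kind="mergesort").reset_index(drop=True)


def prepare_stage_data(records: pd.DataFrame, covariates: pd.DataFrame,
                       stage: str = "juvenile") -> pd.DataFrame:
    """Merge one life stage's censuses with site covariates (canonical order)."""
    df = records[records["life_stage"] == stage].copy()
    if df.empty:
        raise ValueError(f"no {stage!r} records")
    missing_sites = set(df["site_id"]) - set(covariates["site_id"])
    if missing_sites:
        raise ValueError(f"no covariates for site(s) {sorted(missing_sites)}")
    merged = df.merge(covariates, on="site_id", how="left", validate="m:1")
    if "density" not in merged.columns:
        # per-census density from the integer count; a generator-supplied
        # exact density column (continuous mode) takes precedence
        merged["density"] = merged["count"] / (np.pi * merged["radius_m"] ** 2)
    return _canonical_sort(merged)


def fit_hurdle(records: pd.DataFrame, covariates: pd.DataFrame,
               spec: HurdleSpec, seed: int = 0, *, stage: str = "juvenile",
               draws: int = 800, warmup: int = 1000, thin: int = 2) -> HurdleFit:
    """Fit both hurdle stages to one life stage's census records.

    Stage 1 sees presence/absence of every census; stage 2 the positive
    densities only, under the same design transforms.  Records are put in a
    canonical sort order first, so posterior summaries do not depend on the
    order rows arrive in.
    """
    data = prepare_stage_data(records, covariates, stage)
    years = sorted(data["year"].unique())
    X, design = build_design(data, spec, years=years)

    site_ids = tuple(sorted(covariates["site_id"].astype(str)))
    site_lookup = {s: i for i, s in enumerate(site_ids)}
    coords = covariates.set_index("site_id").loc[list(site_ids),
                                                 ["x_km", "y_km"]].to_numpy()
    site_idx = np.array([site_lookup[s] for s in data["site_id"].astype(str)])

    observer_levels = tuple(sorted(data["observer_id"].astype(str).unique()))
    obs_lookup = {o: i for i, o in enumerate(observer_levels)}
    obs_idx = np.array([obs_lookup[o] for o in data["observer_id"].astype(str)])

    y_pres = (data["count"] > 0).to_numpy(dtype=float)
    ss = np.random.SeedSequence(seed)
    seed_bin, seed_gam = (int(s.generate_state(1)[0] % (2 ** 31))
                          for s in ss.spawn(2))

    common = dict(site_idx=site_idx, coords=coords if spec.include_spatial_field
                  else None, obs_idx=obs_idx,
                  n_observers=len(observer_levels) if spec.include_observer_effect
                  else 0, draws=draws, warmup=warmup, thin=thin,
                  site_ids=site_ids, observer_levels=observer_levels)
    pres = fit_presence(y_pres, X, design.colnames, spec, seed=seed_bin,
                        **common)

    pos = data["count"] > 0
    if not pos.any():
        raise ValueError("no positive densities: stage 2 is undefined")
    Xp = X[pos.to_numpy()]
    common_pos = dict(common)
    common_pos["site_idx"] = site_idx[pos.to_numpy()]
    common_pos["obs_idx"] = obs_idx[pos.to_numpy()]
    dens = fit_density(data.loc[pos, "density"].to_numpy(), Xp,
                       design.colnames, spec, seed=seed_gam, **common_pos)

    return HurdleFit(spec=spec, presence=pres, density=dens, design=design,
                     data=data, covariates=covariates, site_ids=site_ids,
                     site_coords=coords,
                     observed_density=data["density"].to_numpy(), seed=seed)


def predict_records(fit: HurdleFit, new_records: pd.DataFrame,
                    covariates: pd.DataFrame,
                    stage: str | None = None) -> np.ndarray:
    """Expected density (p * mu) for held-out census records."""
    df = new_records.copy()
    if stage is not None:
        df = df[df["life_stage"] == stage]
    merged = df.merge(covariates, on="site_id", how="left", validate="m:1")
    X = fit.design.matrix(merged)
    site_idx = fit._site_index(merged)
    p = fit._posterior_mean_p(X, site_idx)
    mu = fit._posterior_mean_mu(X, site_idx)
    return p * mu


# ---------------------------------------------------------------------------
# Grid prediction and hotspots
# ---------------------------------------------------------------------------

@dataclass
class PredictionGrid:
    """Per-cell presence probability, conditional density and their product."""

    table: pd.DataFrame     # x_km, y_km, p, mu, expected, missing
    mode: str               # "per-year" or "period-mean"
    year: int | None = None


def predict_grid(fit: HurdleFit, grid: pd.DataFrame,
                 mode: str = "period-mean",
                 year: int | None = None) -> PredictionGrid:
    """Hurdle predictions on a covariate grid.

    Per cell: posterior-mean presence probability, posterior-mean
    conditional density and the delta expectation ``p * mu``.  The latent
    field is interpolated to cells by its conditional (kriging) mean under
    the posterior-mean field hyperparameters.  ``per-year`` mode applies
    that year's factor level; ``period-mean`` applies the average of the
    year-factor effects, to pair with covariates averaged over the period.
    Cells with a missing covariate are flagged, never imputed.
    """
    if mode == "per-year":
        if year is None:
            raise ValueError("per-year mode needs a year")
        if fit.design.include_year_factor and year not in fit.design.years:
            raise ValueError(f"year {year} outside the fitted range")
    elif mode != "period-mean":
        raise ValueError(f"unknown mode {mode!r}")

    base_names = {n for t in fit.design.terms for n in t.split(":")}
    missing = np.zeros(len(grid), dtype=bool)
    for name in base_names:
        if name not in grid.columns:
            raise KeyError(f"grid is missing covariate column {name!r}")
        missing |= ~np.isfinite(grid[name].to_numpy(dtype=float))
    ok = ~missing
    if not ok.any():
        raise ValueError("every grid cell has a missing covariate")

    sub = grid.loc[ok].copy()
    ref_year = fit.design.years[0] if fit.design.years else None
    sub = sub.assign(year=ref_year)
    X = fit.design.matrix(sub)

    # year factor handling: dummies were built against the reference year
    if fit.design.include_year_factor and len(fit.design.years) > 1:
        year_cols = [fit.design.colnames.index(f"year_{y}")
                     for y in fit.design.years[1:]]
        if mode == "per-year":
            if year != ref_year:
                X[:, fit.design.colnames.index(f"year_{year}")] = 1.0
        else:
            for c in year_cols:
                X[:, c] = 1.0 / len(fit.design.years)

    coords_new = sub[["x_km", "y_km"]].to_numpy(dtype=float)

    def cell_eta(stagefit: StageFit) -> np.ndarray:
        eta = X @ stagefit.draws["beta"].T          # (m, S)
        if "w" in stagefit.draws:
            params = stagefit.field_params_posterior_mean()
            w_grid = spatial.krige_mean(fit.site_coords,
                                        stagefit.draws["w"], coords_new,
                                        params)    # (S, m)
            eta = eta + w_grid.T
        return eta

    p = np.mean(1 / (1 + np.exp(-cell_eta(fit.presence))), axis=1)
    mu = np.mean(np.exp(cell_eta(fit.density)), axis=1)

    out = grid[["x_km", "y_km"]].copy().reset_index(drop=True)
    out["p"] = np.nan
    out["mu"] = np.nan
    out.loc[np.flatnonzero(ok), "p"] = p
    out.loc[np.flatnonzero(ok), "mu"] = mu
    out["expected"] = out["p"] * out["mu"]
    out["missing"] = missing
    return PredictionGrid(table=out, mode=mode, year=year)


def hotspot_cells(grid: PredictionGrid, quantile_q: float = 0.9) -> np.ndarray:
    """Boolean mask of cells at or above the q-quantile of expected density.

    Ties at the threshold are kept, so a perfectly uniform grid is all
    hotspot.  Missing cells never qualify.
    """
    if not 0 < quantile_q < 1:
        raise ValueError("quantile_q must lie in (0, 1)")
    vals = grid.table["expected"].to_numpy(dtype=float)
    ok = np.isfinite(vals)
    if not ok.any():
        raise ValueError("all grid cells are missing")
    thresh = np.quantile(vals[ok], quantile_q)
    return np.where(ok, vals >= thresh, False)
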