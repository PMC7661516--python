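"""Model comparison and predictive validation.

Scores a fitted model from its per-observation posterior log-likelihood
draws (WAIC, CPO) and from point predictions (RMSE, R^2, Pearson r,
AVEerror), drives the backward-elimination variable-selection loop, and
runs repeated split-half cross-validation of the hurdle model.

WAIC is ``-2 * (lppd - p_waic)`` with the variance-based effective
parameter count; CPO_i is the harmonic-mean estimate of the leave-one-out
predictive density, summarised as LCPO = -mean log CPO (lower is better for
both).  AVEerror is the mean absolute prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp


@dataclass(frozen=True)
class FitScore:
    waic: float
    lcpo: float
    rmse: float
    r2: float
    n_params_effective: float


@dataclass(frozen=True)
class CvReport:
    per_fold: pd.DataFrame        # columns: fold, pearson_r, ave_error, n_test
    pooled_r: float
    pooled_ave_error: float
    folds: int
    split_fraction: float


def _check_loglik(loglik: np.ndarray) -> np.ndarray:
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("loglik must be a (draws x observations) matrix")
    if ll.shape[0] < 2:
        raise ValueError("need >= 2 posterior draws")
    if ll.shape[1] < 1:
        raise ValueError("need >= 1 observation")
    if not np.all(np.isfinite(ll)):
        raise ValueError("loglik contains non-finite entries")
    return ll


def waic(loglik: np.ndarray) -> tuple[float, float]:
    """WAIC and effective parameter count from log-likelihood draws.

    ``WAIC = -2 * sum_i [log mean_s exp(ll_si) - var_s(ll_si)]`` with the
    log of the mean computed through log-sum-exp for stability.
    """
    ll = _check_loglik(loglik)
    s = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(s)
    p_i = ll.var(axis=0, ddof=1)
    p_waic = float(p_i.sum())
    return float(-2.0 * (lppd_i.sum() - p_waic)), p_waic


def cpo(loglik: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-observation CPO (harmonic-mean identity) and the LCPO summary.

    ``CPO_i = [mean_s exp(-ll_si)]^{-1}``; LCPO = -mean_i log CPO_i, so
    smaller LCPO means better leave-one-out predictive density.
    """
    ll = _check_loglik(loglik)
    s = ll.shape[0]
    log_inv_cpo = logsumexp(-ll, axis=0) - np.log(s)   # log mean exp(-ll)
    log_cpo = -log_inv_cpo
    lcpo = float(-log_cpo.mean())
    return np.exp(log_cpo), lcpo


def prediction_metrics(observed, predicted) -> dict[str, float]:
    """RMSE, Pearson r, R^2 (= r^2) and AVEerror (mean absolute error)."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    if len(o) < 2:
        raise ValueError("need at least two observations")
    if np.ptp(o) == 0:
        raise ValueError("observed values are constant; r is undefined")
    resid = o - p
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ave_error = float(np.mean(np.abs(resid)))
    if np.ptp(p) == 0:
        r = 0.0   # degenerate constant prediction carries no linear signal
    else:
        r = float(np.corrcoef(o, p)[0, 1])
    return {"rmse": rmse, "pearson_r": r, "r2": r ** 2,
            "ave_error": ave_error}


# ---------------------------------------------------------------------------
# Variable selection (backward elimination + three-criterion compromise)
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    chosen_spec: "HurdleSpec"                     # noqa: F821
    scores: pd.DataFrame
    all_relevant: bool
    warning: str | None = None
    fits: dict = field(default_factory=dict)


def _term_relevance(fit, terms: list[str]) -> pd.DataFrame:
    """Per-term max |posterior mean / sd| across the two stages and whether
    the 95% interval excludes zero in at least one stage."""
    rows = []
    for term in terms:
        zs, excl = [], []
        for stage in (fit.presence, fit.density):
            s = stage.summary.set_index("term")
            if term not in s.index:
                continue
            mean, sd = s.at[term, "mean"], s.at[term, "sd"]
            lo, hi = s.at[term, "q2.5"], s.at[term, "q97.5"]
            zs.append(abs(mean) / max(sd, 1e-12))
            excl.append(lo > 0 or hi < 0)
        rows.append({"term": term, "z": max(zs), "relevant": any(excl)})
    return pd.DataFrame(rows)


def score_hurdle_fit(fit, records=None) -> FitScore:
    """Combined score of a hurdle fit: stage-summed WAIC/LCPO plus
    prediction metrics of expected density against observed density."""
    w1, p1 = waic(fit.presence.loglik)
    w2, p2 = waic(fit.density.loglik)
    _, l1 = cpo(fit.presence.loglik)
    _, l2 = cpo(fit.density.loglik)
    obs = fit.observed_density
    pred = fit.fitted_expected_density()
    m = prediction_metrics(obs, pred)
    return FitScore(waic=w1 + w2, lcpo=l1 + l2, rmse=m["rmse"],
                    r2=m["r2"], n_params_effective=p1 + p2)


def select_model(records: pd.DataFrame, covariates: pd.DataFrame,
                 full_spec, seed: int = 0, *, stage: str = "juvenile",
                 draws: int = 600, warmup: int = 800,
                 max_steps: int | None = None) -> SelectionResult:
    """Backward elimination with the WAIC/RMSE/R^2 rank-sum compromise.

    Starts from the full spec, repeatedly drops the predictor whose 95%
    credible interval most widely covers zero in *both* stages (smallest
    max |z| among non-relevant terms), and stops when every remaining
    predictor is relevant in at least one stage.  All visited specs are
    ranked by (WAIC asc, RMSE asc, R^2 desc); the minimal rank-sum wins,
    ties broken by fewer terms then lower WAIC.  If no visited spec has all
    predictors relevant, the best rank-sum spec is returned with a warning.
    """
    from .hurdle_sdm import fit_hurdle

    spec = full_spec
    visited: list[tuple] = []
    fits = {}
    step = 0
    while True:
        fit = fit_hurdle(records, covariates, spec, seed=seed + step,
                         stage=stage, draws=draws, warmup=warmup)
        sc = score_hurdle_fit(fit)
        rel = _term_relevance(fit, spec.terms)
        all_rel = bool(rel["relevant"].all()) if len(rel) else True
        spec_id = "+".join(spec.terms) or "(intercept)"
        visited.append((spec_id, spec, sc, all_rel))
        fits[spec_id] = fit
        step += 1
        if all_rel or len(spec.terms) == 0:
            break
        if max_steps is not None and step >= max_steps:
            break
        worst = rel.loc[~rel["relevant"], "z"].idxmin()
        drop = rel.loc[worst, "term"]
        spec = spec.without_term(drop)

    tab = pd.DataFrame([{
        "spec_id": sid, "n_terms": len(sp.terms), "waic": sc.waic,
        "p_waic": sc.n_params_effective, "rmse": sc.rmse, "r2": sc.r2,
        "lcpo": sc.lcpo, "all_relevant": rel_ok,
    } for sid, sp, sc, rel_ok in visited])
    tab["rank_sum"] = (tab["waic"].rank(method="min")
                       + tab["rmse"].rank(method="min")
                       + (-tab["r2"]).rank(method="min"))
    order = tab.sort_values(["rank_sum", "n_terms", "waic"]).index
    candidates = tab.loc[order]
    relevant_ok = candidates[candidates["all_relevant"]]
    warning = None
    if len(relevant_ok):
        best_id = relevant_ok.iloc[0]["spec_id"]
        all_rel = True
    else:
        best_id = candidates.iloc[0]["spec_id"]
        all_rel = False
        warning = ("no visited specification has every predictor's 95% "
                   "interval excluding zero; returning best rank-sum spec")
    tab["chosen"] = tab["spec_id"] == best_id
    chosen = next(sp for sid, sp, _, _ in visited if sid == best_id)
    return SelectionResult(chosen_spec=chosen, scores=tab,
                           all_relevant=all_rel, warning=warning, fits=fits)


def cross_validate(records: pd.DataFrame, covariates: pd.DataFrame, spec,
                   folds: int = 10, split_fraction: float = 0.5,
                   seed: int = 0, *, stage: str = "juvenile",
                   draws: int = 500, warmup: int = 700,
                   max_retries: int = 20) -> CvReport:
    """Repeated random split-half validation of the hurdle model.

    Each of the ``folds`` repeats draws a seeded random
    ``split_fraction`` / ``1 - split_fraction`` partition of the census
    records, fits the hurdle model on the training part and predicts the
    expected density of the held-out part; Pearson r and AVEerror are
    reported per repeat and pooled over all held-out predictions.
    A degenerate training half (no presences or no absences) is redrawn up
    to ``max_retries`` times before raising.
    """
    from .hurdle_sdm import fit_hurdle, predict_records

    rows, pooled_obs, pooled_pred = [], [], []
    df = records[records["life_stage"] == stage].reset_index(drop=True)
    n = len(df)
    if n < 10:
        raise ValueError("too few records for split-half validation")
    rng = np.random.default_rng(seed)
    for k in range(folds):
        for attempt in range(max_retries):
            mask = rng.random(n) < split_fraction
            train, test = df[mask], df[~mask]
            ok = (train["count"].gt(0).any() and train["count"].eq(0).any()
                  and len(test) >= 2)
            if ok:
                break
        else:
            raise RuntimeError(
                f"could not draw a non-degenerate split in {max_retries} tries")
        fit = fit_hurdle(train, covariates, spec, seed=seed * 1000 + k,
                         stage=stage, draws=draws, warmup=warmup)
        pred = predict_records(fit, test, covariates)
        if "density" in test.columns:
            obs = test["density"].to_numpy(dtype=float)
        else:
            obs = test["count"].to_numpy() / (np.pi
                                              * test["radius_m"].to_numpy() ** 2)
        m = prediction_metrics(obs, pred)
        rows.append({"fold": k, "pearson_r": m["pearson_r"],
                     "ave_error": m["ave_error"], "n_test": len(test)})
        pooled_obs.append(obs)
        pooled_pred.append(pred)
    pooled = prediction_metrics(np.concatenate(pooled_obs),
                                np.concatenate(pooled_pred))
    return CvReport(per_fold=pd.DataFrame(rows),
                    pooled_r=pooled["pearson_r"],
                    pooled_ave_error=pooled["ave_error"],
                    folds=folds, split_fraction=split_fraction)
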