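import numpy as np
import pandas as pd
import pytest

from abrolhos.synthetic_data import simulate_trend_series
from abrolhos.trend_models import (CountSeries, aggregate_counts,
                                   compare_trends, fit_trend, series_guard,
                                   trend_direction)


def make_series(counts, start=2003, label="x"):
    return CountSeries(label=label, life_stage="juvenile",
                       years=tuple(range(start, start + len(counts))),
                       counts=tuple(counts), effort=(1,) * len(counts))


class TestAggregation:
    def _records(self):
        rows = []
        for site, year, count in [("A-01", 2003, 3), ("A-02", 2003, 4),
                                  ("A-01", 2004, 2), ("B-01", 2003, 5),
                                  ("A-01", 2006, 1)]:
            rows.append({"site_id": site, "location": site.split("-")[0],
                         "mpa_regime": "open", "year": year,
                         "observer_id": "o1", "life_stage": "juvenile",
                         "radius_m": 2.0, "count": count})
        return pd.DataFrame(rows)

    def test_sums_within_location_year(self):
        series = aggregate_counts(self._records(), group="location")
        a = next(s for s in series if s.label == "A")
        assert a.years == (2003, 2004, 2006)
        assert a.counts == (7, 2, 1)
        assert a.effort == (2, 1, 1)

    def test_gap_year_reported(self):
        a = next(s for s in aggregate_counts(self._records())
                 if s.label == "A")
        assert a.gaps == (2005,)

    def test_pooled_region(self):
        s = aggregate_counts(self._records(), group="all")
        assert s.label == "all"
        assert s.counts == (12, 2, 1)

    def test_input_order_invariance(self):
        df = self._records()
        shuffled = df.sample(frac=1, random_state=5)
        assert aggregate_counts(df, group="all") == \
            aggregate_counts(shuffled, group="all")


class TestSeriesGuard:
    def test_low_total_excluded_with_reason(self):
        s = make_series([1, 0, 0, 0, 0, 0])
        filtered, rep = series_guard(s, min_total=10)
        assert rep.excluded
        assert any("low total count" in r for r in rep.reasons)

    def test_drop_years_removed(self):
        s = make_series([5, 6, 7, 8, 9, 10])
        filtered, rep = series_guard(s, min_total=0, drop_years={2005})
        assert 2005 not in filtered.years
        assert rep.dropped_years == (2005,)
        assert not rep.excluded

    def test_identity_guard(self):
        s = make_series([5, 6, 7])
        filtered, rep = series_guard(s, min_total=0)
        assert filtered == s and not rep.excluded and rep.reasons == ()


class TestFitTrend:
    @pytest.mark.parametrize("model_type", ["AR1", "RW1", "RW2"])
    def test_flat_series_fits_flat(self, model_type):
        s = make_series([5, 5, 5, 5, 5, 5])
        fit = fit_trend(s, model_type, seed=4)
        assert np.all(np.abs(fit.fitted["post_mean"] - 5) <= 1.0)
        assert (fit.fitted["q2.5"] <= fit.fitted["post_mean"]).all()
        assert (fit.fitted["post_mean"] <= fit.fitted["q97.5"]).all()
        assert (fit.fitted["post_mean"] > 0).all()

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_trend(make_series([3, 4]), "AR1")
        with pytest.raises(ValueError, match="at least 4"):
            fit_trend(make_series([3, 4, 5]), "RW2")

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="model_type"):
            fit_trend(make_series([3, 4, 5, 6]), "ARMA")

    def test_rw2_band_covers_log_linear_truth(self):
        # exp(1 + 0.3 t) rounded: the RW2 prior favours linear latent trends
        hits = 0
        for rep in range(5):
            t = np.arange(8)
            truth = np.exp(1.0 + 0.3 * t)
            rng = np.random.default_rng(600 + rep)
            counts = rng.poisson(truth)
            fit = fit_trend(make_series(list(counts)), "RW2", seed=rep)
            ok = ((fit.fitted["q2.5"] <= truth)
                  & (truth <= fit.fitted["q97.5"])).all()
            hits += ok
        assert hits >= 4

    def test_ar1_correlation_recovery(self):
        hits = 0
        for rep in range(6):
            s, _ = simulate_trend_series(
                "AR1", {"mu": 2.0, "tau": 4.0, "rho": 0.6}, T=30,
                seed=100 + rep)
            fit = fit_trend(s, "AR1", seed=rep)
            hits += abs(np.median(fit.draws["rho"]) - 0.6) <= 0.3
        assert hits >= 4

    def test_gap_years_bridged_by_latent(self):
        s = CountSeries("g", "juvenile", (2003, 2004, 2006, 2007, 2008),
                        (10, 12, 15, 18, 20), (1,) * 5)
        fit = fit_trend(s, "RW1", seed=1)
        assert fit.years_latent == tuple(range(2003, 2009))
        row = fit.fitted.set_index("year").loc[2005]
        assert not row["observed"]
        assert 5 <= row["post_mean"] <= 30

    def test_rw1_invariant_to_year_relabelling(self):
        s1 = make_series([8, 11, 9, 14, 13, 17], start=2003)
        s2 = make_series([8, 11, 9, 14, 13, 17], start=1990)
        f1 = fit_trend(s1, "RW1", seed=2)
        f2 = fit_trend(s2, "RW1", seed=2)
        assert np.allclose(f1.fitted["post_mean"], f2.fitted["post_mean"])


class TestComparison:
    def test_short_series_skips_rw2(self):
        s = make_series([5, 9, 7])
        comp = compare_trends(s, seed=0, draws=300, warmup=1000)
        assert set(comp.fits) == {"AR1", "RW1"}

    def test_deterministic_given_seed(self):
        s = make_series([20, 18, 22, 15, 12, 10])
        c1 = compare_trends(s, seed=3, draws=300, warmup=1000)
        c2 = compare_trends(s, seed=3, draws=300, warmup=1000)
        assert c1.chosen == c2.chosen
        pd.testing.assert_frame_equal(c1.table, c2.table)

    def test_waic_consistent_with_shared_loglik_path(self):
        from abrolhos.model_eval import waic

        s = make_series([20, 18, 22, 15, 12, 10])
        fit = fit_trend(s, "RW1", seed=5)
        w, _ = waic(fit.loglik)
        assert fit.waic == pytest.approx(w)


class TestDirection:
    def test_steep_decline_certain(self):
        fit = fit_trend(make_series([100, 60, 40, 20, 10, 5]), "RW1", seed=6)
        label, p = trend_direction(fit, 2003, 2008)
        assert label == "declining" and p >= 0.99

    def test_reversal_symmetry(self):
        fit = fit_trend(make_series([5, 10, 20, 40, 60, 100]), "RW1", seed=6)
        label, p = trend_direction(fit, 2003, 2008)
        assert label == "increasing" and p <= 0.01

    def test_constant_series_flat(self):
        fit = fit_trend(make_series([7, 7, 7, 7, 7, 7]), "RW1", seed=7)
        label, _ = trend_direction(fit, 2003, 2008)
        assert label == "flat"

    def test_year_outside_range_rejected(self):
        fit = fit_trend(make_series([7, 7, 7, 7]), "RW1", seed=8)
        with pytest.raises(ValueError, match="outside"):
            trend_direction(fit, 2003, 2012)
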