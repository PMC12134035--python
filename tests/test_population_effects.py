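"""Site-year aggregation, abundance regressions and effect summaries."""

import numpy as np
import pandas as pd
import pytest

from dormouse_torpor import data_model as dm
from dormouse_torpor import glm
from dormouse_torpor import population_effects as pe
from conftest import make_obs


class _FakeScores:
    def __init__(self, scores):
        self.scores = scores


class TestAggregation:
    def test_early_late_counts_sum_to_total(self):
        rows = ([make_obs(site="A", box=f"B{i}", date="2005-05-10") for i in range(2)]
                + [make_obs(site="A", box=f"B{i}", date="2005-09-10") for i in range(3)])
        met = pe.aggregate_site_year(dm.observations_to_frame(rows))
        row = met.set_index(["site_id", "year"]).loc[("A", 2005)]
        assert row["adult_count_total"] == 5
        assert row["adult_count_early"] == 2
        assert row["adult_count_late"] == 3

    def test_breeding_event_and_litter_size(self):
        rows = [make_obs(site="A", box="B1", date="2005-07-02", n_young=4),
                make_obs(site="A", box="B2", date="2005-07-02")]
        rows += [make_obs(site="A", box="B1", date="2005-07-02",
                          age="greys-eyes-open", sex=None, torpid=None, mass=7.1)
                 for _ in range(4)]
        met = pe.aggregate_site_year(dm.observations_to_frame(rows))
        row = met.set_index(["site_id", "year"]).loc[("A", 2005)]
        assert row["breeding_events"] == 1
        assert row["mean_litter_size"] == pytest.approx(4.0)
        assert row["young_count"] == 4
        assert row["mean_young_mass_g"] == pytest.approx(7.1)

    def test_young_mass_missing_without_greys_eyes_open(self):
        rows = [make_obs(site="A", box="B1", n_young=2),
                make_obs(site="A", box="B1", age="pink", sex=None, torpid=None,
                         mass=3.0, n_young=2)]
        met = pe.aggregate_site_year(dm.observations_to_frame(rows))
        assert np.isnan(met["mean_young_mass_g"].iloc[0])

    def test_conservation_on_simulated_data(self, small_dataset):
        met = pe.aggregate_site_year(small_dataset["observations"])
        assert (met["adult_count_early"] + met["adult_count_late"]
                == met["adult_count_total"]).all()


class TestAbundanceRegression:
    def _index_and_abundance(self, b, noise, n_sites=60, seed=0):
        rng = np.random.default_rng(seed)
        idx = rng.uniform(0, 1, n_sites)
        ab = pd.DataFrame({
            "site_id": [f"S{i}" for i in range(n_sites)],
            "abundance_index_surrogate": 1.0 - b * idx + rng.normal(0, noise, n_sites),
            "trend_slope_surrogate": rng.normal(0, 0.05, n_sites),
            "n_years": 5,
        })
        return dict(zip(ab["site_id"], idx)), ab

    def test_negative_relation_recovered(self):
        idx, ab = self._index_and_abundance(b=0.8, noise=0.1)
        fit_ab, _ = pe.abundance_trend_regression(idx, ab)
        slope = fit_ab.params["torpor_index"]
        se = fit_ab.bse["torpor_index"]
        assert slope < 0
        assert abs(slope - (-0.8)) < 2.5 * se

    def test_constant_abundance_zero_slope(self):
        idx, ab = self._index_and_abundance(b=0.0, noise=0.0)
        ab["abundance_index_surrogate"] = 1.0
        fit_ab, _ = pe.abundance_trend_regression(idx, ab)
        assert fit_ab.params["torpor_index"] == pytest.approx(0.0, abs=1e-8)

    def test_null_pvalue_calibration(self):
        """Type-I error: with no true relation, p < 0.05 in about 5% of
        replicates (60 replicates, 3-sigma binomial band)."""
        hits = 0
        reps = 60
        for r in range(reps):
            idx, ab = self._index_and_abundance(b=0.0, noise=0.1, n_sites=100, seed=100 + r)
            fit_ab, _ = pe.abundance_trend_regression(idx, ab)
            hits += fit_ab.pvalues["torpor_index"] < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert hits / reps == pytest.approx(0.05, abs=3 * se + 0.01)

    def test_too_few_sites_error(self):
        idx, ab = self._index_and_abundance(b=0.0, noise=0.1, n_sites=2)
        with pytest.raises(ValueError):
            pe.abundance_trend_regression(idx, ab)


def _metrics(cells):
    return pd.DataFrame([{"site_id": s, "year": y, "young_count": v}
                         for (s, y), v in cells.items()])


class TestEffectModels:
    def test_lag_join_aligns_next_year(self):
        metrics = _metrics({("A", 2005): 10, ("A", 2006): 20,
                            ("B", 2005): 30, ("B", 2006): 40})
        scores_f = _FakeScores({("A", 2005): 0.1, ("B", 2005): 0.9})
        scores_m = _FakeScores({("A", 2005): 0.0, ("B", 2005): 0.0})
        fit = pe.fit_effect_model(metrics, scores_f, scores_m, "young_count", lag=1)
        # only the 2006 responses have a 2005 score available
        assert fit.n == 2

    def test_no_overlap_raises(self):
        metrics = _metrics({("A", 2005): 10})
        empty = _FakeScores({})
        with pytest.raises(ValueError, match="overlap"):
            pe.fit_effect_model(metrics, empty, empty, "young_count")

    def test_constant_scores_reduce_to_intercept(self):
        metrics = _metrics({("A", y): 5 + y % 3 for y in range(2000, 2012)})
        z = _FakeScores({("A", y): 0.0 for y in range(2000, 2012)})
        fit = pe.fit_effect_model(metrics, z, z, "young_count")
        mean = metrics["young_count"].mean()
        pred = fit.predict(pd.DataFrame({"score_F": [0.0], "score_M": [0.0]}))
        assert pred[0] == pytest.approx(mean, abs=1e-6)

    def test_poisson_effect_recovery(self):
        """Known negative female effect, null male effect: signs and CIs
        recovered across replicates."""
        hits_f, hits_m = 0, 0
        reps = 30
        for r in range(reps):
            rng = np.random.default_rng(200 + r)
            n = 400
            sf, sm = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
            lam = np.exp(2.0 - 0.4 * sf + 0.0 * sm)
            df = pd.DataFrame({"site_id": "S", "year": np.arange(n),
                               "young_count": rng.poisson(lam)})
            scores_f = _FakeScores({("S", y): v for y, v in zip(df.year, sf)})
            scores_m = _FakeScores({("S", y): v for y, v in zip(df.year, sm)})
            fit = pe.fit_effect_model(df, scores_f, scores_m, "young_count")
            b, se = fit.params["score_F"], fit.bse["score_F"]
            hits_f += (b - 1.96 * se) <= -0.4 <= (b + 1.96 * se)
            ef = pe.effect_magnitude(fit, "M")
            hits_m += ef.direction == "none"
        assert hits_f >= int(0.85 * reps)
        assert hits_m >= int(0.85 * reps)


class TestEffectMagnitude:
    def _poisson_fit(self, beta_f, n=2000, seed=1):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"score_F": rng.uniform(0, 1, n),
                           "score_M": rng.uniform(0, 1, n)})
        df["y"] = rng.poisson(np.exp(2.0 + beta_f * df.score_F))
        return glm.fit_glm(glm.ModelSpec("y", ("score_F", "score_M"),
                                         family="poisson"), df)

    def test_log_link_percent_change_formula(self):
        fit = self._poisson_fit(-0.5)
        es = pe.effect_magnitude(fit, "F")
        beta = fit.params["score_F"]
        assert es.pct_change == pytest.approx(100 * (np.exp(beta) - 1), abs=1e-10)

    def test_log_link_matches_prediction_ratio(self):
        """Analytic 100(e^beta - 1) equals the prediction-based computation."""
        fit = self._poisson_fit(-0.5, seed=2)
        es = pe.effect_magnitude(fit, "F")
        p0 = glm.predict_response(fit, {"score_F": 0.0, "score_M": 0.0}).estimate
        p1 = glm.predict_response(fit, {"score_F": 1.0, "score_M": 0.0}).estimate
        assert es.pct_change == pytest.approx(100 * (p1 - p0) / p0, abs=1e-10)

    def test_exact_minus_half_beta(self):
        """beta = -0.5 on the log link is a 39.35% reduction."""
        assert 100 * (np.exp(-0.5) - 1) == pytest.approx(-39.3469, abs=1e-4)

    def test_zero_effect_ci_spans_zero(self):
        fit = self._poisson_fit(0.0, seed=3)
        es = pe.effect_magnitude(fit, "F")
        assert es.ci_low < 0 < es.ci_high
        assert es.direction == "none"

    def test_gaussian_identity_percent_change(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"score_F": rng.uniform(0, 1, 500),
                           "score_M": rng.uniform(0, 1, 500)})
        df["y"] = 10.0 + 1.0 * df.score_F + rng.normal(0, 1e-8, 500)
        fit = glm.fit_glm(glm.ModelSpec("y", ("score_F", "score_M")), df)
        es = pe.effect_magnitude(fit, "F")
        assert es.pct_change == pytest.approx(10.0, abs=1e-4)
        assert es.direction == "up"
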