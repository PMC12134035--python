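"""GLM machinery: closed-form oracles, link identities, ROC behaviour."""

import math

import numpy as np
import pandas as pd
import pytest

from dormouse_torpor import glm


def _grouped_binary(n_a=100, k_a=30, n_b=100, k_b=10):
    rows = []
    for grp, n, k in (("A", n_a, k_a), ("B", n_b, k_b)):
        rows += [{"g": grp, "y": 1}] * k + [{"g": grp, "y": 0}] * (n - k)
    return pd.DataFrame(rows)


class TestFitOracles:
    def test_logit_two_group_log_odds_ratio(self):
        """Group contrast under logit equals the closed-form log odds ratio."""
        df = _grouped_binary()
        fit = glm.fit_glm(glm.ModelSpec("y", ("g",), factors={"g": "A"},
                                        family="binomial-logit"), df)
        expected = math.log((10 / 90) / (30 / 70))
        assert fit.params["g[B]"] == pytest.approx(expected, abs=1e-6)
        assert fit.params["g[B]"] == pytest.approx(-1.3499, abs=1e-4)

    def test_intercept_only_logit_half_torpid(self):
        df = pd.DataFrame({"y": [0, 1] * 25})
        fit = glm.fit_glm(glm.ModelSpec("y", (), family="binomial-logit"), df)
        assert fit.params["(Intercept)"] == pytest.approx(0.0, abs=1e-9)
        assert glm.inverse_logit(fit.params["(Intercept)"]) == pytest.approx(0.5)

    def test_poisson_intercept_is_log_mean(self):
        counts = [0, 1, 2, 3, 4, 5, 2, 2, 1, 0]
        df = pd.DataFrame({"y": counts})
        fit = glm.fit_glm(glm.ModelSpec("y", (), family="poisson"), df)
        assert fit.params["(Intercept)"] == pytest.approx(math.log(np.mean(counts)), abs=1e-8)

    def test_gaussian_matches_ols(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.normal(size=50)})
        df["y"] = 1.0 + 2.0 * df.x + rng.normal(size=50)
        fit = glm.fit_glm(glm.ModelSpec("y", ("x",)), df)
        slope, intercept = np.polyfit(df.x, df.y, 1)
        assert fit.params["x"] == pytest.approx(slope, abs=1e-10)
        assert fit.params["(Intercept)"] == pytest.approx(intercept, abs=1e-10)

    def test_aic_counts_coefficients(self):
        df = _grouped_binary()
        fit = glm.fit_glm(glm.ModelSpec("y", ("g",), factors={"g": "A"},
                                        family="binomial-logit"), df)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * len(fit.beta))

    def test_rank_deficiency_names_columns(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4], "x1": [1.0, 2, 3, 4]})
        df["x2"] = 2 * df.x1
        # the QR pivot decides which member of the collinear pair gets named
        with pytest.raises(ValueError, match=r"collinear.*x[12]"):
            glm.fit_glm(glm.ModelSpec("y", ("x1", "x2")), df)

    def test_separation_is_flagged(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                           "y": np.r_[np.zeros(20), np.ones(20)]})
        fit = glm.fit_glm(glm.ModelSpec("y", ("x",), family="binomial-logit"), df)
        assert fit.separation

    def test_interaction_requires_main_effect(self):
        with pytest.raises(ValueError, match="main effect"):
            glm.ModelSpec("y", ("a", "a:b"))


class TestStatsmodelsEquivalence:
    """Spot equivalence with an established implementation (the heavyweight
    50-dataset sweep lives in the acceptance suite)."""

    @pytest.mark.parametrize("family", glm.FAMILIES)
    def test_coefficients_and_aic_agree(self, family):
        import statsmodels.api as sm
        import statsmodels.genmod.families.links as L

        smfam = {"gaussian": sm.families.Gaussian(),
                 "binomial-logit": sm.families.Binomial(),
                 "binomial-cloglog": sm.families.Binomial(L.CLogLog()),
                 "poisson": sm.families.Poisson()}[family]
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"x1": rng.normal(size=120), "x2": rng.normal(size=120)})
        eta = 0.3 + 0.6 * df.x1 - 0.4 * df.x2
        if family.startswith("binomial"):
            mu = glm._FAMILY_MAP[family].inverse(eta)
            df["y"] = (rng.uniform(size=120) < mu).astype(float)
        elif family == "poisson":
            df["y"] = rng.poisson(np.exp(eta)).astype(float)
        else:
            df["y"] = eta + rng.normal(size=120)
        fit = glm.fit_glm(glm.ModelSpec("y", ("x1", "x2"), family=family), df)
        X = fit.design.build_matrix(df)
        ref = sm.GLM(df.y.to_numpy(), X, family=smfam).fit(tol=1e-12, maxiter=300)
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
        if family != "gaussian":  # gaussian AIC conventions differ on the scale parameter
            assert fit.aic == pytest.approx(ref.aic, abs=1e-4)


class TestLinksAndPrediction:
    def test_inverse_logit_values(self):
        assert glm.inverse_logit(0.0) == 0.5
        assert glm.inverse_logit(40.0) == pytest.approx(1.0, abs=1e-12)
        assert glm.inverse_logit(glm.logit(0.23)) == pytest.approx(0.23, abs=1e-12)

    def test_cloglog_round_trip(self):
        p = np.array([0.01, 0.23, 0.5, 0.9, 0.99])
        np.testing.assert_allclose(glm.inverse_cloglog(glm.cloglog(p)), p, atol=1e-12)

    def test_cloglog_shift_identity_on_fit(self):
        """p1 = 1 - (1 - p0)^HR must hold for fitted models and covariate shifts."""
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"x": rng.normal(size=400)})
        mu = glm.inverse_cloglog(-0.5 + 0.8 * df.x)
        df["y"] = (rng.uniform(size=400) < mu).astype(float)
        fit = glm.fit_glm(glm.ModelSpec("y", ("x",), family="binomial-cloglog"), df)
        beta = fit.params["x"]
        hr = glm.hazard_ratio(fit, "x")
        for x0, delta in [(0.0, 1.0), (-1.0, 2.5), (0.7, -1.3)]:
            p0 = glm.predict_response(fit, {"x": x0}).estimate
            p1 = glm.predict_response(fit, {"x": x0 + delta}).estimate
            assert p1 == pytest.approx(1 - (1 - p0) ** (hr ** delta), abs=1e-10)
            assert p1 == pytest.approx(glm.cloglog_shift(p0, beta, delta), abs=1e-10)

    def test_zero_shift_returns_baseline(self):
        for p0 in (0.1, 0.5, 0.72):
            assert glm.cloglog_shift(p0, -0.1175, 0.0) == pytest.approx(p0, abs=1e-14)

    def test_prediction_ci_order_preserved(self):
        df = _grouped_binary()
        fit = glm.fit_glm(glm.ModelSpec("y", ("g",), factors={"g": "A"},
                                        family="binomial-logit"), df)
        pr = glm.predict_response(fit, {"g": "B"})
        assert pr.ci_low < pr.estimate < pr.ci_high
        assert 0.0 < pr.ci_low and pr.ci_high < 1.0

    def test_missing_covariate_raises(self):
        df = _grouped_binary()
        fit = glm.fit_glm(glm.ModelSpec("y", ("g",), factors={"g": "A"},
                                        family="binomial-logit"), df)
        with pytest.raises(KeyError, match="missing"):
            glm.predict_response(fit, {})

    def test_hazard_ratio_unknown_term(self):
        df = _grouped_binary()
        fit = glm.fit_glm(glm.ModelSpec("y", ("g",), factors={"g": "A"},
                                        family="binomial-cloglog"), df)
        with pytest.raises(KeyError):
            glm.hazard_ratio(fit, "nope")
        assert glm.hazard_ratio(fit, "(Intercept)") == pytest.approx(
            math.exp(fit.params["(Intercept)"]))


class TestRoc:
    def test_perfect_separation(self):
        res = glm.auc_roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        res = glm.auc_roc(np.ones(20), [0, 1] * 10)
        assert res.auc == pytest.approx(0.5, abs=1e-12)

    def test_matches_mann_whitney_with_ties(self):
        from scipy.stats import rankdata
        rng = np.random.default_rng(5)
        scores = np.round(rng.uniform(size=500), 2)  # heavy ties
        labels = (rng.uniform(size=500) < 0.4).astype(int)
        res = glm.auc_roc(scores, labels)
        r = rankdata(scores)
        n1 = labels.sum()
        u = (r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * (len(labels) - n1))
        assert res.auc == pytest.approx(u, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            glm.auc_roc([0.1, 0.9], [1, 1])

    def test_curve_endpoints(self):
        res = glm.auc_roc([0.3, 0.7, 0.2, 0.9], [0, 1, 0, 1])
        assert res.fpr[0] == 0 and res.tpr[0] == 0
        assert res.fpr[-1] == 1 and res.tpr[-1] == 1
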