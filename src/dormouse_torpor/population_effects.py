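"""Torpor and population characteristics.

Aggregates the observation table to site-year population metrics (adult
counts overall and by season half, young counts, breeding events, litter
size, mean adult and young mass), regresses site abundance and trend
indices on the site torpor index, and fits the response models linking
yearly sex-specific torpor scores to each metric in the same or the
following year.  Effects are summarised as the percentage change in the
predicted response between a torpor score of 0 (torpor very rare) and 1
(torpor very frequent), with a Wald 95% CI.

The abundance and trend indices are deliberately simple effort-controlled
surrogates (flagged in output column names): the abundance index is
``log10(1 + adults counted per box-visit)`` averaged over years, and the
trend is the per-site slope of ``log(1 + yearly adult count)`` over years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import glm as _glm
from .data_model import YOUNG_CLASSES

__all__ = [
    "EffectSummary",
    "aggregate_site_year",
    "abundance_index",
    "abundance_trend_regression",
    "fit_effect_model",
    "effect_magnitude",
    "COUNT_RESPONSES",
    "GAUSSIAN_RESPONSES",
]

COUNT_RESPONSES = ("adult_count_total", "adult_count_early", "adult_count_late",
                   "young_count", "breeding_events")
GAUSSIAN_RESPONSES = ("mean_litter_size", "mean_adult_mass_g", "mean_young_mass_g")


@dataclass
class EffectSummary:
    """Percent change in a population parameter between torpor scores 0 and 1."""

    response: str
    sex: str
    lag: int  # 0 = same year, 1 = following year
    season: str
    pct_change: float
    ci_low: float
    ci_high: float
    direction: str  # "up", "down" or "none" by CI overlap with 0

    def as_dict(self):
        return {"response": self.response, "sex": self.sex, "lag": self.lag,
                "season": self.season, "pct_change": self.pct_change,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "direction": self.direction}


def aggregate_site_year(obs: pd.DataFrame) -> pd.DataFrame:
    """Site-year population metrics from the full (uncleaned) observation table.

    * adult counts: records with age class ``adult``, split into early
      (April-July) and late (August-October) halves that sum to the total;
    * young count: records in any of the four dependent-young grades;
    * breeding events: box-visits (site, date, box) where young were present;
    * litter size: mean number of young per breeding box-visit;
    * mean adult mass; mean young mass from greys-eyes-open records only
      (missing where that grade was never recorded).
    """
    df = obs.copy()
    adult = df[df["age_class"] == "adult"]
    young = df[df["age_class"].isin(YOUNG_CLASSES)]

    def _count(frame):
        return frame.groupby(["site_id", "year"]).size()

    out = pd.DataFrame({"adult_count_total": _count(adult)})
    out["adult_count_early"] = _count(adult[adult["month"] <= 7])
    out["adult_count_late"] = _count(adult[adult["month"] >= 8])
    out["young_count"] = _count(young)

    visits = df.groupby(["site_id", "year", "date", "box_id"], as_index=False).agg(
        n_young=("n_young_in_box", "max"))
    breeding = visits[visits["n_young"] > 0]
    out["breeding_events"] = breeding.groupby(["site_id", "year"]).size()
    out["mean_litter_size"] = breeding.groupby(["site_id", "year"])["n_young"].mean()
    out["mean_adult_mass_g"] = adult.groupby(["site_id", "year"])["mass_g"].mean()
    geo = young[young["age_class"] == "greys-eyes-open"]
    out["mean_young_mass_g"] = geo.groupby(["site_id", "year"])["mass_g"].mean()

    out = out.reset_index()
    for col in ("adult_count_total", "adult_count_early", "adult_count_late",
                "young_count", "breeding_events"):
        out[col] = out[col].fillna(0).astype(int)
    return out


def abundance_index(obs: pd.DataFrame, boxes_per_site: int | None = None,
                    min_years: int = 3) -> pd.DataFrame:
    """Effort-controlled site abundance and trend surrogates.

    Abundance: mean over years of log10(1 + adults per box-visit), where a
    box-visit is a distinct (date, box) at the site.  Trend: ordinary
    least-squares slope of log(1 + yearly adult count) on year.  Sites with
    fewer than ``min_years`` surveyed years are excluded.
    """
    adult = obs[obs["age_class"] == "adult"]
    per_year = adult.groupby(["site_id", "year"]).size().rename("adults").reset_index()
    effort = obs.groupby(["site_id", "year"]).apply(
        lambda g: g[["date", "box_id"]].drop_duplicates().shape[0],
        include_groups=False).rename("box_visits").reset_index()
    per_year = per_year.merge(effort, on=["site_id", "year"], how="right")
    per_year["adults"] = per_year["adults"].fillna(0)

    rows = []
    for site, g in per_year.groupby("site_id"):
        if g["year"].nunique() < min_years:
            continue
        rate = g["adults"] / g["box_visits"].clip(lower=1)
        abund = float(np.log10(1.0 + rate).mean())
        yrs = g["year"].to_numpy(dtype=float)
        logc = np.log1p(g["adults"].to_numpy(dtype=float))
        slope = float(np.polyfit(yrs, logc, 1)[0]) if len(g) > 1 else 0.0
        rows.append({"site_id": site, "abundance_index_surrogate": abund,
                     "trend_slope_surrogate": slope, "n_years": g["year"].nunique()})
    return pd.DataFrame(rows)


def abundance_trend_regression(index_set, abundance: pd.DataFrame):
    """Gaussian regressions of abundance and trend surrogates on the site torpor index.

    ``index_set`` is a :class:`~dormouse_torpor.torpor_index.TorporIndexSet`
    (or a site -> index mapping).  Returns ``(abundance fit, trend fit)``.
    """
    idx = index_set.indices if hasattr(index_set, "indices") else dict(index_set)
    df = abundance.copy()
    df["torpor_index"] = df["site_id"].map(idx)
    df = df.dropna(subset=["torpor_index"])
    if len(df) < 3:
        raise ValueError("need at least three sites with both indices")
    fit_ab = _glm.fit_glm(
        _glm.ModelSpec("abundance_index_surrogate", ("torpor_index",)), df)
    fit_tr = _glm.fit_glm(
        _glm.ModelSpec("trend_slope_surrogate", ("torpor_index",)), df)
    return fit_ab, fit_tr


def _join_scores(metrics: pd.DataFrame, scores_f, scores_m, lag: int) -> pd.DataFrame:
    """Align metrics in year T+lag with scores in year T."""
    df = metrics.copy()
    key_year = df["year"] - lag  # score year feeding this response year
    df["score_F"] = [scores_f.scores.get((s, int(y)), np.nan)
                     for s, y in zip(df["site_id"], key_year)]
    df["score_M"] = [scores_m.scores.get((s, int(y)), np.nan)
                     for s, y in zip(df["site_id"], key_year)]
    df = df.dropna(subset=["score_F", "score_M"])
    return df


def fit_effect_model(metrics: pd.DataFrame, scores_f, scores_m, response: str,
                     lag: int = 0, family: str | None = None) -> _glm.FitResult:
    """GLM of one population metric on female and male torpor scores.

    Count responses use Poisson log-link; mass and litter-size responses use
    Gaussian identity (both overridable through ``family``).  ``lag=1``
    joins scores in year T to the response in year T+1.
    """
    if family is None:
        family = "poisson" if response in COUNT_RESPONSES else "gaussian"
    df = _join_scores(metrics, scores_f, scores_m, lag)
    df = df.dropna(subset=[response])
    if df.empty:
        raise ValueError(f"no overlapping site-year cells for {response!r} at lag {lag}")
    spec = _glm.ModelSpec(response, ("score_F", "score_M"), family=family)
    # degenerate score columns (e.g. a sex whose scores are all equal) are
    # dropped rather than fatal: the model then reduces toward intercept-only
    return _glm.fit_glm(spec, df, allow_aliased=True)


def effect_magnitude(fit: _glm.FitResult, which_score: str, response: str = "",
                     lag: int = 0, season: str = "all",
                     other_score: float = 0.0) -> EffectSummary:
    """Percent change in the predicted response between score 0 and score 1.

    The other sex's score is held at ``other_score`` (0 by default; pass the
    observed mean to compare at typical conditions — this only shifts the
    Gaussian baseline, the log-link percentage being invariant to it).  For
    a Poisson log-link model this
    is exactly ``100 (exp(beta) - 1)`` with the CI from the coefficient's
    Wald interval; for Gaussian identity it is ``100 beta / prediction-at-0``
    (the intercept), with the CI scaled the same way (the intercept's own
    uncertainty is not propagated).
    """
    if which_score not in ("F", "M"):
        raise ValueError("which_score must be 'F' or 'M'")
    term = f"score_{which_score}"
    beta = fit.coefficient(term)
    se = fit.bse[term]
    lo, hi = beta - 1.96 * se, beta + 1.96 * se
    if fit.spec.family == "poisson":
        pct = 100.0 * (np.exp(beta) - 1.0)
        ci = (100.0 * (np.exp(lo) - 1.0), 100.0 * (np.exp(hi) - 1.0))
    elif fit.spec.family == "gaussian":
        other = "score_M" if which_score == "F" else "score_F"
        base = _glm.predict_response(
            fit, {term: 0.0, other: float(other_score)}).estimate
        if abs(base) < 1e-12:
            raise ValueError("prediction at score 0 is zero; percent change undefined")
        pct = 100.0 * beta / base
        ci = tuple(sorted((100.0 * lo / base, 100.0 * hi / base)))
    else:
        raise ValueError(f"unsupported family {fit.spec.family!r} for effect summary")
    if ci[0] > 0:
        direction = "up"
    elif ci[1] < 0:
        direction = "down"
    else:
        direction = "none"
    return EffectSummary(response or fit.spec.response, which_score, lag, season,
                         float(pct), float(ci[0]), float(ci[1]), direction)
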