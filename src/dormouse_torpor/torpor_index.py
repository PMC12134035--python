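"""Site torpor indices and sex/year/season torpor scores.

The *site torpor index* summarises how often dormice at a site are found in
short torpor relative to an arbitrary reference site, controlling for
month, year and sex: a binomial logit GLM of torpid state on site, month,
year and sex (all factors) is fitted, and each site's treatment-coded
coefficient is inverse-logit transformed.  The reference site — the site
whose coordinates lie nearest the mean latitude/longitude of all sites —
has coefficient zero by construction, hence index exactly 0.5; indices
above 0.5 mean more torpor than the reference, below 0.5 less.

To stop all-zero sites being fitted with probabilities indistinguishable
from zero, any site with no torpid record over the whole period receives a
single synthetic ("dummy") torpid observation at its earliest survey date
before fitting.

*Yearly scores* repeat the idea per sex and site-year cell: a binomial
logit GLM of torpid state on site, year and their interaction (the
saturated site-by-year cell model) is fitted to one sex's records, and the
inverse-logit of each observed cell's fitted linear predictor is that
cell's score in [0, 1].  Early-season scores use April-July records only,
late-season August-October.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm as _glm

__all__ = [
    "TorporIndexSet",
    "YearlyScoreSet",
    "EARLY_MONTHS",
    "LATE_MONTHS",
    "add_dummy_observations",
    "choose_reference_site",
    "site_torpor_index",
    "yearly_sex_scores",
]

EARLY_MONTHS = (4, 5, 6, 7)
LATE_MONTHS = (8, 9, 10)
_SEASON_MONTHS = {"all": tuple(range(4, 11)), "early": EARLY_MONTHS, "late": LATE_MONTHS}


@dataclass
class TorporIndexSet:
    """Site -> index mapping in (0, 1), anchored at 0.5 for the reference site."""

    indices: dict
    reference_site: str
    fit: _glm.FitResult
    dummy_log: list = field(default_factory=list)
    n_obs: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        dummies = {s for s, _ in self.dummy_log}
        return pd.DataFrame({
            "site_id": list(self.indices),
            "index": list(self.indices.values()),
            "n_obs": [self.n_obs.get(s, 0) for s in self.indices],
            "dummy_added": [s in dummies for s in self.indices],
            "is_reference": [s == self.reference_site for s in self.indices],
        })


@dataclass
class YearlyScoreSet:
    """(site, year) -> score in [0, 1] for one sex and season."""

    sex: str
    season: str
    scores: dict
    fit: _glm.FitResult
    n_obs: dict = field(default_factory=dict)
    dummy_log: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"site_id": s, "year": y, "sex": self.sex, "season": self.season,
                 "score": v, "n_obs": self.n_obs.get((s, y), 0)}
                for (s, y), v in self.scores.items()]
        return pd.DataFrame(rows)


def add_dummy_observations(obs: pd.DataFrame):
    """Add one synthetic torpid record per site that never recorded torpor.

    The record is stamped at the site's earliest survey date (month/year
    derived from it), with reference-level sex and the site's median adult
    mass, and is flagged in the ``is_dummy`` column.  Returns
    ``(augmented frame, log)`` with ``log`` a list of ``(site_id, date)``.
    """
    obs = obs.copy()
    if "is_dummy" not in obs.columns:
        obs["is_dummy"] = False
    if obs.empty:
        return obs, []
    torpid_by_site = obs.groupby("site_id")["torpid"].max()
    silent = torpid_by_site[torpid_by_site == 0].index
    log = []
    extra = []
    for site in silent:
        sub = obs[obs.site_id == site]
        first = sub["date"].min()
        ts = pd.Timestamp(first)
        row = sub.iloc[0].to_dict()
        row.update({
            "date": first, "year": int(ts.year), "month": int(ts.month),
            "sex": "F", "torpid": 1,
            "mass_g": float(sub["mass_g"].median()),
            "is_dummy": True,
        })
        extra.append(row)
        log.append((site, first))
    if extra:
        obs = pd.concat([obs, pd.DataFrame(extra)], ignore_index=True)
    return obs, log


def _haversine_km(lat1, lon1, lat2, lon2):
    r = 6371.0
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


def choose_reference_site(sites: pd.DataFrame) -> str:
    """Site nearest (great-circle) to the mean coordinate; ties -> lowest id."""
    sites = sites.reset_index(drop=True)  # tolerate a site_id-named index
    mlat, mlon = sites["latitude"].mean(), sites["longitude"].mean()
    best, best_d = None, np.inf
    for row in sites.sort_values("site_id").itertuples():
        d = _haversine_km(row.latitude, row.longitude, mlat, mlon)
        if d < best_d - 1e-12:
            best, best_d = row.site_id, d
    return best


def site_torpor_index(obs: pd.DataFrame, sites: pd.DataFrame,
                      dummy_log=None) -> TorporIndexSet:
    """Fit the site/month/year/sex logit model and extract site indices.

    ``obs`` should already carry any dummy observations (see
    :func:`add_dummy_observations`); pass its log through ``dummy_log``.
    Every observed site must appear in the site attribute table.
    """
    present = sorted(obs["site_id"].unique())
    if len(present) < 2:
        raise ValueError("site torpor index needs at least two sites")
    known = set(sites["site_id"])
    orphans = [s for s in present if s not in known]
    if orphans:
        raise KeyError(f"site(s) absent from attribute table: {orphans}")

    ref = choose_reference_site(sites[sites["site_id"].isin(present)])
    spec = _glm.ModelSpec(
        response="torpid",
        terms=("site_id", "month", "year", "sex"),
        factors={
            "site_id": ref,
            "month": int(obs["month"].min()),
            "year": int(obs["year"].min()),
            "sex": "F",
        },
        family="binomial-logit",
    )
    fit = _glm.fit_glm(spec, obs, allow_aliased=True)
    indices = {ref: 0.5}
    for site in present:
        if site == ref:
            continue
        name = f"site_id[{site}]"
        beta = fit.params.get(name, 0.0)
        indices[site] = float(_glm.inverse_logit(beta))
    real = obs[~obs["is_dummy"].astype(bool)] if "is_dummy" in obs.columns else obs
    counts = real.groupby("site_id").size().to_dict()
    return TorporIndexSet(indices, ref, fit, list(dummy_log or []), counts)


def yearly_sex_scores(obs: pd.DataFrame, sex: str, season: str = "all",
                      max_iter: int = 35) -> YearlyScoreSet:
    """Per-sex, per-season site-by-year torpor scores.

    Filters to one sex and the season's months, applies the dummy-record
    rule to sites with no torpid record in that subset, fits
    ``torpid ~ site * year`` (both factors) with a binomial logit link, and
    scores each observed cell as the inverse-logit of its fitted linear
    predictor.  Cells without data are absent from the result, never
    extrapolated.
    """
    if season not in _SEASON_MONTHS:
        raise ValueError(f"season must be one of {sorted(_SEASON_MONTHS)}")
    if sex not in ("F", "M"):
        raise ValueError("sex must be 'F' or 'M'")
    sub = obs[(obs["sex"] == sex) & obs["month"].isin(_SEASON_MONTHS[season])].copy()
    cells = sub.groupby(["site_id", "year"]).size()
    if len(cells) < 2:
        raise ValueError("need at least two site-year cells with data")
    sub, dummy_log = add_dummy_observations(sub)

    ref_site = sorted(sub["site_id"].unique())[0]
    ref_year = int(sub["year"].min())
    spec = _glm.ModelSpec(
        response="torpid",
        terms=("site_id", "year", "site_id:year"),
        factors={"site_id": ref_site, "year": ref_year},
        family="binomial-logit",
    )
    # the saturated cell model separates whenever a cell is all-torpid or
    # torpor-free; a modest iteration cap drives those cells' fitted
    # probabilities into [<0.01, >0.99] without chasing infinite coefficients
    fit = _glm.fit_glm(spec, sub, allow_aliased=True, max_iter=max_iter)

    cell_frame = sub.groupby(["site_id", "year"], as_index=False).first()
    eta = fit.linear_predictor(cell_frame)
    scores = {}
    for (row, e) in zip(cell_frame.itertuples(), eta):
        scores[(row.site_id, int(row.year))] = float(_glm.inverse_logit(e))
    counts = {(s, int(y)): int(n) for (s, y), n in cells.items()}
    return YearlyScoreSet(sex, season, scores, fit, counts, dummy_log)
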