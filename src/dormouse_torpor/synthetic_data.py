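"""Synthetic nest-box monitoring data with known ground truth.

The real monitoring data are restricted, so every downstream stage is
exercised on generated tables that emulate their structure: monthly
nest-box checks April-October at a grid of woodland sites in Britain, with
adults, juveniles and litters of dependent young in boxes, and daily site
weather (minimum temperature, rainfall) around a 30-year seasonal baseline.

Each adult record's torpid state is drawn from a Bernoulli whose
probability comes from a complementary log-log linear predictor with known
coefficients over month, mass, sex, box social context and multi-window
weather residuals, plus Gaussian per-site offsets.  The realised linear
predictor and probability of every adult record are kept in a truth table
so that model-recovery tests can compare fits against the generating
process.

The default configuration targets the broad features of the real
programme: five visits per site-year, an overall torpid fraction near 23%,
lighter animals early in the season and heavier late (so the mass-by-month
sign flip is reproducible), and colder/wetter conditions raising torpor
probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import covariates as _cov
from . import glm as _glm

__all__ = [
    "WeatherParams",
    "SimulationConfig",
    "DEFAULT_TRUE_COEFFICIENTS",
    "individual_model_spec",
    "simulate_sites",
    "simulate_weather",
    "simulate_observations",
    "simulate_dataset",
    "write_dataset",
]

#: young age-grade sampling weights (greys-eyes-open commonest, as in checks)
_YOUNG_CLASS_P = {"pink": 0.2, "greys-eyes-closed": 0.2,
                  "greys-eyes-open": 0.4, "fully-furred": 0.2}
_YOUNG_MASS = {"pink": (3.0, 0.5), "greys-eyes-closed": (5.0, 0.8),
               "greys-eyes-open": (7.0, 1.0), "fully-furred": (9.0, 1.2)}


@dataclass
class WeatherParams:
    """Seasonal sinusoid for daily minimum temperature and a Bernoulli-gamma
    daily rainfall model.  The 30-year baseline is the deterministic part."""

    tmin_mean_c: float = 6.0
    tmin_amplitude_c: float = 6.5
    tmin_peak_doy: int = 200
    tmin_noise_sd: float = 2.8
    site_tmin_offset_sd: float = 0.8
    rain_p_wet: float = 0.45
    rain_gamma_shape: float = 0.7
    rain_gamma_scale_mm: float = 6.0


#: generating coefficients on the cloglog linear-predictor scale, keyed by
#: design-matrix column name of :func:`individual_model_spec`.  Terms absent
#: here have true coefficient zero (the weekly/monthly weather windows and
#: the count of young, mirroring effects found negligible in the field).
DEFAULT_TRUE_COEFFICIENTS = {
    "(Intercept)": 0.15,
    "month[5]": -0.20,
    "month[6]": 0.00,
    "month[7]": 0.30,
    "month[8]": -1.00,
    "month[9]": -2.20,
    "month[10]": -1.90,
    "mass_g": -0.037,
    "sex[M]": -0.185,
    "n_adults_in_box": -0.127,
    "n_juveniles_in_box": -0.30,
    "breeding_box": -2.0,
    "month[5]:mass_g": -0.010,
    "month[6]:mass_g": -0.030,
    "month[7]:mass_g": -0.050,
    "month[8]:mass_g": -0.040,
    "month[9]:mass_g": 0.060,
    "month[10]:mass_g": 0.080,
    "month[5]:sex[M]": 0.05,
    "month[6]:sex[M]": 0.05,
    "month[7]:sex[M]": 0.10,
    "month[8]:sex[M]": 0.30,
    "month[9]:sex[M]": -0.35,
    "month[10]:sex[M]": 0.00,
    "tmin_daily_resid": -0.1175,
    "tmin_seasonal_resid": -0.1715,
    "rain_daily_resid": 0.0081,
    "rain_seasonal_resid": 0.0012,
}


@dataclass
class SimulationConfig:
    n_sites: int = 40
    year_start: int = 2001
    year_end: int = 2010
    visits_per_year: int = 5
    boxes_per_site: int = 50
    occupancy_prob: float = 0.10
    extra_adult_rate: float = 0.35
    juvenile_rate_early: float = 0.05
    juvenile_rate_late: float = 0.40
    breeding_prob_core: float = 0.18   # June-September
    breeding_prob_other: float = 0.02
    litter_poisson_mean: float = 2.5
    mass_mean_april_g: float = 17.0
    mass_slope_per_month_g: float = 0.5
    mass_sd_g: float = 2.5
    site_offset_sd: float = 0.6
    # contribution of (mean-centred) site attributes to the mean of each
    # site's linear-predictor offset: western, higher, more-ancient and
    # better-connected sites lean torpid, the pattern the site-level
    # analysis is meant to recover; {} makes offsets pure noise
    site_effect_coefficients: dict = field(default_factory=lambda: {
        "longitude": -0.15,
        "elevation_scaled": 0.30,
        "prop_ancient": 0.60,
        "broadleaf_connectivity_km2": 0.35,
    })
    missing_rate: float = 0.01
    negative_mass_rate: float = 0.002
    juvenile_torpid_prob: float = 0.10
    true_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS))
    weather: WeatherParams = field(default_factory=WeatherParams)
    seed: int = 20260929

    def __post_init__(self):
        for name in ("n_sites", "visits_per_year", "boxes_per_site"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.year_end < self.year_start:
            raise ValueError("year_end before year_start")
        if not 1 <= self.visits_per_year <= 7:
            raise ValueError("visits_per_year must be in 1..7 (one per active month)")

    @property
    def years(self):
        return range(self.year_start, self.year_end + 1)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        if "weather" in d and isinstance(d["weather"], dict):
            d["weather"] = WeatherParams(**d["weather"])
        return cls(**d)


def individual_model_spec(response: str = "torpid") -> _glm.ModelSpec:
    """The individual torpor model: cloglog GLM of torpid state on month,
    mass, sex, box social context and the eight weather-window residuals,
    with mass-by-month and sex-by-month interactions.  Reference levels:
    April, female, non-breeding box (a numeric 0/1 indicator)."""
    return _glm.ModelSpec(
        response=response,
        terms=(
            "month", "mass_g", "sex",
            "n_adults_in_box", "n_juveniles_in_box", "n_young_in_box",
            "breeding_box",
            "month:mass_g", "month:sex",
            "tmin_daily_resid", "tmin_weekly_resid", "tmin_monthly_resid",
            "tmin_seasonal_resid",
            "rain_daily_resid", "rain_weekly_resid", "rain_monthly_resid",
            "rain_seasonal_resid",
        ),
        factors={"month": 4, "sex": "F"},
        family="binomial-cloglog",
    )


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def simulate_sites(cfg: SimulationConfig) -> pd.DataFrame:
    """Site attribute table: Britain-like coordinates, terrain and habitat.

    Distributions: latitude U(50.5, 54.5), longitude U(-5.0, 1.5), elevation
    U(10, 300) m, slope U(0, 25) deg, aspect U(0, 360) deg, habitat fractions
    Beta(2,2)/Beta(4,2), connectivities log-normal (median ~0.5 km2).  The
    solar index is computed from latitude/slope/aspect.
    """
    rng = _rng(cfg, 1)
    n = cfg.n_sites
    df = pd.DataFrame({
        "site_id": [f"S{i + 1:03d}" for i in range(n)],
        "latitude": rng.uniform(50.5, 54.5, n),
        "longitude": rng.uniform(-5.0, 1.5, n),
        "elevation_m": rng.uniform(10.0, 300.0, n),
        "slope_deg": rng.uniform(0.0, 25.0, n),
        "aspect_deg": rng.uniform(0.0, 360.0, n),
        "prop_ancient": rng.beta(2.0, 2.0, n),
        "prop_broadleaf": rng.beta(4.0, 2.0, n),
        "broadleaf_connectivity_km2": rng.lognormal(-0.7, 0.6, n),
        "ancient_connectivity_km2": rng.lognormal(-1.2, 0.7, n),
    })
    df["solar_index"] = [
        _cov.solar_index(lat, sl, asp)
        for lat, sl, asp in zip(df.latitude, df.slope_deg, df.aspect_deg)
    ]
    sd = df["elevation_m"].std(ddof=0)
    df["elevation_scaled"] = (df["elevation_m"] - df["elevation_m"].mean()) / sd
    return df


def _tmin_climatology(doy, wp: WeatherParams):
    doy = np.asarray(doy, dtype=float)
    return wp.tmin_mean_c + wp.tmin_amplitude_c * np.cos(
        2.0 * np.pi * (doy - wp.tmin_peak_doy) / 365.25)


def simulate_weather(cfg: SimulationConfig, sites: pd.DataFrame):
    """Daily site weather plus the baseline climatology.

    Returns ``(weather, baseline)``: per-site daily minimum temperature
    (seasonal sinusoid + site offset + Gaussian noise) and rainfall
    (Bernoulli wet days with gamma amounts), from 1 January of the first
    year through 31 December of the last, and a 365-row day-of-year
    baseline holding the deterministic expectations (the stand-in for the
    30-year mean series).
    """
    rng = _rng(cfg, 2)
    wp = cfg.weather
    dates = pd.date_range(f"{cfg.year_start}-01-01", f"{cfg.year_end}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    n_sites, n_days = len(sites), len(dates)

    clim = _tmin_climatology(doy, wp)
    site_off = rng.normal(0.0, wp.site_tmin_offset_sd, n_sites)
    tmin = clim[None, :] + site_off[:, None] + rng.normal(0.0, wp.tmin_noise_sd, (n_sites, n_days))
    wet = rng.uniform(size=(n_sites, n_days)) < wp.rain_p_wet
    amounts = rng.gamma(wp.rain_gamma_shape, wp.rain_gamma_scale_mm, (n_sites, n_days))
    rain = np.where(wet, amounts, 0.0)

    weather = pd.DataFrame({
        "site_id": np.repeat(sites["site_id"].to_numpy(), n_days),
        "date": np.tile(dates.to_numpy(), n_sites),
        "tmin_c": tmin.ravel(),
        "rain_mm": rain.ravel(),
    })
    base_doy = np.arange(1, 366)
    baseline = pd.DataFrame({
        "day_of_year": base_doy,
        "tmin_c": _tmin_climatology(base_doy, wp),
        "rain_mm": np.full(365, wp.rain_p_wet * wp.rain_gamma_shape * wp.rain_gamma_scale_mm),
    })
    return weather, baseline


def _visit_dates(cfg: SimulationConfig, rng) -> pd.DataFrame:
    """One row per (site, year, visit): month drawn without replacement from
    April-October, day uniform on 1-28."""
    site_ids = [f"S{i + 1:03d}" for i in range(cfg.n_sites)]
    years = list(cfg.years)
    n_cells = len(site_ids) * len(years)
    months_pool = np.tile(np.arange(4, 11), (n_cells, 1))
    months = rng.permuted(months_pool, axis=1)[:, :cfg.visits_per_year]
    days = rng.integers(1, 29, size=months.shape)
    rows = {
        "site_id": np.repeat(site_ids, len(years) * cfg.visits_per_year),
        "year": np.tile(np.repeat(years, cfg.visits_per_year), len(site_ids)),
        "month": months.ravel(),
        "day": days.ravel(),
    }
    df = pd.DataFrame(rows)
    df["date"] = pd.to_datetime(dict(year=df.year, month=df.month, day=df.day))
    return df


def simulate_observations(cfg: SimulationConfig, sites: pd.DataFrame,
                          weather: pd.DataFrame, baseline: pd.DataFrame):
    """Observation table plus the ground-truth table for adult records.

    Each visit occupies a Binomial(boxes, occupancy) number of boxes; each
    occupied box holds 1 + Poisson adults with month-dependent masses, a
    possible litter of dependent young, and juveniles late in the season.
    Adult torpid states are Bernoulli draws from the cloglog linear
    predictor assembled from ``cfg.true_coefficients`` (validated against
    the model's design columns) plus a Gaussian site offset.  A small
    fraction of adult records then has sex/mass/torpid blanked or mass made
    negative, so that the cleaning rules have work to do.

    Returns ``(observations, truth)`` where ``truth`` has one row per adult
    record: ``obs_id``, linear predictor ``lp`` and probability ``p_torpid``.
    """
    rng = _rng(cfg, 3)
    visits = _visit_dates(cfg, rng)
    n_occ = rng.binomial(cfg.boxes_per_site, cfg.occupancy_prob, len(visits))
    bv = visits.loc[visits.index.repeat(n_occ)].reset_index(drop=True)
    bv["box_id"] = [f"B{j + 1:03d}" for k in n_occ for j in range(k)]

    m = len(bv)
    month = bv["month"].to_numpy()
    bv["n_adults_in_box"] = 1 + rng.poisson(cfg.extra_adult_rate, m)
    juv_rate = np.where(month >= 8, cfg.juvenile_rate_late, cfg.juvenile_rate_early)
    bv["n_juveniles_in_box"] = rng.poisson(juv_rate)
    p_breed = np.where((month >= 6) & (month <= 9),
                       cfg.breeding_prob_core, cfg.breeding_prob_other)
    breeding = rng.uniform(size=m) < p_breed
    bv["n_young_in_box"] = np.where(breeding, 1 + rng.poisson(cfg.litter_poisson_mean, m), 0)
    bv["breeding_box"] = (bv["n_young_in_box"] > 0).astype(int)

    # ---- adult records -------------------------------------------------
    ad = bv.loc[bv.index.repeat(bv["n_adults_in_box"])].reset_index(drop=True)
    na = len(ad)
    ad["age_class"] = "adult"
    ad["sex"] = np.where(rng.uniform(size=na) < 0.5, "M", "F")
    mass_mean = cfg.mass_mean_april_g + cfg.mass_slope_per_month_g * (ad["month"].to_numpy() - 4)
    ad["mass_g"] = np.round(rng.normal(mass_mean, cfg.mass_sd_g), 1)

    wcov = _cov.window_summaries(weather, baseline, ad[["site_id", "date"]])
    ad = pd.concat([ad, wcov], axis=1)

    spec = individual_model_spec()
    ad["torpid"] = 0  # placeholder so the design can be built
    design = _glm.DesignInfo(spec, ad)
    unknown = set(cfg.true_coefficients) - set(design.column_names)
    if unknown:
        raise ValueError(
            "true_coefficients reference absent design column(s): "
            + ", ".join(sorted(unknown))
        )
    beta = np.array([cfg.true_coefficients.get(nm, 0.0) for nm in design.column_names])
    site_ids = sites["site_id"].to_numpy()
    offset_mean = np.zeros(len(site_ids))
    for col, coef in cfg.site_effect_coefficients.items():
        if col not in sites.columns:
            raise ValueError(f"site_effect_coefficients references absent site column {col!r}")
        v = sites[col].to_numpy(dtype=float)
        offset_mean += coef * (v - v.mean())
    offsets = dict(zip(site_ids, offset_mean
                       + _rng(cfg, 4).normal(0.0, cfg.site_offset_sd, len(site_ids))))
    lp = design.build_matrix(ad) @ beta + ad["site_id"].map(offsets).to_numpy()
    p = _glm.inverse_cloglog(lp)
    ad["torpid"] = (rng.uniform(size=na) < p).astype(int)

    # ---- juvenile records ---------------------------------------------
    jv = bv.loc[bv.index.repeat(bv["n_juveniles_in_box"])].reset_index(drop=True)
    jv["age_class"] = "juvenile"
    jv["sex"] = np.where(rng.uniform(size=len(jv)) < 0.5, "M", "F")
    jv["mass_g"] = np.round(rng.normal(14.0, 1.5, len(jv)), 1)
    jv["torpid"] = (rng.uniform(size=len(jv)) < cfg.juvenile_torpid_prob).astype(int)

    # ---- dependent-young records ---------------------------------------
    yg = bv.loc[bv.index.repeat(bv["n_young_in_box"])].reset_index(drop=True)
    classes = list(_YOUNG_CLASS_P)
    yg["age_class"] = rng.choice(classes, size=len(yg), p=[_YOUNG_CLASS_P[c] for c in classes])
    mu = yg["age_class"].map({c: _YOUNG_MASS[c][0] for c in classes}).to_numpy(dtype=float)
    sd = yg["age_class"].map({c: _YOUNG_MASS[c][1] for c in classes}).to_numpy(dtype=float)
    yg["mass_g"] = np.round(np.maximum(rng.normal(mu, sd), 0.5), 1)
    yg["sex"] = None
    yg["torpid"] = np.nan

    # ---- measurement problems on adult records -------------------------
    ad["torpid"] = ad["torpid"].astype(float)
    for col in ("sex", "mass_g", "torpid"):
        blank = rng.uniform(size=na) < cfg.missing_rate
        ad.loc[blank, col] = None if col == "sex" else np.nan
    neg = rng.uniform(size=na) < cfg.negative_mass_rate
    ad.loc[neg, "mass_g"] = -np.abs(rng.normal(15.0, 5.0, int(neg.sum())))

    keep = ["site_id", "box_id", "date", "year", "month", "sex", "age_class",
            "mass_g", "torpid", "n_adults_in_box", "n_juveniles_in_box",
            "n_young_in_box", "breeding_box"]
    wcols = list(wcov.columns)
    obs = pd.concat([ad[keep + wcols], jv[keep], yg[keep]], ignore_index=True)
    obs.insert(0, "obs_id", [f"O{i + 1:06d}" for i in range(len(obs))])

    truth = pd.DataFrame({
        "obs_id": obs["obs_id"].iloc[:na].to_numpy(),
        "lp": lp,
        "p_torpid": p,
    })
    return obs, truth


def simulate_dataset(cfg: SimulationConfig) -> dict:
    """Run all three generators; returns sites/weather/baseline/observations/truth."""
    sites = simulate_sites(cfg)
    weather, baseline = simulate_weather(cfg, sites)
    obs, truth = simulate_observations(cfg, sites, weather, baseline)
    return {"sites": sites, "weather": weather, "baseline": baseline,
            "observations": obs, "truth": truth}


def write_dataset(tables: dict, outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
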