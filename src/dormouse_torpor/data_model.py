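"""Observation records, site attributes and record-filtering rules.

The unit of analysis is a single nest-box dormouse record from a monthly
volunteer check: who (sex, age class, mass), where (site, box), when (date),
whether the animal was torpid, and the social context of the box (other
adults, juveniles, dependent young).  Two cleaned datasets are derived:

* the *site* dataset (adult records with complete sex/mass/torpid, active
  season April-October, programme years, sites with a minimum number of
  records) used for the site torpor index, and
* the *individual* dataset (additionally mass strictly above 10 g, sites
  with at least two records) used for the individual cloglog torpor model.

Animals are unmarked, so all per-site thresholds count records, not
individuals.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from datetime import date as _date

import pandas as pd

__all__ = [
    "Observation",
    "SiteAttributes",
    "CleaningReport",
    "YOUNG_CLASSES",
    "AGE_CLASSES",
    "load_observations",
    "load_sites",
    "observations_to_frame",
    "frame_to_observations",
    "clean_for_site_analysis",
    "clean_for_individual_analysis",
]

#: the four dependent-young age grades; "greys-eyes-open" (~16-28 days old)
#: is the grade used for mean young mass.
YOUNG_CLASSES = ("pink", "greys-eyes-closed", "greys-eyes-open", "fully-furred")
AGE_CLASSES = ("adult", "juvenile") + YOUNG_CLASSES
SEXES = ("F", "M")


@dataclass
class Observation:
    """One dormouse record from one nest-box check."""

    site_id: str
    box_id: str
    date: _date
    year: int
    month: int
    sex: str | None  # F/M, None if unrecorded
    age_class: str
    mass_g: float | None
    torpid: int | None  # 1 torpid, 0 active, None unrecorded
    n_adults_in_box: int = 1
    n_juveniles_in_box: int = 0
    n_young_in_box: int = 0

    @property
    def breeding_box(self) -> bool:
        """True when dependent young were present at the check."""
        return self.n_young_in_box > 0


@dataclass
class SiteAttributes:
    site_id: str
    latitude: float
    longitude: float
    elevation_m: float
    slope_deg: float
    aspect_deg: float
    prop_ancient: float
    prop_broadleaf: float
    broadleaf_connectivity_km2: float
    ancient_connectivity_km2: float
    solar_index: float
    elevation_scaled: float = float("nan")


@dataclass
class CleaningReport:
    """Per-rule removal counts; ``removed + retained == n_input`` always."""

    n_input: int
    n_retained: int
    removed: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    def to_json(self) -> str:
        return json.dumps(asdict(self))


_OBS_COLUMNS = [
    "site_id", "box_id", "date", "year", "month", "sex", "age_class",
    "mass_g", "torpid", "n_adults_in_box", "n_juveniles_in_box",
    "n_young_in_box",
]


def _parse_optional_float(text):
    return None if text in ("", None, "NA") else float(text)


def _parse_optional_int(text):
    return None if text in ("", None, "NA") else int(float(text))


def load_observations(path) -> list[Observation]:
    """Read an observation CSV into typed records.

    Empty cells for sex/mass/torpid are recorded as missing, never coerced to
    zero.  A month column that conflicts with the date is an error rather
    than a silent fix; unknown sex or age-class codes are errors naming the
    offending row (1-based, excluding the header).
    """
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in ("site_id", "box_id", "date", "age_class") if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"observation CSV lacks column(s): {missing}")
        for i, row in enumerate(reader, start=1):
            try:
                d = _date.fromisoformat(row["date"])
                month = _parse_optional_int(row.get("month"))
                year = _parse_optional_int(row.get("year"))
                if month is not None and month != d.month:
                    raise ValueError(f"month column {month} conflicts with date {d}")
                if year is not None and year != d.year:
                    raise ValueError(f"year column {year} conflicts with date {d}")
                sex = row.get("sex") or None
                if sex is not None and sex not in SEXES:
                    raise ValueError(f"unknown sex code {sex!r}")
                age = row["age_class"]
                if age not in AGE_CLASSES:
                    raise ValueError(f"unknown age class {age!r}")
                torpid = _parse_optional_int(row.get("torpid"))
                if torpid is not None and torpid not in (0, 1):
                    raise ValueError(f"torpid must be 0/1, got {torpid}")
                out.append(Observation(
                    site_id=row["site_id"],
                    box_id=row["box_id"],
                    date=d,
                    year=d.year,
                    month=d.month,
                    sex=sex,
                    age_class=age,
                    mass_g=_parse_optional_float(row.get("mass_g")),
                    torpid=torpid,
                    n_adults_in_box=_parse_optional_int(row.get("n_adults_in_box")) or 1,
                    n_juveniles_in_box=_parse_optional_int(row.get("n_juveniles_in_box")) or 0,
                    n_young_in_box=_parse_optional_int(row.get("n_young_in_box")) or 0,
                ))
            except (ValueError, KeyError) as err:
                raise ValueError(f"malformed observation row {i}: {err}") from err
    return out


def load_sites(path) -> pd.DataFrame:
    """Read the site attribute table; adds centred/scaled elevation across sites."""
    df = pd.read_csv(path, dtype={"site_id": str})
    needed = {"site_id", "latitude", "longitude", "elevation_m"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"site CSV lacks column(s): {sorted(missing)}")
    sd = df["elevation_m"].std(ddof=0)
    df["elevation_scaled"] = (df["elevation_m"] - df["elevation_m"].mean()) / (sd if sd > 0 else 1.0)
    return df.set_index("site_id", drop=False)


def observations_to_frame(obs: list[Observation]) -> pd.DataFrame:
    df = pd.DataFrame([{
        "site_id": o.site_id, "box_id": o.box_id, "date": o.date,
        "year": o.year, "month": o.month, "sex": o.sex,
        "age_class": o.age_class, "mass_g": o.mass_g, "torpid": o.torpid,
        "n_adults_in_box": o.n_adults_in_box,
        "n_juveniles_in_box": o.n_juveniles_in_box,
        "n_young_in_box": o.n_young_in_box,
        "breeding_box": int(o.n_young_in_box > 0),
    } for o in obs])
    if df.empty:
        df = pd.DataFrame(columns=_OBS_COLUMNS + ["breeding_box"])
    return df


def frame_to_observations(df: pd.DataFrame) -> list[Observation]:
    out = []
    for row in df.itertuples(index=False):
        d = row.date if isinstance(row.date, _date) else pd.Timestamp(row.date).date()
        out.append(Observation(
            site_id=str(row.site_id), box_id=str(row.box_id), date=d,
            year=int(row.year), month=int(row.month),
            sex=None if pd.isna(row.sex) else str(row.sex),
            age_class=str(row.age_class),
            mass_g=None if pd.isna(row.mass_g) else float(row.mass_g),
            torpid=None if pd.isna(row.torpid) else int(row.torpid),
            n_adults_in_box=int(row.n_adults_in_box),
            n_juveniles_in_box=int(row.n_juveniles_in_box),
            n_young_in_box=int(row.n_young_in_box),
        ))
    return out


# ---------------------------------------------------------------------------
# cleaning rules


def _record_level_rules(min_year):
    """Record-level filters shared by both cleaned datasets, in application order."""
    return [
        ("non_adult", lambda o: o.age_class != "adult"),
        ("incomplete_sex_mass_torpid",
         lambda o: o.sex is None or o.mass_g is None or o.torpid is None),
        ("erroneous_mass", lambda o: o.mass_g is not None and o.mass_g < 0),
        ("outside_active_season", lambda o: o.month < 4 or o.month > 10),
        ("before_min_year", lambda o: o.year < min_year),
    ]


def _apply_rules(obs, rules):
    removed = {}
    kept = obs
    for name, is_bad in rules:
        nxt = [o for o in kept if not is_bad(o)]
        removed[name] = len(kept) - len(nxt)
        kept = nxt
    return kept, removed


def _drop_small_sites(obs, min_count, rule_name, removed):
    counts = {}
    for o in obs:
        counts[o.site_id] = counts.get(o.site_id, 0) + 1
    kept = [o for o in obs if counts[o.site_id] >= min_count]
    removed[rule_name] = len(obs) - len(kept)
    return kept


def clean_for_site_analysis(obs, min_dormice_per_site: int = 15, min_year: int = 1993):
    """Cleaning for the site torpor-index dataset.

    Keeps adult records with complete sex/mass/torpid, non-negative mass,
    active-season months (April-October) and years from ``min_year``; then
    drops whole sites contributing fewer than ``min_dormice_per_site``
    retained records (the site-count rule runs last, on the filtered data).
    Returns ``(retained records, CleaningReport)``.
    """
    n0 = len(obs)
    kept, removed = _apply_rules(obs, _record_level_rules(min_year))
    kept = _drop_small_sites(kept, min_dormice_per_site, "small_site", removed)
    return kept, CleaningReport(n0, len(kept), removed)


def clean_for_individual_analysis(obs, min_mass_g: float = 10.0,
                                  min_site_dormice: int = 2, min_year: int = 1993):
    """Cleaning for the individual torpor-model dataset.

    Applies the shared record-level rules, then keeps only records with mass
    strictly above ``min_mass_g`` (masses at or below 10 g are treated as
    recording errors), and finally drops sites with fewer than
    ``min_site_dormice`` retained records.  Returns
    ``(retained records, CleaningReport)``.
    """
    n0 = len(obs)
    rules = _record_level_rules(min_year) + [
        ("mass_at_or_below_minimum",
         lambda o: o.mass_g is not None and o.mass_g <= min_mass_g),
    ]
    kept, removed = _apply_rules(obs, rules)
    kept = _drop_small_sites(kept, min_site_dormice, "single_dormouse_site", removed)
    return kept, CleaningReport(n0, len(kept), removed)
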