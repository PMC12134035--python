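#!/usr/bin/env python
"""Torpor scores versus population parameters.

Builds sex-specific yearly torpor scores (whole-season, early and late),
aggregates site-year population metrics, regresses the abundance and trend
surrogates on the site torpor index, fits the effect models (each metric on
female + male scores, same year and next year) and writes the score-0-vs-1
percentage effect matrix.
"""

import argparse
from pathlib import Path

import pandas as pd

from dormouse_torpor import data_model as dm
from dormouse_torpor import population_effects as pe
from dormouse_torpor import torpor_index as ti

ALL_RESPONSES = list(pe.COUNT_RESPONSES) + list(pe.GAUSSIAN_RESPONSES)
SEASONAL_RESPONSES = ["adult_count_total", "young_count"]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--cleaned", type=Path, default=Path("results/cleaned"))
    ap.add_argument("--site-index", type=Path, default=Path("results/site_index"))
    ap.add_argument("--out", type=Path, default=Path("results/population"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    obs_full = pd.read_csv(args.data / "observations.csv", parse_dates=["date"])
    clean = pd.read_csv(args.cleaned / "cleaned_site.csv", parse_dates=["date"])

    metrics = pe.aggregate_site_year(obs_full)
    metrics.to_csv(args.out / "metrics.csv", index=False)
    print(f"site-year metrics: {len(metrics)} cells")

    idx_frame = pd.read_csv(args.site_index / "site_index.csv")
    idx = dict(zip(idx_frame.site_id, idx_frame["index"]))
    ab = pe.abundance_index(obs_full)
    fit_ab, fit_tr = pe.abundance_trend_regression(idx, ab)
    for label, fit in (("abundance", fit_ab), ("trend", fit_tr)):
        b, p = fit.params["torpor_index"], fit.pvalues["torpor_index"]
        print(f"  {label} surrogate ~ torpor index: slope {b:+.4f}, p {p:.4f}")
    ab.to_csv(args.out / "abundance_surrogates.csv", index=False)

    scores = {}
    for season in ("all", "early", "late"):
        for sex in ("F", "M"):
            scores[(sex, season)] = ti.yearly_sex_scores(clean, sex, season)
    pd.concat([s.to_frame() for s in scores.values()]) \
        .to_csv(args.out / "yearly_scores.csv", index=False)
    print(f"yearly scores: {sum(len(s.scores) for s in scores.values())} "
          "(site, year, sex, season) cells")

    rows = []
    for season in ("all", "early", "late"):
        responses = ALL_RESPONSES if season == "all" else SEASONAL_RESPONSES
        sf, sm = scores[("F", season)], scores[("M", season)]
        for response in responses:
            for lag in (0, 1):
                try:
                    fit = pe.fit_effect_model(metrics, sf, sm, response, lag)
                except (ValueError, KeyError):
                    continue
                for sex in ("F", "M"):
                    if f"score_{sex}" not in fit.names:
                        continue
                    es = pe.effect_magnitude(fit, sex, response, lag, season)
                    rows.append(es.as_dict())
    effects = pd.DataFrame(rows)
    effects.to_csv(args.out / "effects.csv", index=False)

    print(f"effect matrix: {len(effects)} cells -> {args.out / 'effects.csv'}")
    same_year = effects[(effects.lag == 0) & (effects.season == "all")]
    for r in same_year.itertuples():
        arrow = {"up": "+", "down": "-", "none": "="}[r.direction]
        print(f"  [{arrow}] {r.response:<22s} {r.sex} score 0->1: "
              f"{r.pct_change:+.1f}% (95% CI {r.ci_low:+.1f} to {r.ci_high:+.1f})")


if __name__ == "__main__":
    main()
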