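#!/usr/bin/env python
"""Individual-level cloglog torpor model with multi-scale climate covariates.

Joins daily/weekly/monthly/seasonal weather residuals (site series minus the
30-year baseline) onto the cleaned individual dataset, fits the binomial
cloglog GLM of torpid state on month, mass, sex, box social context and the
eight weather windows (with mass-by-month and sex-by-month interactions),
and validates it with an ROC sweep.  Writes the coefficient table with
hazard ratios, the ROC curve, and a comparison of fitted coefficients
against the generator's truth.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dormouse_torpor import covariates as cov
from dormouse_torpor import glm
from dormouse_torpor import synthetic_data as sd


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--cleaned", type=Path, default=Path("results/cleaned"))
    ap.add_argument("--out", type=Path, default=Path("results/individual_model"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    obs = pd.read_csv(args.cleaned / "cleaned_individual.csv", parse_dates=["date"])
    weather = pd.read_csv(args.data / "weather.csv", parse_dates=["date"])
    baseline = pd.read_csv(args.data / "baseline.csv")

    wcov = cov.window_summaries(weather, baseline, obs)
    df = pd.concat([obs, wcov], axis=1)
    print(f"fitting cloglog torpor model on {len(df)} adult records")

    spec = sd.individual_model_spec()
    fit = glm.fit_glm(spec, df)
    summary = fit.summary_frame()
    summary.to_csv(args.out / "coefficients.csv")
    (args.out / "model.json").write_text(fit.to_json())

    cfg_path = args.data / "config.json"
    if cfg_path.exists():
        truth = sd.SimulationConfig.from_json(cfg_path.read_text()).true_coefficients
        summary["true_coefficient"] = [truth.get(n, 0.0) for n in summary.index]
        summary["within_95_ci"] = (np.abs(summary.coefficient - summary.true_coefficient)
                                   <= 1.96 * summary.std_error)
        summary.to_csv(args.out / "coefficients.csv")
        print(f"  {int(summary.within_95_ci.sum())}/{len(summary)} coefficients "
              "cover the generator's truth in their 95% CI")
        print("  (the default dataset has unmodelled Gaussian site offsets, so "
              "some attenuation of fixed effects is expected)")

    print(f"  AIC {fit.aic:.1f}, converged after {fit.n_iter} IRLS iterations")
    for term in ("tmin_daily_resid", "tmin_seasonal_resid",
                 "rain_daily_resid", "rain_seasonal_resid", "breeding_box"):
        hr = glm.hazard_ratio(fit, term)
        p = fit.pvalues[term]
        print(f"  {term:<22s} coef {fit.params[term]:+.4f}  hazard ratio {hr:.4f}  p {p:.2g}")

    roc = glm.auc_roc(fit.predict(df), df["torpid"].to_numpy())
    pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(args.out / "roc.csv", index=False)
    print(f"  in-sample ROC AUC {roc.auc:.3f}")


if __name__ == "__main__":
    main()
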