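"""All-subsets model selection over site covariates.

Fits every subset of a set of candidate covariates (intercept always
included) as Gaussian GLMs on the site torpor index, ranks models by AIC,
takes the *top set* of models within a ΔAIC threshold (2 by default) of the
best, and summarises:

* **importance** of a variable — the fraction of top-set models that
  contain it (an unweighted proportion, which is how these analyses are
  usually reported for this statistic; not the sum-of-Akaike-weights
  convention), and
* **weighted-average coefficients** — full model averaging over the top
  set with Akaike weights renormalised within the set, counting a model
  that omits a variable as contributing coefficient zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import glm as _glm

__all__ = [
    "DredgeResult",
    "dredge",
    "top_model_set",
    "variable_importance",
    "weighted_average_coefficients",
]


@dataclass
class DredgeResult:
    """Every fitted subset with its AIC ranking."""

    table: pd.DataFrame  # one row per model: terms, k, aic, delta_aic, weight, in_top_set
    fits: list  # FitResult per row
    candidates: list
    delta: float

    @property
    def best_index(self) -> int:
        return int(self.table["delta_aic"].idxmin())

    @property
    def best_fit(self):
        return self.fits[self.best_index]


def dredge(data: pd.DataFrame, response: str, candidates, family: str = "gaussian",
           delta: float = 2.0) -> DredgeResult:
    """Exhaustively fit all 2^k covariate subsets and rank them by AIC.

    ``data`` must be complete cases for ``response`` and every candidate;
    non-finite values raise an error listing the offending rows.  At most 20
    candidates are allowed (2^20 fits).  Ties for the best AIC are flagged in
    the table (every tied model gets ``delta_aic`` 0).
    """
    candidates = list(candidates)
    if len(candidates) > 20:
        raise ValueError("dredge is exhaustive; at most 20 candidate terms")
    check = data[[response] + candidates]
    bad = check.index[~np.isfinite(check.to_numpy(dtype=float)).all(axis=1)]
    if len(bad):
        raise ValueError(f"non-finite response/covariate values at rows: {list(bad[:10])}")

    rows = []
    fits = []
    for k in range(len(candidates) + 1):
        for subset in combinations(candidates, k):
            spec = _glm.ModelSpec(response, subset, family=family)
            fit = _glm.fit_glm(spec, data)
            fits.append(fit)
            rows.append({"terms": subset, "k": len(subset), "aic": fit.aic})
    table = pd.DataFrame(rows)
    best = table["aic"].min()
    table["delta_aic"] = table["aic"] - best
    rel = np.exp(-0.5 * table["delta_aic"])
    table["weight"] = rel / rel.sum()
    table["in_top_set"] = table["delta_aic"] <= delta
    table["aic_tie"] = np.isclose(table["aic"], best) & (table["delta_aic"] > 0)
    return DredgeResult(table, fits, candidates, delta)


def top_model_set(dr: DredgeResult, delta: float = 2.0) -> pd.DataFrame:
    """Models within ``delta`` AIC of the best; always contains the best model."""
    return dr.table[dr.table["delta_aic"] <= delta]


def variable_importance(dr: DredgeResult, top: pd.DataFrame | None = None) -> dict:
    """Fraction of top-set models containing each candidate variable."""
    if top is None:
        top = top_model_set(dr, dr.delta)
    if top.empty:
        raise ValueError("top model set is empty")
    n = len(top)
    return {v: float(sum(v in t for t in top["terms"]) / n) for v in dr.candidates}


def weighted_average_coefficients(dr: DredgeResult, top: pd.DataFrame | None = None) -> dict:
    """Akaike-weighted full-average coefficient per candidate over the top set.

    Weights are renormalised within the set; models omitting a variable
    contribute zero for it (full averaging).
    """
    if top is None:
        top = top_model_set(dr, dr.delta)
    if top.empty:
        raise ValueError("top model set is empty")
    w = top["weight"].to_numpy()
    w = w / w.sum()
    out = {v: 0.0 for v in dr.candidates}
    for weight, idx in zip(w, top.index):
        params = dr.fits[idx].params
        for v in dr.candidates:
            out[v] += weight * params.get(v, 0.0)
    return out
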