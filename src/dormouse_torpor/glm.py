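"""Generalised linear models for the torpor analyses.

Implements the model machinery every stage of the pipeline shares: binomial
GLMs with logit or complementary log-log (cloglog) links for the torpid/not
torpid response, Gaussian models for the site-index regressions and Poisson
log-link models for count responses.  Fitting is by iteratively reweighted
least squares (IRLS) with step-halving, inference is Wald, and model
comparison uses AIC computed from the full log-likelihood.

The cloglog link is central: under ``g(p) = log(-log(1 - p))`` a shift of a
covariate by ``delta`` multiplies the event hazard by ``exp(beta * delta)``,
so a baseline probability ``p0`` maps to ``1 - (1 - p0) ** exp(beta * delta)``.
``hazard_ratio`` and ``cloglog_shift`` expose that identity directly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "PredictionResult",
    "RocResult",
    "fit_glm",
    "predict_response",
    "hazard_ratio",
    "cloglog_shift",
    "inverse_logit",
    "logit",
    "inverse_cloglog",
    "cloglog",
    "auc_roc",
    "FAMILIES",
]

_ETA_MAX = 30.0
_MU_EPS = 1e-12
#: absolute coefficient magnitude beyond which a fit is flagged as separated
SEPARATION_CAP = 15.0

FAMILIES = ("gaussian", "binomial-logit", "binomial-cloglog", "poisson")


# ---------------------------------------------------------------------------
# link functions


def inverse_logit(x):
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    return special.expit(x)


def logit(p):
    return special.logit(p)


def cloglog(p):
    """Complementary log-log link g(p) = log(-log(1 - p))."""
    p = np.asarray(p, dtype=float)
    return np.log(-np.log1p(-p))


def inverse_cloglog(eta):
    """Inverse cloglog, 1 - exp(-exp(eta)), clipped against overflow."""
    eta = np.clip(np.asarray(eta, dtype=float), -_ETA_MAX, _ETA_MAX)
    return -np.expm1(-np.exp(eta))


def cloglog_shift(p0, beta, delta):
    """Probability after shifting a cloglog-model covariate by ``delta``.

    Under the cloglog link the hazard is multiplied by ``exp(beta * delta)``,
    so ``p0`` maps to ``1 - (1 - p0) ** exp(beta * delta)``.
    """
    return -np.expm1(np.log1p(-np.asarray(p0, dtype=float)) * np.exp(beta * delta))


class _Family:
    name: str

    def link(self, mu):  # pragma: no cover - abstract
        raise NotImplementedError

    def inverse(self, eta):  # pragma: no cover - abstract
        raise NotImplementedError


class _Gaussian(_Family):
    name = "gaussian"

    def link(self, mu):
        return np.asarray(mu, dtype=float)

    def inverse(self, eta):
        return np.asarray(eta, dtype=float)


class _BinomialLogit(_Family):
    name = "binomial-logit"

    def link(self, mu):
        return logit(mu)

    def inverse(self, eta):
        return inverse_logit(eta)

    def init_mu(self, y):
        return (y + 0.5) / 2.0

    def dmu_deta(self, eta):
        mu = inverse_logit(eta)
        return mu * (1.0 - mu)

    def variance(self, mu):
        return mu * (1.0 - mu)

    def loglik(self, y, mu):
        mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
        return float(np.sum(y * np.log(mu) + (1.0 - y) * np.log1p(-mu)))


class _BinomialCloglog(_BinomialLogit):
    name = "binomial-cloglog"

    def link(self, mu):
        return cloglog(mu)

    def inverse(self, eta):
        return inverse_cloglog(eta)

    def dmu_deta(self, eta):
        eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
        return np.exp(eta - np.exp(eta))


class _Poisson(_Family):
    name = "poisson"

    def link(self, mu):
        return np.log(mu)

    def inverse(self, eta):
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))

    def init_mu(self, y):
        return y + 0.5

    def dmu_deta(self, eta):
        return self.inverse(eta)

    def variance(self, mu):
        return mu

    def loglik(self, y, mu):
        mu = np.maximum(mu, _MU_EPS)
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1.0)))


_FAMILY_MAP = {
    "gaussian": _Gaussian(),
    "binomial-logit": _BinomialLogit(),
    "binomial-cloglog": _BinomialCloglog(),
    "poisson": _Poisson(),
}


# ---------------------------------------------------------------------------
# model specification and design matrices


@dataclass(frozen=True)
class ModelSpec:
    """Symbolic model description.

    Parameters
    ----------
    response : str
        Column holding the response variable.
    terms : sequence of str
        Main effects (column names) and pairwise interactions written
        ``"a:b"``.  Interaction components must also appear as main effects.
    factors : dict, optional
        Maps categorical variables to their declared reference level;
        everything else is treated as numeric.  Treatment (dummy) coding is
        used throughout.
    family : str
        One of ``gaussian``, ``binomial-logit``, ``binomial-cloglog``,
        ``poisson``.
    """

    response: str
    terms: tuple
    factors: dict = field(default_factory=dict)
    family: str = "gaussian"

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "factors", dict(self.factors))
        if self.family not in _FAMILY_MAP:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        mains = {t for t in self.terms if ":" not in t}
        for t in self.terms:
            if ":" in t:
                parts = t.split(":")
                if len(parts) != 2:
                    raise ValueError(f"only pairwise interactions supported: {t!r}")
                for p in parts:
                    if p not in mains:
                        raise ValueError(
                            f"interaction {t!r} references {p!r}, which is not a declared main effect"
                        )

    @property
    def variables(self):
        out = []
        for t in self.terms:
            for v in t.split(":"):
                if v not in out:
                    out.append(v)
        return out


class DesignInfo:
    """Treatment-coded design-matrix builder bound to observed factor levels."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        self.levels = {}
        for var, ref in spec.factors.items():
            if var not in data.columns:
                raise KeyError(f"factor {var!r} not in data")
            obs = pd.unique(data[var].dropna())
            obs = sorted(obs, key=str)
            if ref not in obs:
                raise ValueError(f"reference level {ref!r} absent from column {var!r}")
            self.levels[var] = [ref] + [l for l in obs if l != ref]
        self.column_names = ["(Intercept)"]
        for term in spec.terms:
            self.column_names.extend(n for n, _ in self._term_columns_meta(term))

    def _var_columns_meta(self, var):
        """(name, encoder) pairs for one variable; encoder maps a Series/value to floats."""
        if var in self.levels:
            out = []
            for lvl in self.levels[var][1:]:
                out.append((f"{var}[{lvl}]", ("factor", var, lvl)))
            return out
        return [(var, ("numeric", var))]

    def _term_columns_meta(self, term):
        parts = term.split(":")
        metas = [self._var_columns_meta(p) for p in parts]
        if len(metas) == 1:
            return metas[0]
        out = []
        for n1, m1 in metas[0]:
            for n2, m2 in metas[1]:
                out.append((f"{n1}:{n2}", ("product", m1, m2)))
        return out

    def _eval_meta(self, meta, data):
        kind = meta[0]
        if kind == "numeric":
            col = pd.to_numeric(data[meta[1]], errors="raise").to_numpy(dtype=float)
            return col
        if kind == "factor":
            _, var, lvl = meta
            vals = data[var]
            unknown = set(pd.unique(vals.dropna())) - set(self.levels[var])
            if unknown:
                raise ValueError(f"unknown level(s) {sorted(map(str, unknown))} for factor {var!r}")
            return (vals == lvl).to_numpy(dtype=float)
        # product
        return self._eval_meta(meta[1], data) * self._eval_meta(meta[2], data)

    def build_matrix(self, data: pd.DataFrame) -> np.ndarray:
        n = len(data)
        cols = [np.ones(n)]
        for term in self.spec.terms:
            for _, meta in self._term_columns_meta(term):
                cols.append(self._eval_meta(meta, data))
        return np.column_stack(cols)

    def build_row(self, setting: dict) -> np.ndarray:
        missing = [v for v in self.spec.variables if v not in setting]
        if missing:
            raise KeyError(f"covariate setting missing model variable(s): {missing}")
        frame = pd.DataFrame({k: [v] for k, v in setting.items()})
        return self.build_matrix(frame)[0]


# ---------------------------------------------------------------------------
# results


@dataclass
class FitResult:
    """A fitted GLM: coefficients, Wald inference and fit statistics."""

    spec: ModelSpec
    names: list
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    aic: float
    n: int
    converged: bool
    n_iter: int
    separation: bool
    design: DesignInfo
    aliased: list = field(default_factory=list)

    @property
    def params(self) -> dict:
        return dict(zip(self.names, self.beta))

    @property
    def bse(self) -> dict:
        return dict(zip(self.names, self.se))

    @property
    def pvalues(self) -> dict:
        z = self.beta / self.se
        return dict(zip(self.names, 2.0 * stats.norm.sf(np.abs(z))))

    def coefficient(self, term: str) -> float:
        if term not in self.params:
            raise KeyError(f"no term {term!r}; model terms are {self.names}")
        return self.params[term]

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        X = self.design.build_matrix(data)
        keep = [i for i, n in enumerate(self.design.column_names) if n not in self.aliased]
        return X[:, keep] @ self.beta

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return _FAMILY_MAP[self.spec.family].inverse(self.linear_predictor(data))

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "coefficient": self.beta,
                "std_error": self.se,
                "p_value": list(self.pvalues.values()),
            },
            index=self.names,
        )
        if self.spec.family == "binomial-cloglog":
            out.insert(2, "hazard_ratio", np.exp(self.beta))
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.spec.family,
                "response": self.spec.response,
                "terms": list(self.spec.terms),
                "names": list(self.names),
                "beta": self.beta.tolist(),
                "se": self.se.tolist(),
                "cov": self.cov.tolist(),
                "loglik": self.loglik,
                "aic": self.aic,
                "n": self.n,
                "converged": self.converged,
                "separation": self.separation,
            }
        )


@dataclass
class PredictionResult:
    eta: float
    se_eta: float
    estimate: float
    ci_low: float
    ci_high: float


# ---------------------------------------------------------------------------
# fitting


def _rank_and_aliased(X, names):
    """QR with column pivoting; returns kept-column index and aliased names."""
    from scipy.linalg import qr as _sqr

    _, R, piv = _sqr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    keep = np.sort(piv[:rank])
    aliased = [names[i] for i in np.sort(piv[rank:])]
    return keep, aliased


def fit_glm(spec: ModelSpec, data: pd.DataFrame, *, allow_aliased: bool = False,
            max_iter: int = 100, tol: float = 1e-11) -> FitResult:
    """Fit a GLM by IRLS (exact weighted least squares for the Gaussian family).

    Treatment coding is applied against the reference levels declared in
    ``spec.factors``.  Convergence requires the relative deviance change to
    fall below ``tol``; on an IRLS step that decreases the log-likelihood the
    step is halved until it no longer does.  Structurally aliased (collinear)
    columns raise an error naming them unless ``allow_aliased`` is set, in
    which case they are dropped as R's ``glm`` does (needed for site x year
    factorial fits with empty cells).

    A fit whose largest absolute coefficient exceeds ``SEPARATION_CAP`` is
    flagged ``separation=True`` (fitted probabilities pinned at 0/1).
    """
    design = DesignInfo(spec, data)
    y = pd.to_numeric(data[spec.response], errors="raise").to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"non-finite values in response {spec.response!r}")
    X = design.build_matrix(data)
    names = list(design.column_names)
    n, p = X.shape

    keep, aliased = _rank_and_aliased(X, names)
    if aliased:
        if not allow_aliased:
            raise ValueError(
                "design matrix is rank deficient; collinear column(s): " + ", ".join(aliased)
            )
        X = X[:, keep]
        names = [names[i] for i in keep]
        p = X.shape[1]

    fam = _FAMILY_MAP[spec.family]

    if spec.family == "gaussian":
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        sigma2_mle = rss / n
        # unbiased scale for Wald standard errors, MLE scale for the likelihood
        dof = max(n - p, 1)
        xtx_inv = np.linalg.inv(X.T @ X)
        cov = (rss / dof) * xtx_inv
        loglik = -0.5 * n * (math.log(2.0 * math.pi * max(sigma2_mle, 1e-300)) + 1.0)
        aic = -2.0 * loglik + 2.0 * p
        se = np.sqrt(np.diag(cov))
        return FitResult(spec, names, beta, se, cov, loglik, aic, n, True, 0, False,
                         design, aliased)

    mu = fam.init_mu(y)
    eta = fam.link(np.clip(mu, _MU_EPS, None) if spec.family == "poisson"
                   else np.clip(mu, _MU_EPS, 1 - _MU_EPS))
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = fam.dmu_deta(eta)
        var = np.maximum(fam.variance(np.clip(mu, _MU_EPS, 1 - _MU_EPS)
                                      if spec.family.startswith("binomial") else mu), _MU_EPS)
        d = np.maximum(d, _MU_EPS)
        w = d * d / var
        z = eta + (y - mu) / d
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)

        # step-halving: never accept a step that lowers the log-likelihood
        step = 1.0
        for _ in range(32):
            cand = beta + step * (beta_new - beta)
            eta_c = X @ cand
            mu_c = fam.inverse(eta_c)
            ll_c = fam.loglik(y, mu_c)
            if np.isfinite(ll_c) and (ll_c >= ll_old - 1e-12 or step < 1e-8):
                break
            step *= 0.5
        dbeta = np.max(np.abs(cand - beta)) / (1.0 + np.max(np.abs(cand)))
        beta, eta, mu = cand, eta_c, mu_c
        if abs(ll_c - ll_old) / (abs(ll_c) + 0.1) < tol and dbeta < 1e-9:
            converged = True
            ll_old = ll_c
            break
        ll_old = ll_c

    d = np.maximum(fam.dmu_deta(eta), _MU_EPS)
    var = np.maximum(fam.variance(np.clip(mu, _MU_EPS, 1 - _MU_EPS)
                                  if spec.family.startswith("binomial") else mu), _MU_EPS)
    w = d * d / var
    fisher = X.T @ (X * w[:, None])
    cov = np.linalg.pinv(fisher)
    cov = 0.5 * (cov + cov.T)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    loglik = fam.loglik(y, mu)
    aic = -2.0 * loglik + 2.0 * p
    separation = bool(np.max(np.abs(beta)) > SEPARATION_CAP)
    return FitResult(spec, names, beta, se, cov, loglik, aic, n, converged, it,
                     separation, design, aliased)


def hazard_ratio(fit: FitResult, term: str) -> float:
    """exp(beta) for a named term: the multiplicative effect on the cloglog hazard."""
    return float(np.exp(fit.coefficient(term)))


def predict_response(fit: FitResult, setting: dict) -> PredictionResult:
    """Response-scale prediction with a Wald 95% CI transformed from the linear predictor.

    The CI is computed on the eta scale and mapped through the inverse link,
    which keeps probability predictions inside [0, 1] and preserves ordering.
    """
    row_full = fit.design.build_row(setting)
    keep = [i for i, n in enumerate(fit.design.column_names) if n not in fit.aliased]
    row = row_full[keep]
    eta = float(row @ fit.beta)
    se_eta = float(math.sqrt(max(row @ fit.cov @ row, 0.0)))
    fam = _FAMILY_MAP[fit.spec.family]
    lo, hi = fam.inverse(eta - 1.96 * se_eta), fam.inverse(eta + 1.96 * se_eta)
    return PredictionResult(eta, se_eta, float(fam.inverse(eta)), float(lo), float(hi))


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def auc_roc(scores, labels, threshold_grid=None) -> RocResult:
    """ROC curve and trapezoidal AUC.

    Sweeps every distinct score as a threshold (or ``threshold_grid`` if
    given), accumulating true- and false-positive rates, and integrates by
    the trapezoid rule.  Tied scores collapse to a single curve vertex, so
    each tied positive/negative pair contributes 1/2 -- the Mann-Whitney
    convention, making the area equal to the rank-based U statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("auc_roc requires both classes present")
    if threshold_grid is None:
        order = np.argsort(-scores, kind="mergesort")
        s_sorted = scores[order]
        y_sorted = pos[order].astype(float)
        distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
        tp = np.cumsum(y_sorted)[distinct]
        fp = (distinct + 1) - tp
        thresholds = s_sorted[distinct]
    else:
        thresholds = np.sort(np.asarray(threshold_grid, dtype=float))[::-1]
        tp = np.array([(scores[pos] >= t).sum() for t in thresholds], dtype=float)
        fp = np.array([(scores[~pos] >= t).sum() for t in thresholds], dtype=float)
    tpr = np.r_[0.0, tp / n1]
    fpr = np.r_[0.0, fp / n0]
    if fpr[-1] < 1.0 or tpr[-1] < 1.0:
        fpr = np.r_[fpr, 1.0]
        tpr = np.r_[tpr, 1.0]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(auc, fpr, tpr, np.asarray(thresholds, dtype=float))
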