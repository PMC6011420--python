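"""Outcome models: IPW logistic, Cox proportional hazards, lognormal AFT.

All three regress an IQR-standardized exposure summary (or quartile
indicators) on the delivery outcome, weighted by the nested case-control
design weights, and report the effect on its natural scale:

* logistic — odds ratio of preterm birth (delivery before 259 days) per IQR;
* Cox — hazard ratio of delivery per IQR (every pregnancy ends in delivery,
  so there is no censoring; HR > 1 means shorter time to delivery); ties on
  the day scale are handled with the Efron approximation;
* lognormal AFT — with no censoring this is a weighted normal linear model
  for log gestational age; the coefficient is reported as the percent change
  in gestational age per IQR, 100 * (exp(gamma) - 1).

Variance estimation: the design weights make the usual information-based
variance invalid, so a robust (sandwich) variance with squared weights in the
meat is used for the logistic and AFT fits (computed explicitly), and
lifelines' robust variance for the Cox fit. The model-based SE is also kept
on each estimate for comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

__all__ = [
    "EffectEstimate",
    "encode_covariates",
    "fit_logistic",
    "fit_cox",
    "fit_aft_lognormal",
    "percent_change",
    "fit_quartile_models",
]

Z_95 = stats.norm.ppf(0.975)


@dataclass
class EffectEstimate:
    """One exposure effect from one outcome model.

    ``effect`` is on the natural scale (OR / HR / percent change) with a 95%
    Wald CI obtained by transforming the coefficient-scale limits.
    """

    model: str                  # "logistic" | "cox" | "aft"
    exposure: str
    scale: str                  # "per_IQR" or "Q2"/"Q3"/"Q4"
    coef: float
    se: float                   # robust (sandwich) SE
    effect: float
    ci_low: float
    ci_high: float
    n: int
    se_model: float = float("nan")   # model-based SE, for comparison
    pvalue: float = float("nan")

    def summary(self) -> str:
        name = {"logistic": "OR", "cox": "HR", "aft": "% change"}[self.model]
        return (f"{self.exposure} [{self.scale}] {self.model}: "
                f"{name}={self.effect:.3f} (95% CI {self.ci_low:.3f}, "
                f"{self.ci_high:.3f})")

    def as_row(self) -> dict:
        return {
            "exposure": self.exposure, "model": self.model,
            "scale": self.scale, "n": self.n, "coefficient": self.coef,
            "se": self.se, "effect": self.effect,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pvalue": self.pvalue,
        }


def percent_change(gamma: float) -> float:
    """AFT coefficient -> percent change in gestational age, 100(e^g - 1)."""
    return 100.0 * (math.exp(gamma) - 1.0)


def encode_covariates(z: pd.DataFrame) -> pd.DataFrame:
    """Design columns for adjustment covariates.

    Categorical (object/category) columns become reference-coded indicators
    with the most frequent level as reference; numeric columns pass through.
    """
    if z is None or z.shape[1] == 0:
        return pd.DataFrame(index=None if z is None else z.index)
    parts = []
    for col in z.columns:
        s = z[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            ref = s.value_counts().idxmax()
            for level in sorted(x for x in s.unique() if x != ref):
                parts.append(pd.Series(
                    (s == level).astype(float), name=f"{col}[{level}]"))
        else:
            parts.append(s.astype(float))
    return pd.concat(parts, axis=1)


def _design(x, z: pd.DataFrame | None) -> pd.DataFrame:
    if isinstance(x, pd.Series):
        x = x.to_frame()
    xz = pd.concat([x.astype(float), encode_covariates(z)], axis=1)
    if xz.isna().any().any():
        raise ValueError("missing values in design matrix")
    return sm.add_constant(xz, has_constant="add")


def _wald(coef, se, transform):
    lo, hi = coef - Z_95 * se, coef + Z_95 * se
    return transform(coef), transform(lo), transform(hi)


def fit_logistic(x, e, z=None, weights=None, label=None) -> EffectEstimate:
    """IPW logistic regression of the preterm indicator on one exposure.

    ``x`` is the IQR-standardized exposure (Series); ``z`` optional covariate
    DataFrame; ``weights`` the design weights (default 1). Returns the OR per
    IQR with a robust-SE Wald CI.
    """
    ests = _fit_logistic_multi(x, e, z, weights)
    est = ests[0]
    if label:
        est.exposure = label
    return est


def _fit_logistic_multi(x, e, z, weights) -> list[EffectEstimate]:
    design = _design(x, z)
    y = np.asarray(e, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    res = sm.GLM(y, design, family=sm.families.Binomial(),
                 freq_weights=w).fit()
    if not res.converged or not np.all(np.isfinite(res.params)):
        raise RuntimeError("logistic fit did not converge")
    col_sd = design.std().to_numpy()
    scaled = np.abs(res.params.to_numpy())[col_sd > 0] * col_sd[col_sd > 0]
    if scaled.size and scaled.max() > 15:
        raise ValueError("(quasi-)separation: a coefficient diverged")
    p = np.asarray(res.fittedvalues)
    xa = design.to_numpy()
    bread = res.cov_params().to_numpy()
    score = (w * (y - p))[:, None] * xa
    cov = bread @ (score.T @ score) @ bread
    n_exp = 1 if isinstance(x, pd.Series) else x.shape[1]
    names = [x.name] if isinstance(x, pd.Series) else list(x.columns)
    out = []
    for i, name in enumerate(names):
        j = list(design.columns).index(name)
        coef = float(res.params.iloc[j])
        se = float(np.sqrt(max(cov[j, j], 0.0)))
        eff, lo, hi = _wald(coef, se, math.exp)
        out.append(EffectEstimate(
            model="logistic", exposure=str(name), scale="per_IQR",
            coef=coef, se=se, effect=eff, ci_low=lo, ci_high=hi,
            n=len(y), se_model=float(res.bse.iloc[j]),
            pvalue=2 * stats.norm.sf(abs(coef / se))))
    return out


def fit_cox(x, t_days, z=None, weights=None, label=None) -> EffectEstimate:
    """IPW Cox proportional-hazards fit of time to delivery on one exposure.

    All subjects are events (every pregnancy delivers). Efron tie handling,
    robust variance.
    """
    return _fit_cox_multi(x, t_days, z, weights, label)[0]


def _fit_cox_multi(x, t_days, z, weights, label=None) -> list[EffectEstimate]:
    t = np.asarray(t_days, dtype=float)
    if np.all(t == t[0]):
        raise ValueError("all event times identical")
    design = _design(x, z).drop(columns="const")
    names = [x.name] if isinstance(x, pd.Series) else list(x.columns)
    # a constant exposure leaves the partial likelihood flat: estimate 0
    flat = [c for c in names if design[c].nunique() == 1]
    if flat:
        if set(flat) != set(names):
            raise ValueError(f"constant exposure column(s) {flat}")
        return [EffectEstimate(
            model="cox", exposure=label or str(c), scale="per_IQR",
            coef=0.0, se=float("inf"), effect=1.0, ci_low=0.0,
            ci_high=float("inf"), n=len(t), pvalue=1.0) for c in flat]
    df = design.copy()
    df["_T"] = t
    df["_E"] = 1
    w = np.ones(len(t)) if weights is None else np.asarray(weights, dtype=float)
    df["_w"] = w
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="_T", event_col="_E", weights_col="_w",
                robust=True)
    names = [x.name] if isinstance(x, pd.Series) else list(x.columns)
    out = []
    for i, name in enumerate(names):
        coef = float(cph.params_[name])
        se = float(cph.standard_errors_[name])
        eff, lo, hi = _wald(coef, se, math.exp)
        out.append(EffectEstimate(
            model="cox", exposure=label or str(name), scale="per_IQR",
            coef=coef, se=se, effect=eff, ci_low=lo, ci_high=hi,
            n=len(t), pvalue=2 * stats.norm.sf(abs(coef / se))))
    return out


def _weighted_ols(xa: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares with an explicit IPW sandwich.

    Returns (beta, cov_robust, cov_model). The sandwich meat uses squared
    weights — the estimating equation is sum_i w_i (y_i - x_i'b) x_i = 0.
    """
    xtw = xa.T * w
    bread = np.linalg.inv(xtw @ xa)
    beta = bread @ (xtw @ y)
    resid = y - xa @ beta
    score = (w * resid)[:, None] * xa
    cov_robust = bread @ (score.T @ score) @ bread
    sigma2 = float(np.sum(w * resid**2) / np.sum(w))
    dof = max(len(y) - xa.shape[1], 1)
    sigma2_unb = float(np.sum(w * resid**2) / np.sum(w) * len(y) / dof)
    cov_model = bread * sigma2_unb * np.sum(w) / len(y)
    return beta, cov_robust, cov_model


def fit_aft_lognormal(x, t_days, z=None, weights=None, label=None) -> EffectEstimate:
    """Lognormal accelerated failure time fit (no censoring).

    With every subject delivering, the lognormal AFT reduces to a weighted
    normal linear model for log T; the per-IQR coefficient is reported as
    100 * (exp(gamma) - 1), the percent change in gestational age.
    """
    return _fit_aft_multi(x, t_days, z, weights, label)[0]


def _fit_aft_multi(x, t_days, z, weights, label=None) -> list[EffectEstimate]:
    t = np.asarray(t_days, dtype=float)
    if np.any(t <= 0):
        raise ValueError("gestational ages must be positive")
    design = _design(x, z)
    y = np.log(t)
    w = np.ones(len(t)) if weights is None else np.asarray(weights, dtype=float)
    beta, cov_r, cov_m = _weighted_ols(design.to_numpy(), y, w)
    names = [x.name] if isinstance(x, pd.Series) else list(x.columns)
    cols = list(design.columns)
    out = []
    for name in names:
        j = cols.index(name)
        coef = float(beta[j])
        se = float(np.sqrt(cov_r[j, j]))
        eff, lo, hi = _wald(coef, se, percent_change)
        out.append(EffectEstimate(
            model="aft", exposure=label or str(name), scale="per_IQR",
            coef=coef, se=se, effect=eff, ci_low=lo, ci_high=hi,
            n=len(t), se_model=float(np.sqrt(cov_m[j, j])),
            pvalue=2 * stats.norm.sf(abs(coef / se))))
    return out


def fit_quartile_models(
    quartile, e, t_days, z=None, weights=None, label="score",
) -> list[EffectEstimate]:
    """Quartile-contrast versions of all three models.

    ``quartile`` holds integer categories 1..4 (1 = reference). Returns nine
    estimates: Q2/Q3/Q4 vs Q1 for logistic, Cox and AFT.
    """
    q = np.asarray(quartile)
    counts = pd.Series(q).value_counts()
    for level in (1, 2, 3, 4):
        if counts.get(level, 0) == 0:
            raise ValueError(f"empty quartile Q{level}")
    dummies = pd.DataFrame(
        {f"Q{k}": (q == k).astype(float) for k in (2, 3, 4)})
    if isinstance(quartile, pd.Series):
        dummies.index = quartile.index
    if z is not None:
        dummies.index = z.index
    out = []
    for fitter, yarg in ((_fit_logistic_multi, e),
                         (_fit_cox_multi, t_days),
                         (_fit_aft_multi, t_days)):
        ests = fitter(dummies, yarg, z, weights)
        for est, col in zip(ests, ("Q2", "Q3", "Q4")):
            est.scale = col
            est.exposure = label
        out.extend(ests)
    return out
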