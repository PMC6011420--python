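"""Two-stage repeated-measures exposure modelling.

Stage 1 fits a random-intercept linear mixed model to the repeated log
exposure measurements (or to per-visit risk scores),

    y_ij = phi_0 + phi_1 * T_ij + phi_2 * SG_ij + b_0i + e_ij,

with ``b_0i ~ N(0, sigma_b^2)`` and ``e_ij ~ N(0, sigma^2)``, where T_ij is
gestational week at sample collection and SG_ij the visit's specific gravity.
The best linear unbiased predictors (BLUPs) of the subject intercepts are
shrinkage estimates of each subject's long-term exposure level relative to
the population mean — subjects with fewer visits are shrunk harder — and,
after IQR standardization, they serve as the exposure summary in the stage-2
outcome models. Unlike the simple visit average, the BLUP uses all four
visits and handles unequal visit counts in a principled way, at the price of
extra sampling noise in the stage-2 coefficient (attenuation of the observed
associations).

Estimation is REML via statsmodels MixedLM; if the optimizer fails, a
method-of-moments (one-way ANOVA on fixed-effect residuals) fallback is used
with a logged warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exposures import iqr_standardize

__all__ = ["RandomIntercept", "RandomInterceptResults"]

logger = logging.getLogger(__name__)


@dataclass
class RandomInterceptResults:
    """Fitted random-intercept model.

    Attributes
    ----------
    fe_params : Series
        Fixed effects (intercept and covariate slopes).
    var_between : float
        Between-subject variance sigma_b^2.
    var_resid : float
        Residual (within-subject) variance sigma^2.
    blups : Series
        BLUPs of the subject-specific intercepts, indexed by subject.
    n_visits : Series
        Observations per subject.
    converged : bool
    method : str
        "reml", "ml" or "moments" (fallback).
    """

    fe_params: pd.Series
    var_between: float
    var_resid: float
    blups: pd.Series
    n_visits: pd.Series
    converged: bool
    method: str

    @property
    def icc(self) -> float:
        return self.var_between / (self.var_between + self.var_resid)

    def standardized_blups(self, quantile_method: str = "linear"):
        """IQR-standardized BLUPs and the IQR used.

        Raises if the BLUP IQR is zero (no usable between-subject signal).
        """
        return iqr_standardize(self.blups, quantile_method=quantile_method)

    def summary(self) -> str:
        lines = [
            f"Random-intercept LMM ({self.method}), "
            f"{len(self.blups)} subjects, {int(self.n_visits.sum())} obs",
            f"  sigma_b^2 = {self.var_between:.4f}   "
            f"sigma^2 = {self.var_resid:.4f}   ICC = {self.icc:.3f}",
        ]
        for name, val in self.fe_params.items():
            lines.append(f"  {name:>12}: {val: .5f}")
        return "\n".join(lines)


class RandomIntercept:
    """Random-intercept linear mixed model for repeated exposure measures.

    Parameters
    ----------
    data
        Long-format DataFrame, one row per subject-visit.
    response
        Column holding the (log) exposure or per-visit risk score.
    group
        Subject identifier column.
    covariates
        Fixed-effect columns; default gestational week at sampling and
        specific gravity, both uncentered.
    """

    def __init__(self, data: pd.DataFrame, response: str,
                 group: str = "subject_id",
                 covariates=("gest_week", "sg")):
        self.data = data.dropna(subset=[response]).copy()
        self.response = response
        self.group = group
        self.covariates = list(covariates)
        if self.data[group].nunique() < 2:
            raise ValueError("need at least 2 subjects")
        if not np.all(np.isfinite(self.data[response].to_numpy(dtype=float))):
            raise ValueError("response contains non-finite values")

    def _exog(self) -> pd.DataFrame:
        x = self.data[self.covariates].astype(float) if self.covariates \
            else pd.DataFrame(index=self.data.index)
        return sm.add_constant(x, has_constant="add")

    def fit(self, reml: bool = True) -> RandomInterceptResults:
        exog = self._exog()
        endog = self.data[self.response].astype(float)
        groups = self.data[self.group]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(endog, exog, groups=groups)
                res = None
                for kwargs in ({"method": "bfgs", "gtol": 1e-10}, {},
                               {"method": "cg"}):
                    try:
                        res = model.fit(reml=reml, **kwargs)
                        if res.converged:
                            break
                    except Exception:
                        continue
                if res is None:
                    raise RuntimeError("all MixedLM optimizers failed")
            if not res.converged or not np.isfinite(res.scale):
                raise RuntimeError("MixedLM did not converge")
            var_b = float(res.cov_re.iloc[0, 0])
            var_e = float(res.scale)
            blups = pd.Series(
                {g: float(re_.iloc[0]) for g, re_ in res.random_effects.items()},
                name="blup")
            fe = res.fe_params
            method = "reml" if reml else "ml"
            converged = True
        except Exception as exc:  # noqa: BLE001 - fall back, keep diagnostics
            logger.warning(
                "mixed-model fit failed (%s); using method-of-moments "
                "fallback", exc)
            fe, var_b, var_e, blups = self._moments(exog, endog, groups)
            method = "moments"
            converged = False
        nvis = groups.value_counts().sort_index()
        nvis.index.name = self.group
        blups = blups.reindex(nvis.index)
        return RandomInterceptResults(
            fe_params=fe, var_between=max(var_b, 0.0), var_resid=var_e,
            blups=blups, n_visits=nvis, converged=converged, method=method)

    def _moments(self, exog, endog, groups):
        """One-way ANOVA variance components on fixed-effect residuals."""
        ols = sm.OLS(endog, exog).fit()
        resid = pd.Series(ols.resid, index=endog.index)
        g = groups
        n_i = g.value_counts()
        n_tot, n_grp = len(resid), len(n_i)
        grp_mean = resid.groupby(g).mean()
        ssw = float(((resid - grp_mean.reindex(g).to_numpy())**2).sum())
        var_e = ssw / max(n_tot - n_grp, 1)
        ssb = float((n_i * (grp_mean - resid.mean())**2).sum())
        msb = ssb / max(n_grp - 1, 1)
        n0 = (n_tot - float((n_i**2).sum()) / n_tot) / max(n_grp - 1, 1)
        var_b = max((msb - var_e) / n0, 0.0)
        shrink = var_b / (var_b + var_e / n_i)
        blups = (shrink * grp_mean).rename("blup")
        return ols.params, var_b, var_e, blups
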