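"""Summative phthalate risk scores: ERS and WQS with two selection routes.

Two subset-selection strategies tame the multicollinearity of the nine
metabolites before a score is built:

* correlation screen ("Corr") — metabolites whose pairwise correlation
  exceeds a threshold form a block; only the block member most strongly
  associated with the outcome (largest single-pollutant |z|) is kept;
* stepwise ("Stepwise") — bidirectional AIC stepwise selection on an
  IPW logistic model of preterm birth, adjustment covariates forced in.

On the selected subset two scores are built:

* ERS (environmental risk score) — a linear combination of the
  IQR-standardized exposure summaries weighted by the coefficients of one
  joint IPW logistic model of preterm birth;
* WQS (weighted quantile sum) — exposures are quantile-scored (quartiles by
  default) and the index ``sum_k w_k q_ik`` is fitted with nonnegative
  weights summing to one and a nonnegative index coefficient (direction of
  harm = higher odds of preterm birth), averaged over bootstrap resamples.

Both scores are IQR-standardized before use in outcome models; quartile
categorization uses design-weighted quantiles so cutpoints refer to the
source cohort, not the case-enriched sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .exposures import iqr_standardize
from .outcome import encode_covariates

__all__ = [
    "select_by_correlation",
    "select_stepwise",
    "ERSRegression",
    "ERSResults",
    "quantile_score",
    "WQSRegression",
    "WQSResults",
    "weighted_quantile",
    "quartile_categorize",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- selection

def select_by_correlation(corr: pd.DataFrame, assoc: pd.Series,
                          threshold: float = 0.5) -> list[str]:
    """Correlation-screened subset.

    Metabolites are grouped into blocks — connected components of the graph
    with an edge wherever |r| > threshold — and each block contributes only
    its member with the strongest outcome association (largest |assoc|,
    e.g. the single-pollutant Cox z-statistic). Singleton blocks are kept
    as-is, so the result always contains exactly one member per block.
    """
    names = list(corr.columns)
    parent = {m: m for m in names}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if abs(corr.loc[a, b]) > threshold:
                parent[find(a)] = find(b)
    blocks: dict[str, list[str]] = {}
    for m in names:
        blocks.setdefault(find(m), []).append(m)
    chosen = []
    for members in blocks.values():
        missing = [m for m in members if m not in assoc.index]
        if len(members) > 1 and missing:
            raise ValueError(
                f"association statistic missing for block members {missing}")
        best = max(members, key=lambda m: abs(assoc.get(m, 0.0)))
        chosen.append(best)
    return [m for m in names if m in chosen]


def _weighted_logit_fit(y, design, w):
    res = sm.GLM(y, design, family=sm.families.Binomial(),
                 freq_weights=w).fit()
    return res


def _weighted_logit_aic(y, design, w) -> float:
    res = _weighted_logit_fit(y, design, w)
    return float(2 * design.shape[1] - 2 * res.llf)


def select_stepwise(exposures: pd.DataFrame, e, z=None, weights=None) -> list[str]:
    """Bidirectional AIC-stepwise logistic selection of metabolites.

    The IPW logistic model of the preterm indicator always contains the
    adjustment covariates; metabolite columns are added/removed one at a
    time until no single move lowers the AIC. Deterministic given the input.
    Metabolites causing perfect separation or a singular fit are dropped
    with a warning.
    """
    y = np.asarray(e, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    zenc = encode_covariates(z) if z is not None else pd.DataFrame(
        index=exposures.index)

    def aic_for(cols):
        design = sm.add_constant(
            pd.concat([exposures[list(cols)], zenc], axis=1),
            has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return _weighted_logit_aic(y, design, w)

    candidates = list(exposures.columns)
    usable = []
    for m in candidates:
        try:
            aic_for([m])
            usable.append(m)
        except Exception:  # perfect separation / singular
            logger.warning("dropping %s from stepwise (unstable fit)", m)
    current: list[str] = []
    best = aic_for(current)
    while True:
        moves = []
        for m in usable:
            trial = current + [m] if m not in current \
                else [c for c in current if c != m]
            try:
                moves.append((aic_for(trial), trial))
            except Exception:
                continue
        moves.sort(key=lambda t: t[0])
        if not moves or moves[0][0] >= best - 1e-9:
            break
        best, current = moves[0][0], moves[0][1]
    return [m for m in candidates if m in current]


# --------------------------------------------------------------------- ERS

@dataclass
class ERSResults:
    """Fitted environmental risk score."""

    subset: list[str]
    weights: pd.Series          # logistic coefficients per metabolite
    scores: pd.Series           # RS_i = sum_k w_k x_ik
    scores_std: pd.Series       # RS_i / IQR(RS)
    iqr: float

    def summary(self) -> str:
        lines = [f"ERS on {len(self.subset)} metabolites "
                 f"(IQR = {self.iqr:.4f})"]
        for m, w in self.weights.items():
            lines.append(f"  {m:>9}: {w: .4f}")
        return "\n".join(lines)


class ERSRegression:
    """Environmental risk score from one joint IPW logistic model.

    The ERS weight of each selected metabolite is its coefficient in a single
    logistic model of preterm birth containing all selected metabolites and
    the adjustment covariates; a joint fit avoids double-counting correlated
    metabolites. The score is the weighted sum of the (IQR-standardized)
    exposure summaries, itself IQR-standardized afterwards.
    """

    def __init__(self, exposures: pd.DataFrame, e, z=None, weights=None):
        if exposures.shape[1] == 0:
            raise ValueError("empty metabolite subset")
        self.exposures = exposures
        self.e = np.asarray(e, dtype=float)
        self.z = z
        self.w = np.ones(len(self.e)) if weights is None \
            else np.asarray(weights, dtype=float)

    def fit(self, quantile_method: str = "linear") -> ERSResults:
        design = sm.add_constant(
            pd.concat([self.exposures,
                       encode_covariates(self.z) if self.z is not None
                       else pd.DataFrame(index=self.exposures.index)], axis=1),
            has_constant="add")
        arr = design.to_numpy(dtype=float)
        if np.linalg.matrix_rank(arr) < arr.shape[1]:
            raise ValueError("rank-deficient design (collinear exposures)")
        res = _weighted_logit_fit(self.e, design, self.w)
        if not res.converged:
            raise RuntimeError("ERS logistic fit did not converge")
        coefs = res.params[list(self.exposures.columns)]
        scores = compute_ers(self.exposures, coefs)
        scores_std, iqr = iqr_standardize(scores, quantile_method)
        return ERSResults(subset=list(self.exposures.columns),
                          weights=coefs, scores=scores,
                          scores_std=scores_std, iqr=iqr)


def compute_ers(exposures: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Linear combination RS_i = sum_k w_k x_ik (weights aligned by name)."""
    aligned = weights.reindex(exposures.columns)
    if aligned.isna().any():
        raise ValueError("weights not aligned with exposure columns")
    return pd.Series(exposures.to_numpy(dtype=float) @ aligned.to_numpy(),
                     index=exposures.index, name="ers")


# --------------------------------------------------------------------- WQS

def quantile_score(values, q: int = 4) -> np.ndarray:
    """Quantile-score a continuous exposure into integers 0..q-1.

    Cutpoints sit at the sample quantiles i/q (linear interpolation); a value
    exactly at a cutpoint falls in the lower category. Rank statistics only —
    invariant to monotone transforms of the input.
    """
    arr = np.asarray(values, dtype=float)
    if len(np.unique(arr)) < q:
        raise ValueError(f"need at least {q} distinct values")
    cuts = np.quantile(arr, [i / q for i in range(1, q)])
    return (arr[:, None] > cuts[None, :]).sum(axis=1)


@dataclass
class WQSResults:
    """Fitted weighted quantile sum index."""

    subset: list[str]
    weights: pd.Series           # nonnegative, sum to 1
    beta1: float                 # index coefficient, refit on full data
    beta1_se: float
    index: pd.Series             # WQS_i = sum_k w_k q_ik
    index_std: pd.Series
    iqr: float
    q: int
    n_bootstrap: int
    n_converged: int
    n_positive: int
    bootstrap_weights: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            f"WQS on {len(self.subset)} metabolites, q={self.q}, "
            f"B={self.n_bootstrap} ({self.n_positive} positive-direction "
            f"bootstraps averaged)",
            f"  beta1 = {self.beta1:.4f} (SE {self.beta1_se:.4f}), "
            f"index IQR = {self.iqr:.4f}",
        ]
        for m, w in self.weights.items():
            lines.append(f"  {m:>9}: {w: .4f}")
        return "\n".join(lines)


class WQSRegression:
    """Weighted quantile sum regression with bootstrap-averaged weights.

    Exposure summaries are quantile-scored into 0..q-1; on each bootstrap
    resample the IPW logistic likelihood of the preterm indicator on
    ``beta0 + beta1 * sum_k w_k q_ik + Z phi`` is maximized subject to
    ``w_k >= 0``, ``sum w = 1`` and ``beta1 >= 0`` (harm direction = higher
    preterm odds). Final weights average the bootstraps with ``beta1 > 0``
    that converged (all converged bootstraps, with a warning, if none); the
    index coefficient is then re-estimated on the full data with the weights
    frozen. No training/validation split is used by default — at nested
    case-control sample sizes a split costs more precision than the
    overfitting it prevents.
    """

    def __init__(self, exposures: pd.DataFrame, e, z=None, weights=None,
                 q: int = 4, n_bootstrap: int = 100, seed: int | None = None):
        if exposures.shape[1] < 2:
            raise ValueError("WQS needs at least 2 metabolites")
        if n_bootstrap < 2:
            raise ValueError("need at least 2 bootstrap resamples")
        self.exposures = exposures
        self.e = np.asarray(e, dtype=float)
        self.z = z
        self.w = np.ones(len(self.e)) if weights is None \
            else np.asarray(weights, dtype=float)
        self.q = q
        self.B = n_bootstrap
        self.seed = seed

    # -- constrained ML for one sample ------------------------------------
    @staticmethod
    def _fit_constrained(qmat, y, zmat, w):
        """Maximize the weighted logistic likelihood under WQS constraints.

        Returns (beta1, weights, converged).
        """
        n, m = qmat.shape
        p_z = zmat.shape[1]

        def unpack(theta):
            b0, b1 = theta[0], theta[1]
            wts = theta[2:2 + m]
            phi = theta[2 + m:]
            return b0, b1, wts, phi

        def negll(theta):
            b0, b1, wts, phi = unpack(theta)
            eta = b0 + b1 * (qmat @ wts) + (zmat @ phi if p_z else 0.0)
            # numerically stable -loglik
            return float(np.sum(w * (np.logaddexp(0.0, eta) - y * eta)))

        ybar = np.clip(np.average(y, weights=w), 1e-3, 1 - 1e-3)
        x0 = np.concatenate([
            [np.log(ybar / (1 - ybar)), 0.1], np.full(m, 1.0 / m),
            np.zeros(p_z)])
        bounds = [(None, None), (0.0, None)] + [(0.0, 1.0)] * m \
            + [(None, None)] * p_z
        cons = [{"type": "eq",
                 "fun": lambda th: np.sum(th[2:2 + m]) - 1.0}]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = optimize.minimize(
                negll, x0, method="SLSQP", bounds=bounds, constraints=cons,
                options={"maxiter": 200, "ftol": 1e-9})
        b0, b1, wts, phi = unpack(sol.x)
        wts = np.clip(wts, 0.0, None)
        s = wts.sum()
        ok = sol.success and s > 0 and abs(s - 1.0) < 1e-4
        return float(b1), (wts / s if s > 0 else wts), bool(ok)

    def fit(self, quantile_method: str = "linear") -> WQSResults:
        cols = list(self.exposures.columns)
        qmat = np.column_stack([
            quantile_score(self.exposures[c], self.q) for c in cols
        ]).astype(float)
        zenc = encode_covariates(self.z) if self.z is not None \
            else pd.DataFrame(index=self.exposures.index)
        zmat = zenc.to_numpy(dtype=float) if zenc.shape[1] else \
            np.empty((len(qmat), 0))
        rng = np.random.default_rng(self.seed)
        n = len(qmat)
        boot_w, boot_b1, boot_ok = [], [], []
        for _ in range(self.B):
            idx = rng.integers(0, n, size=n)
            b1, wts, ok = self._fit_constrained(
                qmat[idx], self.e[idx], zmat[idx], self.w[idx])
            boot_b1.append(b1)
            boot_w.append(wts)
            boot_ok.append(ok)
        boot_w = np.asarray(boot_w)
        boot_b1 = np.asarray(boot_b1)
        boot_ok = np.asarray(boot_ok)
        if boot_ok.sum() < self.B / 2:
            raise RuntimeError(
                f"WQS optimizer failed on {self.B - int(boot_ok.sum())} of "
                f"{self.B} bootstraps")
        use = boot_ok & (boot_b1 > 0)
        if not use.any():
            logger.warning(
                "no bootstrap gave beta1 > 0; averaging all converged "
                "bootstraps")
            use = boot_ok
        wbar = boot_w[use].mean(axis=0)
        wbar = wbar / wbar.sum()
        index = pd.Series(qmat @ wbar, index=self.exposures.index, name="wqs")
        # refit beta1 on the full data with weights frozen
        design = sm.add_constant(
            pd.concat([index.rename("wqs_index"), zenc], axis=1),
            has_constant="add")
        res = _weighted_logit_fit(self.e, design, self.w)
        beta1 = float(res.params["wqs_index"])
        beta1_se = float(res.bse["wqs_index"])
        index_std, iqr = iqr_standardize(index, quantile_method)
        return WQSResults(
            subset=cols, weights=pd.Series(wbar, index=cols),
            beta1=beta1, beta1_se=beta1_se, index=index,
            index_std=index_std, iqr=iqr, q=self.q, n_bootstrap=self.B,
            n_converged=int(boot_ok.sum()), n_positive=int(use.sum()),
            bootstrap_weights=boot_w)


# --------------------------------------------------------------- quartiles

def weighted_quantile(values, probs, sample_weights) -> np.ndarray:
    """Design-weighted quantiles (expanded-sample semantics).

    For integer weights this equals numpy's linear-interpolation quantile on
    the sample with each observation repeated ``weight`` times.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(sample_weights, dtype=float)
    order = np.argsort(x, kind="mergesort")
    x, w = x[order], w[order]
    cw = np.cumsum(w)
    total = cw[-1]

    def at(i):
        # value at 0-based position i of the weight-expanded sorted sample
        j = np.searchsorted(cw, i, side="right")
        return x[min(j, len(x) - 1)]

    out = []
    for p in np.atleast_1d(probs):
        h = p * (total - 1)          # linear-interpolation position
        lo = np.floor(h)
        frac = h - lo
        out.append((1 - frac) * at(lo) + frac * at(lo + 1))
    return np.asarray(out)


def quartile_categorize(scores, sample_weights=None):
    """Categorize a risk score into design-weighted quartiles Q1..Q4.

    Cutpoints are the weighted 25/50/75th percentiles (Q1, the lowest, is
    the reference category downstream). Returns integer categories 1..4 and
    the three cutpoints. Ties at a cutpoint fall in the lower category.
    """
    x = np.asarray(scores, dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct score values")
    w = np.ones(len(x)) if sample_weights is None \
        else np.asarray(sample_weights, dtype=float)
    cuts = weighted_quantile(x, [0.25, 0.5, 0.75], w)
    if not (cuts[0] < cuts[1] < cuts[2]):
        raise ValueError("degenerate quartile cutpoints")
    cats = 1 + (x[:, None] > cuts[None, :]).sum(axis=1)
    if isinstance(scores, pd.Series):
        cats = pd.Series(cats, index=scores.index, name="quartile")
    return cats, cuts
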