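"""Synthetic pregnancy-cohort generator.

Emulates the data structure of a prospective birth cohort with up to four
prenatal urine-collection visits: nine urinary phthalate metabolite
concentrations per visit (right-skewed, with a strongly correlated DEHP
block), urinary specific gravity, gestational age at delivery (left-skewed,
~11% preterm), visit attrition driven by early delivery, assay detection
limits, and a nested case-control subsample with inverse-probability design
weights.

The generative model for log concentrations is a classical variance-components
decomposition

    log X_ijk = b_ik + lambda * (SG_ij - sg_center) + e_ijk

with subject-level intercepts ``b_i ~ MVN(mu_log, cov_log)`` shared across
visits, a urinary-dilution term proportional to specific gravity, and
visit-level noise ``e_ij`` whose per-metabolite variance is chosen so that the
intraclass correlation of observed log concentrations equals the configured
``icc`` (the dilution variance is folded into the within-subject budget).
The dilution term is linear in SG so that regression models that adjust for
SG as a covariate — the recommended practice, since regressing on
dilution-corrected concentrations can bias estimates — see exactly the
generative signal.

Two delivery-time modes are provided:

* ``aft_lognormal`` — log gestational age is a normal linear model in the
  subject's mean log exposure over the first three visits plus covariates.
  This is the exact generative counterpart of the lognormal accelerated
  failure time analysis model and is the ground truth for parameter-recovery
  checks.
* ``term_preterm_mixture`` (default) — a two-component normal mixture of a
  term component and an early-delivery component, which reproduces the heavy
  left skew and the ~11% preterm fraction seen in real cohorts. Exposure acts
  on the log-odds of membership in the early component.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "METABOLITES",
    "DEHP_METABOLITES",
    "MOLAR_MASS_G_MOL",
    "PRETERM_CUTOFF_DAYS",
    "SimTruth",
    "default_truth",
    "generate_full_cohort",
    "apply_visit_attrition",
    "censor_at_lod",
    "sample_nested_case_control",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

#: The nine urinary phthalate metabolites measured at every visit.
METABOLITES = [
    "MEHP", "MEHHP", "MEOHP", "MECPP", "MBzP", "MBP", "MiBP", "MEP", "MCPP",
]

#: Oxidative metabolites of di(2-ethylhexyl) phthalate summed into the molar
#: DEHP index.
DEHP_METABOLITES = ["MEHP", "MEHHP", "MEOHP", "MECPP"]

#: Molecular weights (g/mol) used for the nmol/L molar sum.
MOLAR_MASS_G_MOL = {
    "MEHP": 278.34,
    "MEHHP": 294.34,
    "MEOHP": 292.33,
    "MECPP": 308.33,
}

#: Preterm birth = delivery before 37 completed weeks, encoded as exactly
#: 259 days.
PRETERM_CUTOFF_DAYS = 259

RACE_LEVELS = ["white", "black", "other"]
EDUCATION_LEVELS = ["high_school", "some_college", "college_plus"]


def _default_correlation() -> np.ndarray:
    """Between-subject correlation of log concentrations.

    The four DEHP metabolites share a common parent compound and are strongly
    correlated (r = 0.85); the dibutyl metabolites MBP/MiBP are moderately
    correlated; MEP (personal-care-product source) is only weakly related to
    the rest.
    """
    k = len(METABOLITES)
    r = np.full((k, k), 0.25)
    idx = {m: i for i, m in enumerate(METABOLITES)}
    for a in DEHP_METABOLITES:
        for b in DEHP_METABOLITES:
            r[idx[a], idx[b]] = 0.85
    r[idx["MBP"], idx["MiBP"]] = r[idx["MiBP"], idx["MBP"]] = 0.45
    for m in METABOLITES:
        r[idx["MEP"], idx[m]] = r[idx[m], idx["MEP"]] = 0.15
    np.fill_diagonal(r, 1.0)
    return r


@dataclass
class SimTruth:
    """Full parameterization of the synthetic cohort.

    Parameters
    ----------
    n_subjects
        Number of pregnancies followed to a live singleton delivery.
    metabolite_names
        Labels for the measured analytes (length K).
    mu_log
        Per-metabolite means of the subject-level log concentrations
        (log µg/L).
    cov_log
        K x K between-subject covariance of log concentrations (symmetric
        positive semi-definite).
    icc
        Per-metabolite intraclass correlation of observed log concentrations,
        strictly inside (0, 1). Within-visit variance is derived as
        ``diag(cov_log) * (1 - icc) / icc`` minus the dilution variance.
    visit_weeks, visit_jitter
        Median gestational week of each visit and the half-width of the
        uniform jitter around it; must be strictly increasing.
    sg_center, sg_spread
        Median and SD of urinary specific gravity (truncated normal > 1).
    dilution_slope
        Slope of log concentration on (SG - sg_center); shared by all
        metabolites.
    outcome_mode
        ``"aft_lognormal"`` or ``"term_preterm_mixture"`` (see module
        docstring).
    gamma_true
        Per-metabolite exposure coefficients, per unit log concentration: in
        ``aft_lognormal`` mode these multiply mean log exposure in the linear
        predictor of log T; in ``term_preterm_mixture`` mode they act on the
        log-odds of early delivery. The defaults are mixture-mode log-odds
        with the strongest effect on MECPP; set explicit (much smaller)
        values when using aft_lognormal.
    covariate_effects
        Mapping of covariate terms to coefficients on the same linear
        predictor as ``gamma_true``.
    sigma_log_T
        Residual SD of log gestational age (aft_lognormal mode).
    lod
        Per-metabolite assay detection limit in µg/L, or None to disable
        detection-limit censoring.
    missing_rate_by_visit
        Probability that each of visits 2..4 is missing at random (element 0,
        for visit 1, must be zero — visit 1 defines cohort entry).
    """

    n_subjects: int = 1181
    metabolite_names: list[str] = field(default_factory=lambda: list(METABOLITES))
    mu_log: np.ndarray = field(default_factory=lambda: np.log(
        np.array([4.0, 18.0, 13.0, 30.0, 7.0, 16.0, 7.0, 120.0, 2.5])))
    cov_log: np.ndarray | None = None
    icc: np.ndarray = field(default_factory=lambda: np.array(
        [0.21, 0.20, 0.20, 0.26, 0.34, 0.42, 0.48, 0.61, 0.19]))
    total_var_log: np.ndarray = field(default_factory=lambda: np.full(9, 1.21))
    visit_weeks: tuple = (9.71, 17.9, 26.0, 35.1)
    visit_jitter: tuple = (2.5, 2.0, 1.6, 1.6)
    sg_center: float = 1.015
    sg_spread: float = 0.0055
    dilution_slope: float = 55.0
    outcome_mode: str = "term_preterm_mixture"
    gamma_true: np.ndarray = field(default_factory=lambda: np.array(
        [0.20, 0.10, 0.10, 0.40, 0.15, 0.20, 0.0, 0.0, 0.10]))
    covariate_effects: dict = field(default_factory=dict)
    sigma_log_T: float = 0.045
    aft_intercept: float = float(np.log(274.0))
    term_mean_days: float = 277.0
    term_sd_days: float = 8.5
    early_mean_days: float = 246.0
    early_sd_days: float = 12.0
    # baseline early-component membership; with the default exposure effects
    # the marginal preterm fraction lands at ~0.11 (the 130/1181 design)
    p_early: float = 0.095
    lod: np.ndarray | None = None
    lod_target_fraction: np.ndarray | None = field(default_factory=lambda: np.array(
        [0.047, 0.01, 0.01, 0.005, 0.01, 0.005, 0.005, 0.002, 0.02]))
    missing_rate_by_visit: tuple = (0.0, 0.10, 0.12, 0.10)
    seed: int = 0

    def __post_init__(self):
        k = len(self.metabolite_names)
        self.mu_log = np.asarray(self.mu_log, dtype=float)
        self.icc = np.asarray(self.icc, dtype=float)
        self.total_var_log = np.asarray(self.total_var_log, dtype=float)
        self.gamma_true = np.asarray(self.gamma_true, dtype=float)
        if self.cov_log is None:
            sd_b = np.sqrt(self.icc * self.total_var_log)
            self.cov_log = _default_correlation() * np.outer(sd_b, sd_b)
        self.cov_log = np.asarray(self.cov_log, dtype=float)
        if self.cov_log.shape != (k, k):
            raise ValueError("cov_log must be K x K")
        if not np.allclose(self.cov_log, self.cov_log.T):
            raise ValueError("cov_log must be symmetric")
        eig = np.linalg.eigvalsh(self.cov_log)
        if eig.min() < -1e-10:
            raise ValueError("cov_log must be positive semi-definite")
        if np.any(self.icc <= 0) or np.any(self.icc >= 1):
            raise ValueError("icc must lie strictly in (0, 1)")
        if np.any(np.diff(self.visit_weeks) <= 0):
            raise ValueError("visit_weeks must be strictly increasing")
        if self.sg_center <= 1:
            raise ValueError("sg_center must exceed 1")
        if self.missing_rate_by_visit[0] != 0:
            raise ValueError("visit 1 cannot be missing at random")
        if self.outcome_mode not in ("aft_lognormal", "term_preterm_mixture"):
            raise ValueError(f"unknown outcome_mode {self.outcome_mode!r}")
        # total variance of observed log conc is fixed at total_var_log:
        # between + within + dilution.
        between = np.diag(self.cov_log)
        dil = self.dilution_slope**2 * self.sg_spread**2
        self._within_var = self.total_var_log - between - dil
        if np.any(self._within_var <= 0):
            raise ValueError(
                "within-visit variance non-positive; increase total_var_log "
                "or reduce dilution_slope/sg_spread")
        if self.lod is None and self.lod_target_fraction is not None:
            z = stats.norm.ppf(np.asarray(self.lod_target_fraction, dtype=float))
            self.lod = np.exp(self.mu_log + z * np.sqrt(self.total_var_log))

    def to_json(self) -> str:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, tuple):
                v = list(v)
            d[f.name] = v
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d and not f.name.startswith("_"):
                v = d[f.name]
                if f.name in ("mu_log", "cov_log", "icc", "total_var_log",
                              "gamma_true", "lod", "lod_target_fraction"):
                    v = None if v is None else np.asarray(v, dtype=float)
                elif f.name in ("visit_weeks", "visit_jitter",
                                "missing_rate_by_visit"):
                    v = tuple(v)
                kwargs[f.name] = v
        return cls(**kwargs)


def default_truth(**overrides) -> SimTruth:
    """A SimTruth with the package's default study conditions.

    Defaults give a left-skewed gestational-age distribution with ~11%
    preterm deliveries, a DEHP block with pairwise correlation > 0.5,
    per-metabolite ICC between 0.19 and 0.61, and a ~4.7% non-detect
    fraction for MEHP.
    """
    return SimTruth(**overrides)


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    race = rng.choice(RACE_LEVELS, size=n, p=[0.72, 0.13, 0.15])
    edu = rng.choice(EDUCATION_LEVELS, size=n, p=[0.164, 0.35, 0.486])
    age = np.clip(rng.normal(32.2, 4.6, size=n), 18, 45)
    insurance = (rng.random(n) < 0.799).astype(int)  # 1 = private
    return pd.DataFrame({
        "race": race, "education": edu,
        "maternal_age": age, "insurance_private": insurance,
    })


def _covariate_linpred(z: pd.DataFrame, effects: dict) -> np.ndarray:
    """Linear predictor contribution of covariates.

    Recognised keys: ``race:<level>``, ``education:<level>``,
    ``maternal_age`` (centred at 32 years), ``insurance_private``.
    """
    lp = np.zeros(len(z))
    for key, coef in effects.items():
        if key == "maternal_age":
            lp += coef * (z["maternal_age"].to_numpy() - 32.0)
        elif key == "insurance_private":
            lp += coef * z["insurance_private"].to_numpy()
        elif ":" in key:
            col, level = key.split(":", 1)
            lp += coef * (z[col] == level).to_numpy(dtype=float)
        else:
            raise KeyError(f"unknown covariate effect {key!r}")
    return lp


def generate_full_cohort(truth: SimTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the full cohort before attrition / LOD censoring / sampling.

    Returns
    -------
    subjects : DataFrame
        One row per subject: ``subject_id``, ``T_days`` (gestational age at
        delivery), ``preterm``, covariates, and ``sampled``/``weight``
        placeholders.
    visits : DataFrame
        One row per subject-visit (all four scheduled visits, including any
        that fall after delivery — remove those with
        :func:`apply_visit_attrition`): ``subject_id``, ``visit``,
        ``gest_week``, ``sg``, one concentration column per metabolite (µg/L)
        and one ``det_<metabolite>`` detection flag (all True here).
    """
    rng = np.random.default_rng(truth.seed)
    n, k = truth.n_subjects, len(truth.metabolite_names)
    n_visits = len(truth.visit_weeks)

    # subject-level true log concentrations
    chol_b = np.linalg.cholesky(
        truth.cov_log + 1e-12 * np.eye(k))
    b = truth.mu_log + rng.standard_normal((n, k)) @ chol_b.T

    # visit schedule and specific gravity
    weeks = (np.asarray(truth.visit_weeks)
             + rng.uniform(-1, 1, size=(n, n_visits)) * np.asarray(truth.visit_jitter))
    sg = rng.normal(truth.sg_center, truth.sg_spread, size=(n, n_visits))
    sg = np.clip(sg, 1.002, 1.035)

    # within-visit noise: same correlation structure as the between-subject
    # covariance (shared sources of short-term variation), scaled to the
    # per-metabolite within variance.
    corr = truth.cov_log / np.sqrt(
        np.outer(np.diag(truth.cov_log), np.diag(truth.cov_log)))
    sd_w = np.sqrt(truth._within_var)
    cov_w = corr * np.outer(sd_w, sd_w)
    chol_w = np.linalg.cholesky(cov_w + 1e-12 * np.eye(k))
    eps = rng.standard_normal((n, n_visits, k)) @ chol_w.T

    log_true = b[:, None, :] + eps                     # pre-dilution signal
    xbar_true = log_true[:, :3, :].mean(axis=1)        # visits 1-3 mean

    z = _draw_covariates(rng, n)
    z_lp = _covariate_linpred(z, truth.covariate_effects)

    if truth.outcome_mode == "aft_lognormal":
        lp = (truth.aft_intercept
              + (xbar_true - truth.mu_log) @ truth.gamma_true + z_lp)
        t_days = np.exp(lp + truth.sigma_log_T * rng.standard_normal(n))
    else:
        logit0 = np.log(truth.p_early / (1 - truth.p_early))
        eta = logit0 + (xbar_true - truth.mu_log) @ truth.gamma_true + z_lp
        p = 1.0 / (1.0 + np.exp(-eta))
        early = rng.random(n) < p
        t_days = np.where(
            early,
            rng.normal(truth.early_mean_days, truth.early_sd_days, n),
            rng.normal(truth.term_mean_days, truth.term_sd_days, n))
        t_days = np.clip(t_days, 150.0, 300.0)

    subjects = pd.DataFrame({
        "subject_id": np.arange(1, n + 1),
        "T_days": t_days,
        "preterm": (t_days < PRETERM_CUTOFF_DAYS).astype(int),
    })
    subjects = pd.concat([subjects, z], axis=1)
    subjects["sampled"] = False
    subjects["weight"] = np.nan

    # observed concentrations include the dilution term
    log_obs = log_true + truth.dilution_slope * (
        sg[:, :, None] - truth.sg_center)
    conc = np.exp(log_obs)

    rows = {
        "subject_id": np.repeat(subjects["subject_id"].to_numpy(), n_visits),
        "visit": np.tile(np.arange(1, n_visits + 1), n),
        "gest_week": weeks.ravel(),
        "sg": sg.ravel(),
    }
    visits = pd.DataFrame(rows)
    for j, m in enumerate(truth.metabolite_names):
        visits[m] = conc[:, :, j].ravel()
        visits[f"det_{m}"] = True
    return subjects, visits


def apply_visit_attrition(
    visits: pd.DataFrame,
    subjects: pd.DataFrame,
    missing_rate_by_visit=(0.0, 0.0, 0.0, 0.0),
    seed: int | None = None,
) -> pd.DataFrame:
    """Drop visits at/after delivery, then visits missing at random.

    A sample cannot be collected once the subject has delivered: every visit
    with ``gest_week * 7 >= T_days`` is removed. Additional visits (never
    visit 1) are removed independently at the configured per-visit rates.
    """
    rates = np.asarray(missing_rate_by_visit, dtype=float)
    if rates[0] != 0:
        raise ValueError("visit 1 cannot be missing at random")
    rng = np.random.default_rng(seed)
    t = subjects.set_index("subject_id")["T_days"]
    delivered = visits["gest_week"].to_numpy() * 7.0 >= \
        t.reindex(visits["subject_id"]).to_numpy()
    keep = ~delivered
    vis_idx = visits["visit"].to_numpy() - 1
    rand_miss = rng.random(len(visits)) < rates[vis_idx]
    keep &= ~rand_miss
    return visits.loc[keep].reset_index(drop=True)


def censor_at_lod(visits: pd.DataFrame, lod, metabolites=None) -> pd.DataFrame:
    """Apply assay detection limits.

    Concentrations strictly below the LOD are flagged as non-detects and
    stored at the LOD value (a value exactly at the LOD counts as detected);
    the LOD/sqrt(2) substitution happens later, in exposure processing.
    """
    metabolites = list(metabolites or METABOLITES)
    lod = np.asarray(lod, dtype=float)
    if np.any(lod <= 0):
        raise ValueError("lod must be positive")
    out = visits.copy()
    for j, m in enumerate(metabolites):
        below = out[m].to_numpy() < lod[j]
        out[f"det_{m}"] = ~below
        out.loc[below, m] = lod[j]
    return out


def sample_nested_case_control(
    subjects: pd.DataFrame,
    visits: pd.DataFrame,
    n_controls: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw the nested case-control sample and attach design weights.

    All preterm cases are sampled with weight 1. Controls are drawn uniformly
    without replacement from non-cases who have a visit-1 sample and at least
    one later visit; each sampled control carries the design weight
    (number of eligible non-cases) / n_controls, so the weighted sample
    represents cases plus the eligible control pool.
    """
    rng = np.random.default_rng(seed)
    out = subjects.copy()
    has_v1 = set(visits.loc[visits["visit"] == 1, "subject_id"])
    later = visits.loc[visits["visit"] > 1, "subject_id"]
    has_later = set(later)
    eligible = out["subject_id"].map(
        lambda s: (s in has_v1) and (s in has_later))
    is_case = out["preterm"] == 1
    pool = out.loc[~is_case & eligible, "subject_id"].to_numpy()
    if n_controls > len(pool):
        raise ValueError(
            f"n_controls={n_controls} exceeds eligible pool of {len(pool)}")
    chosen = rng.choice(pool, size=n_controls, replace=False)
    out["sampled"] = False
    out.loc[is_case, "sampled"] = True
    out.loc[out["subject_id"].isin(chosen), "sampled"] = True
    out["weight"] = np.nan
    out.loc[is_case, "weight"] = 1.0
    out.loc[out["subject_id"].isin(chosen), "weight"] = len(pool) / n_controls
    return out


def simulate_cohort(
    truth: SimTruth,
    n_controls: int | None = None,
    attrition: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full generation pipeline: cohort, attrition, LOD censoring, sampling.

    ``n_controls`` defaults to sampling controls at ~2.7 per case (the design
    ratio 352/130) capped by the eligible pool; pass 0 to skip case-control
    sampling (the whole cohort is then flagged sampled with weight 1).
    """
    ss = np.random.SeedSequence(truth.seed)
    s_attr, s_cc = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)]
    subjects, visits = generate_full_cohort(truth)
    if attrition:
        visits = apply_visit_attrition(
            visits, subjects, truth.missing_rate_by_visit, seed=s_attr)
    else:
        visits = apply_visit_attrition(visits, subjects, seed=s_attr)
    if truth.lod is not None:
        visits = censor_at_lod(visits, truth.lod, truth.metabolite_names)
    if n_controls == 0:
        subjects["sampled"] = True
        subjects["weight"] = 1.0
        return subjects, visits
    if n_controls is None:
        n_cases = int(subjects["preterm"].sum())
        want = round(n_cases * 352 / 130)
        has_v1 = set(visits.loc[visits["visit"] == 1, "subject_id"])
        has_later = set(visits.loc[visits["visit"] > 1, "subject_id"])
        pool = subjects.loc[
            (subjects["preterm"] == 0)
            & subjects["subject_id"].isin(has_v1)
            & subjects["subject_id"].isin(has_later)]
        n_controls = min(want, len(pool))
    subjects = sample_nested_case_control(subjects, visits, n_controls, seed=s_cc)
    return subjects, visits


def write_cohort(outdir, subjects: pd.DataFrame, visits: pd.DataFrame,
                 truth: SimTruth | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects.to_csv(outdir / "cohort_subjects.csv", index=False)
    visits.to_csv(outdir / "cohort_visits.csv", index=False)
    if truth is not None:
        (outdir / "simtruth.json").write_text(truth.to_json())


def read_cohort(outdir) -> tuple[pd.DataFrame, pd.DataFrame]:
    outdir = Path(outdir)
    subjects = pd.read_csv(outdir / "cohort_subjects.csv")
    visits = pd.read_csv(outdir / "cohort_visits.csv")
    return subjects, visits
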