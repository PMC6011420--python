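"""End-to-end orchestration of the two analysis arms.

The average-exposure arm summarizes each exposure as the mean of its
log-transformed concentrations over the first three visits; the
repeated-measures arm summarizes it as the IQR-standardized BLUP of a
random-intercept mixed model fitted to all available visits. Each summary is
carried through single-pollutant models (nine metabolites plus the molar
DEHP sum) and through four summative risk scores (ERS/WQS crossed with
correlation-screen/stepwise selection; WQS only in the average arm, since the
stage-1 mixed model needs a continuous response and the quantile-scored WQS
is inherently discrete).

Exposure summaries are computed before any outcome model is touched, and the
descriptive correlation table uses SG-corrected concentrations while every
regression uses raw concentrations with specific gravity as a covariate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (DEHP_METABOLITES, METABOLITES, SimTruth, default_truth,
                     read_cohort, simulate_cohort, write_cohort)
from .exposures import (build_average_exposures, iqr_standardize,
                        molar_sum_dehp, sg_correct, substitute_nondetects)
from .longitudinal import RandomIntercept
from .outcome import (fit_aft_lognormal, fit_cox, fit_logistic,
                      fit_quartile_models)
from .scores import (ERSRegression, WQSRegression, quartile_categorize,
                     select_by_correlation, select_stepwise)

__all__ = [
    "AnalysisConfig", "ConfigError", "run_average_analysis",
    "run_repeated_analysis", "make_report", "run_pipeline", "descriptives",
]

logger = logging.getLogger(__name__)

#: Exposures whose single-pollutant models additionally adjust for health
#: insurance (all risk-score models adjust for it as well).
INSURANCE_ADJUSTED = {"MBzP", "MBP", "MiBP", "MEP", "MCPP"}

BASE_COVARIATES = ["maternal_age", "race", "education"]


class ConfigError(ValueError):
    """Invalid analysis configuration."""


@dataclass
class AnalysisConfig:
    """Configuration for one pipeline run."""

    arm: str = "average"                     # "average" | "repeated"
    exposures: list[str] = field(
        default_factory=lambda: list(METABOLITES) + ["sum_dehp"])
    scores: list[str] = field(default_factory=lambda: [
        "ers_corr", "ers_stepwise", "wqs_corr", "wqs_stepwise"])
    q: int = 4
    n_bootstrap: int = 100
    corr_threshold: float = 0.5
    seed: int = 0
    visit_set: tuple = (1, 2, 3)
    quantile_method: str = "linear"

    def validate(self, available_metabolites) -> None:
        if self.arm not in ("average", "repeated"):
            raise ConfigError(f"unknown analysis arm {self.arm!r}")
        known = set(available_metabolites) | {"sum_dehp"}
        bad = [m for m in self.exposures if m not in known]
        if bad:
            raise ConfigError(f"unknown exposures {bad}")
        if self.arm == "repeated" and any(s.startswith("wqs") for s in self.scores):
            raise ConfigError(
                "WQS is not available in the repeated-measures arm: the "
                "stage-1 linear mixed model needs a continuous response and "
                "the weighted quantile sum is inherently discrete")
        if self.seed is None and any(s.startswith("wqs") for s in self.scores):
            raise ConfigError("WQS requires a seed")


def _covariates_for(subjects: pd.DataFrame, exposure: str,
                    avg_sg: pd.Series | None, is_score: bool) -> pd.DataFrame:
    cols = subjects[BASE_COVARIATES + ["insurance_private"]].copy()
    if not is_score and exposure not in INSURANCE_ADJUSTED:
        cols = cols.drop(columns="insurance_private")
    if avg_sg is not None:
        cols.insert(0, "avg_sg", avg_sg)
    return cols


def _three_models(x_std, subj, z, w, label):
    return [
        fit_logistic(x_std, subj["preterm"].to_numpy(), z, w, label=label),
        fit_cox(x_std, subj["T_days"].to_numpy(), z, w, label=label),
        fit_aft_lognormal(x_std, subj["T_days"].to_numpy(), z, w, label=label),
    ]


def _score_models(score_std, quartiles, subj, z, w, label):
    ests = _three_models(score_std, subj, z, w, label)
    ests += fit_quartile_models(
        quartiles, subj["preterm"].to_numpy(), subj["T_days"].to_numpy(),
        z, w, label=label)
    return ests


def _analysis_frame(subjects: pd.DataFrame, exposures: pd.DataFrame):
    """Align sampled subjects with their exposure summaries."""
    subj = subjects[subjects["sampled"]].set_index("subject_id")
    subj = subj.join(exposures, how="inner")
    w = subj["weight"].to_numpy(dtype=float)
    return subj, w


def _corr_matrix_sg_corrected(visits: pd.DataFrame, metabolites,
                              visit_set=(1, 2, 3)) -> pd.DataFrame:
    """Descriptive Pearson correlation of mean log SG-corrected exposures."""
    work = visits.copy()
    for m in metabolites:
        det = work.get(f"det_{m}")
        if det is not None:
            work[m] = substitute_nondetects(work[m], det, work[m])
        work[m] = sg_correct(work[m], work["sg"])
    sub = work[work["visit"].isin(list(visit_set))]
    means = np.log(sub[list(metabolites)]).groupby(sub["subject_id"]).mean()
    return means.corr()


def run_average_analysis(subjects: pd.DataFrame, visits: pd.DataFrame,
                         config: AnalysisConfig):
    """Average-exposure arm: single-pollutant models plus four risk scores.

    Returns ``(effects DataFrame, artifacts dict)``.
    """
    config.validate(METABOLITES)
    exposures = build_average_exposures(
        visits, METABOLITES, visit_set=config.visit_set)
    subj, w = _analysis_frame(subjects, exposures)
    avg_sg = subj["avg_sg"]

    effects, iqrs, failures = [], {}, {}
    std_cols = {}
    # every metabolite is standardized (risk scores may draw on all nine);
    # single-pollutant models run only for the configured exposures
    for m in dict.fromkeys(list(METABOLITES) + list(config.exposures)):
        x_std, iqr = iqr_standardize(subj[m], config.quantile_method)
        std_cols[m] = x_std
        iqrs[m] = iqr
        if m not in config.exposures:
            continue
        z = _covariates_for(subj, m, avg_sg, is_score=False)
        try:
            effects.extend(_three_models(x_std, subj, z, w, label=m))
        except Exception as exc:  # keep the run going, log the exposure
            logger.error("single-pollutant models failed for %s: %s", m, exc)
            failures[m] = str(exc)

    # association strength for the correlation screen: single-pollutant Cox z
    # (computed for all nine metabolites, whether or not they are reported)
    cox_z = pd.Series({
        est.exposure: est.coef / est.se
        for est in effects if est.model == "cox" and est.scale == "per_IQR"
    })
    for m in METABOLITES:
        if m not in cox_z.index:
            z = _covariates_for(subj, m, avg_sg, is_score=False)
            est = fit_cox(std_cols[m], subj["T_days"].to_numpy(), z, w,
                          label=m)
            cox_z[m] = est.coef / est.se
    corr = _corr_matrix_sg_corrected(visits, METABOLITES, config.visit_set)

    artifacts = {
        "iqr": iqrs, "corr_matrix": corr, "cox_z": cox_z,
        "subsets": {}, "score_weights": {}, "scores": {}, "failures": failures,
        "exposures": subj[[c for c in exposures.columns]],
    }
    metab_std = pd.DataFrame({m: std_cols[m] for m in METABOLITES})
    z_score = _covariates_for(subj, "score", avg_sg, is_score=True)

    subset_corr = select_by_correlation(corr, cox_z, config.corr_threshold)
    subset_step = select_stepwise(
        metab_std, subj["preterm"].to_numpy(), z_score, w)
    if not subset_step:
        logger.warning("stepwise selection retained no metabolite; "
                       "falling back to the correlation-screen subset")
        subset_step = subset_corr
    artifacts["subsets"] = {"corr": subset_corr, "stepwise": subset_step}

    for score_name in config.scores:
        kind, sel = score_name.split("_", 1)
        subset = subset_corr if sel == "corr" else subset_step
        try:
            if kind == "ers":
                res = ERSRegression(
                    metab_std[subset], subj["preterm"].to_numpy(),
                    z_score, w).fit(config.quantile_method)
                weights_out = res.weights.to_dict()
            else:
                res = WQSRegression(
                    metab_std[subset], subj["preterm"].to_numpy(),
                    z_score, w, q=config.q, n_bootstrap=config.n_bootstrap,
                    seed=config.seed).fit(config.quantile_method)
                weights_out = {"weights": res.weights.to_dict(),
                               "beta1": res.beta1}
            quartiles, cuts = quartile_categorize(res.scores_std
                                                  if kind == "ers"
                                                  else res.index_std, w)
            effects.extend(_score_models(
                res.scores_std if kind == "ers" else res.index_std,
                quartiles, subj, z_score, w, label=score_name))
            artifacts["score_weights"][score_name] = weights_out
            artifacts["scores"][score_name] = res
            artifacts.setdefault("score_quartiles", {})[score_name] = quartiles
            iqrs[score_name] = res.iqr
        except Exception as exc:
            logger.error("risk score %s failed: %s", score_name, exc)
            failures[score_name] = str(exc)

    table = pd.DataFrame([e.as_row() for e in effects])
    table.insert(0, "analysis", "average")
    return table, artifacts


def _long_exposures(visits: pd.DataFrame, metabolites) -> pd.DataFrame:
    """Per-visit log exposures (substituted), long columns wide per metabolite."""
    work = visits.copy()
    for m in metabolites:
        det = work.get(f"det_{m}")
        if det is not None:
            work[m] = substitute_nondetects(work[m], det, work[m])
    if all(m in work for m in DEHP_METABOLITES):
        work["sum_dehp"] = molar_sum_dehp(
            work["MEHP"], work["MEHHP"], work["MEOHP"], work["MECPP"])
    keep = ["subject_id", "visit", "gest_week", "sg"]
    out = work[keep].copy()
    for m in list(metabolites) + (["sum_dehp"] if "sum_dehp" in work else []):
        out[f"log_{m}"] = np.log(work[m].astype(float))
    return out


def run_repeated_analysis(subjects: pd.DataFrame, visits: pd.DataFrame,
                          config: AnalysisConfig,
                          average_artifacts: dict | None = None):
    """Repeated-measures arm: LMM/BLUP single-pollutant and ERS models.

    Stage 1 uses all four visits (the mixed model handles unequal visit
    counts); stage 2 adjusts for the baseline covariates (specific gravity is
    already a stage-1 fixed effect). The per-visit ERS reuses the
    average-arm subset selection and ERS weights, applied to visit-specific
    standardized log concentrations; ``average_artifacts`` (from
    :func:`run_average_analysis`) supplies them and is computed on the fly if
    not given.
    """
    config.validate(METABOLITES)
    if average_artifacts is None:
        avg_config = AnalysisConfig(
            arm="average",
            exposures=config.exposures,
            scores=[s.replace("wqs", "ers") for s in config.scores],
            seed=config.seed, q=config.q, n_bootstrap=config.n_bootstrap,
            corr_threshold=config.corr_threshold,
            visit_set=config.visit_set,
            quantile_method=config.quantile_method)
        _, average_artifacts = run_average_analysis(
            subjects, visits, avg_config)

    sampled = subjects[subjects["sampled"]].set_index("subject_id")
    long = _long_exposures(visits, METABOLITES)
    long = long[long["subject_id"].isin(sampled.index)]

    effects, failures, blup_info = [], {}, {}
    blup_values: list[pd.DataFrame] = []
    for m in config.exposures:
        try:
            fit = RandomIntercept(long, f"log_{m}").fit()
            blups_std, iqr = fit.standardized_blups(config.quantile_method)
            subj = sampled.loc[sampled.index.intersection(blups_std.index)]
            x = blups_std.reindex(subj.index).rename(m)
            w = subj["weight"].to_numpy(dtype=float)
            z = _covariates_for(subj, m, None, is_score=False)
            effects.extend(_three_models(x, subj, z, w, label=m))
            blup_info[m] = {"iqr": iqr, "var_between": fit.var_between,
                            "var_resid": fit.var_resid, "method": fit.method}
            blup_values.append(pd.DataFrame({
                "exposure": m, "subject_id": fit.blups.index,
                "blup": fit.blups.to_numpy(),
                "blup_std": (fit.blups / iqr).to_numpy(),
                "n_visits": fit.n_visits.to_numpy()}))
        except Exception as exc:
            logger.error("repeated-measures models failed for %s: %s", m, exc)
            failures[m] = str(exc)

    # per-visit ERS -> stage-1 LMM -> stage-2 models
    avg_iqr = average_artifacts["iqr"]
    for score_name in [s for s in config.scores if s.startswith("ers")]:
        sel = score_name.split("_", 1)[1]
        subset = average_artifacts["subsets"][sel]
        wts = average_artifacts["score_weights"].get(score_name)
        try:
            if wts is None:
                raise RuntimeError(
                    f"average-arm weights unavailable for {score_name}")
            ers_long = long[["subject_id", "visit", "gest_week", "sg"]].copy()
            vals = np.zeros(len(long))
            for m in subset:
                vals += wts[m] * long[f"log_{m}"].to_numpy() / avg_iqr[m]
            ers_long["ers_visit"] = vals
            fit = RandomIntercept(ers_long, "ers_visit").fit()
            blups_std, iqr = fit.standardized_blups(config.quantile_method)
            subj = sampled.loc[sampled.index.intersection(blups_std.index)]
            x = blups_std.reindex(subj.index).rename(score_name)
            w = subj["weight"].to_numpy(dtype=float)
            z = _covariates_for(subj, score_name, None, is_score=True)
            effects.extend(_three_models(x, subj, z, w, label=score_name))
            blup_info[score_name] = {
                "iqr": iqr, "var_between": fit.var_between,
                "var_resid": fit.var_resid, "method": fit.method}
            blup_values.append(pd.DataFrame({
                "exposure": score_name, "subject_id": fit.blups.index,
                "blup": fit.blups.to_numpy(),
                "blup_std": (fit.blups / iqr).to_numpy(),
                "n_visits": fit.n_visits.to_numpy()}))
        except Exception as exc:
            logger.error("repeated-measures score %s failed: %s",
                         score_name, exc)
            failures[score_name] = str(exc)

    table = pd.DataFrame([e.as_row() for e in effects])
    table.insert(0, "analysis", "repeated")
    return table, {"blups": blup_info, "failures": failures,
                   "blup_values": (pd.concat(blup_values, ignore_index=True)
                                   if blup_values else None),
                   "average_artifacts": average_artifacts}


def descriptives(subjects: pd.DataFrame, visits: pd.DataFrame) -> dict:
    """Design-weighted descriptive summaries of the analysis sample."""
    sampled = subjects[subjects["sampled"]]
    w = sampled["weight"].to_numpy(dtype=float)
    out = {
        "n_sampled": int(len(sampled)),
        "n_cases": int(sampled["preterm"].sum()),
        "weighted_preterm_fraction": float(
            np.average(sampled["preterm"], weights=w)),
        "weight_sum": float(w.sum()),
    }
    nondetect = {}
    vsub = visits[visits["subject_id"].isin(sampled["subject_id"])]
    for m in METABOLITES:
        det = vsub.get(f"det_{m}")
        if det is not None:
            nondetect[m] = float(1.0 - det.mean())
    out["nondetect_fraction"] = nondetect
    gm = {}
    for m in METABOLITES:
        gm[m] = float(np.exp(np.log(vsub[m].astype(float)).mean()))
    out["geometric_mean_ugL"] = gm
    hist, edges = np.histogram(
        sampled["T_days"], bins=np.arange(150, 311, 7))
    out["gestational_age_histogram"] = {
        "bin_left_days": edges[:-1].tolist(), "count": hist.tolist()}
    return out


def make_report(outdir, effects: pd.DataFrame, artifacts: dict,
                desc: dict, config: AnalysisConfig,
                truth: SimTruth | None = None) -> dict:
    """Write the effect tables, weights, descriptives and run manifest."""
    if effects is None or len(effects) == 0:
        raise ValueError("no effect estimates to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    effects.to_csv(outdir / "effects.tsv", sep="\t", index=False,
                   float_format="%.6g")
    weights_payload = {
        "subsets": artifacts.get("subsets", {}),
        "score_weights": artifacts.get("score_weights", {}),
        "iqr": artifacts.get("iqr", {}),
        "blups": artifacts.get("blups", {}),
        "seed": config.seed,
        "n_bootstrap": config.n_bootstrap,
    }
    (outdir / "weights.json").write_text(
        json.dumps(weights_payload, indent=2, default=str))
    corr = artifacts.get("corr_matrix")
    if corr is None and "average_artifacts" in artifacts:
        corr = artifacts["average_artifacts"].get("corr_matrix")
    if corr is not None:
        corr.to_csv(outdir / "correlation_sg_corrected.csv",
                    float_format="%.4f")
    exposures = artifacts.get("exposures")
    if exposures is not None:
        exposures.to_csv(outdir / "exposures_mean.csv",
                         float_format="%.6g")
    if artifacts.get("scores"):
        rows = []
        for name, res in artifacts["scores"].items():
            kind, sel = name.split("_", 1)
            raw = res.scores if kind == "ers" else res.index
            std = res.scores_std if kind == "ers" else res.index_std
            quart = artifacts.get("score_quartiles", {}).get(name)
            df = pd.DataFrame({
                "subject_id": raw.index, "score_kind": kind,
                "selection": sel, "score": raw.to_numpy(),
                "score_std": std.to_numpy(),
                "quartile": (quart.to_numpy() if quart is not None
                             else np.nan)})
            rows.append(df)
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / "risk_scores.csv", index=False, float_format="%.6g")
    blup_values = artifacts.get("blup_values")
    if blup_values is not None:
        blup_values.to_csv(outdir / "blups.csv", index=False,
                           float_format="%.6g")
    (outdir / "descriptives.json").write_text(
        json.dumps(desc, indent=2))
    manifest = {
        "gestmix_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "simtruth": None if truth is None else json.loads(truth.to_json()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    paths = {p.name: p for p in (
        outdir / "effects.tsv", outdir / "weights.json",
        outdir / "descriptives.json", outdir / "manifest.json")}
    return paths


def run_pipeline(config: AnalysisConfig,
                 data_dir=None, truth: SimTruth | None = None,
                 outdir=None):
    """Simulate or load a cohort, run the configured arm, optionally report."""
    if data_dir is not None:
        subjects, visits = read_cohort(data_dir)
    else:
        truth = truth or default_truth(seed=config.seed)
        subjects, visits = simulate_cohort(truth)
    if config.arm == "average":
        effects, artifacts = run_average_analysis(subjects, visits, config)
    else:
        effects, artifacts = run_repeated_analysis(subjects, visits, config)
    desc = descriptives(subjects, visits)
    if outdir is not None:
        make_report(outdir, effects, artifacts, desc, config, truth)
    return effects, artifacts, desc
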