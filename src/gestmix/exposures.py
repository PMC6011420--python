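"""Exposure processing: from raw urinary concentrations to model-ready summaries.

Steps, in the order they are applied:

1. non-detect substitution — values below the assay detection limit are
   replaced by LOD / sqrt(2);
2. (descriptive only) specific-gravity dilution correction
   ``P_c = P * (M_SG - 1) / (SG - 1)`` with ``M_SG = 1.015``;
3. molar summation of the four DEHP metabolites into a single nmol/L index;
4. natural-log transform and averaging over the first three visits;
5. IQR standardization, so regression coefficients are per interquartile
   range of the summary.

Regression contract: models are fitted on *unadjusted* (not SG-corrected)
exposures with specific gravity entering as a covariate — regressing on
dilution-corrected concentrations can bias effect estimates. ``sg_correct``
exists only for descriptive tables (e.g. the between-metabolite correlation
matrix).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .cohort import DEHP_METABOLITES, METABOLITES, MOLAR_MASS_G_MOL

__all__ = [
    "substitute_nondetects",
    "sg_correct",
    "molar_sum_dehp",
    "average_log_exposure",
    "iqr_standardize",
    "build_average_exposures",
]

logger = logging.getLogger(__name__)

MEDIAN_SG = 1.015


def substitute_nondetects(conc, detected, lod):
    """Replace non-detects by LOD / sqrt(2); detected values pass through.

    Idempotent: a stored non-detect already at LOD/sqrt(2) with its flag
    still False maps to the same value again.
    """
    conc = np.asarray(conc, dtype=float)
    detected = np.asarray(detected, dtype=bool)
    lod = np.asarray(lod, dtype=float)
    if np.any(lod <= 0):
        raise ValueError("lod must be positive")
    return np.where(detected, conc, lod / math.sqrt(2.0))


def sg_correct(conc, sg, median_sg: float = MEDIAN_SG):
    """Specific-gravity dilution correction P_c = P (M_SG - 1)/(SG - 1).

    Descriptive use only; see the module docstring for the regression
    contract. Raises if any SG <= 1 (the correction is singular at SG = 1).
    """
    conc = np.asarray(conc, dtype=float)
    sg = np.asarray(sg, dtype=float)
    if np.any(sg <= 1.0):
        raise ValueError("specific gravity must exceed 1 for dilution correction")
    return conc * (median_sg - 1.0) / (sg - 1.0)


def molar_sum_dehp(mehp, mehhp, meohp, mecpp):
    """Molar sum of the four DEHP metabolites, µg/L -> nmol/L.

    conc[µg/L] * 1000 / MW[g/mol] = nmol/L, summed over the four analytes.
    """
    parts = {"MEHP": mehp, "MEHHP": mehhp, "MEOHP": meohp, "MECPP": mecpp}
    total = None
    for name, val in parts.items():
        val = np.asarray(val, dtype=float)
        if np.any(val < 0):
            raise ValueError(f"negative concentration for {name}")
        term = val * 1000.0 / MOLAR_MASS_G_MOL[name]
        total = term if total is None else total + term
    return total


def average_log_exposure(
    visits: pd.DataFrame,
    metabolite: str,
    visit_set=(1, 2, 3),
) -> pd.Series:
    """Mean of natural-log concentrations over the given visits, per subject.

    The fourth visit is excluded by default because subjects who deliver
    early are less likely to have one, which would make its availability
    informative of the outcome. Subjects with no qualifying visit are
    dropped with a logged warning. Non-detect substitution must already have
    been applied (concentrations must be positive).
    """
    sub = visits[visits["visit"].isin(list(visit_set))]
    vals = sub[metabolite].to_numpy(dtype=float)
    if np.any(vals <= 0):
        raise ValueError(
            f"non-positive concentration for {metabolite}; apply non-detect "
            "substitution first")
    means = np.log(sub[metabolite].astype(float)).groupby(
        sub["subject_id"]).mean()
    all_subjects = visits["subject_id"].unique()
    missing = np.setdiff1d(all_subjects, means.index.to_numpy())
    if len(missing):
        logger.warning(
            "%d subject(s) have no visit in %s for %s and are excluded",
            len(missing), tuple(visit_set), metabolite)
    means.name = metabolite
    return means


def iqr_standardize(values, quantile_method: str = "linear"):
    """Divide by the interquartile range (no centering).

    Returns ``(values / iqr, iqr)`` where ``iqr = Q3 - Q1`` under the given
    numpy quantile method (default "linear", the conventional type-7 rule).
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 4:
        raise ValueError("need at least 4 finite values to estimate an IQR")
    q1, q3 = np.quantile(finite, [0.25, 0.75], method=quantile_method)
    iqr = q3 - q1
    if iqr <= 0:
        raise ValueError("degenerate exposure: IQR is zero")
    out = arr / iqr
    if isinstance(values, pd.Series):
        out = pd.Series(out, index=values.index, name=values.name)
    return out, float(iqr)


def build_average_exposures(
    visits: pd.DataFrame,
    metabolites=None,
    visit_set=(1, 2, 3),
    include_dehp_sum: bool = True,
) -> pd.DataFrame:
    """Subject-level mean-log exposure table (plus average SG).

    Applies non-detect substitution per metabolite, computes the per-visit
    molar DEHP sum (log nmol/L) if requested, natural-log transforms, and
    averages over ``visit_set``. Returns a DataFrame indexed by subject_id
    with one column per exposure and an ``avg_sg`` column.
    """
    metabolites = list(metabolites or METABOLITES)
    work = visits.copy()
    for m in metabolites:
        det = work.get(f"det_{m}")
        if det is not None:
            # stored non-detect value is the LOD itself
            work[m] = substitute_nondetects(work[m], det, work[m])
    if include_dehp_sum and all(m in work for m in DEHP_METABOLITES):
        work["sum_dehp"] = molar_sum_dehp(
            work["MEHP"], work["MEHHP"], work["MEOHP"], work["MECPP"])
    cols = {}
    for m in metabolites + (["sum_dehp"] if "sum_dehp" in work else []):
        cols[m] = average_log_exposure(work, m, visit_set=visit_set)
    sub = work[work["visit"].isin(list(visit_set))]
    cols["avg_sg"] = sub.groupby("subject_id")["sg"].mean()
    return pd.DataFrame(cols)
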