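"""Resection-completeness summary measures and outcome models.

Per patient, a biomarker map (per-electrode SOZ probability or HFA rate)
and the resection mask are collapsed into summary measures of how
preferentially high-biomarker tissue was removed:

* biomarker difference: mean(resected) - mean(preserved)
* difference index: (R - P) / (R + P) of the side means
* resection ratio: sum over resected / sum over all electrodes
* critical resection percentage: % of supra-critical electrodes resected
  (critical value defaults to the 90th percentile of the patient's values)
* distinguishability statistic: probability that a random resected
  electrode's value exceeds a random preserved one's (the AUROC of the
  resected mask against the values, half credit for ties)

The outcome models relate these measures to ILAE class-1 seizure freedom:
a maximum-likelihood logistic regression on the ten standard-care
covariates with the summary measure as an optional eleventh predictor, and
a leave-one-patient-out evaluation comparing AUROC/AUPRC with and without
the measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from .simulate import STANDARD_CARE_COVARIATES
from .stats import EvalResult, auprc, auroc, delong_test

__all__ = [
    "biomarker_difference",
    "alternative_measures",
    "patient_summary_table",
    "standard_care_logistic",
    "LogisticReport",
    "loo_outcome_eval",
    "LooResult",
    "subgroup_eval",
]

MEASURES = (
    "biomarker_difference",
    "difference_index",
    "resection_ratio",
    "critical_resection_percentage",
    "distinguishability_statistic",
)


def _split_sides(values, resected_mask):
    values = np.asarray(values, dtype=float)
    mask = np.asarray(resected_mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("values and resected mask must align")
    ok = ~np.isnan(values)
    return values[ok & mask], values[ok & ~mask]


def biomarker_difference(values, resected_mask) -> float:
    """mean(resected) - mean(preserved); higher means high-biomarker tissue
    was preferentially resected. Returns NaN with a warning when one side
    has no valued electrode (the patient drops from that analysis)."""
    res, pre = _split_sides(values, resected_mask)
    if res.size == 0 or pre.size == 0:
        warnings.warn("biomarker difference undefined: one side is empty", RuntimeWarning)
        return float("nan")
    return float(res.mean() - pre.mean())


def _rank_auc(values: np.ndarray, mask: np.ndarray) -> float:
    from scipy.stats import rankdata

    m, n = int(mask.sum()), int((~mask).sum())
    ranks = rankdata(values)
    return float((ranks[mask].sum() - m * (m + 1) / 2.0) / (m * n))


def alternative_measures(values, resected_mask, critical_value: float | None = None) -> dict:
    """All five resection-completeness summary measures at once.

    ``critical_value`` parameterizes the critical resection percentage; the
    default is the 90th percentile of the patient's electrode values. When
    no electrode exceeds the critical value that entry is NaN with a
    warning; degenerate sides make the side-mean measures NaN as in
    :func:`biomarker_difference`.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(resected_mask, dtype=bool)
    ok = ~np.isnan(values)
    v, m = values[ok], mask[ok]
    res, pre = v[m], v[~m]
    out = {k: float("nan") for k in MEASURES}
    if res.size and pre.size:
        out["biomarker_difference"] = float(res.mean() - pre.mean())
        denom = res.mean() + pre.mean()
        out["difference_index"] = float((res.mean() - pre.mean()) / denom) if denom != 0 else float("nan")
        out["distinguishability_statistic"] = _rank_auc(v, m)
    else:
        warnings.warn("one resection side is empty; side-based measures undefined", RuntimeWarning)
    total = v.sum()
    if total != 0:
        out["resection_ratio"] = float(v[m].sum() / total)
    if critical_value is None:
        critical_value = float(np.percentile(v, 90.0)) if v.size else float("nan")
    above = v > critical_value
    if above.any():
        out["critical_resection_percentage"] = float(100.0 * m[above].mean())
    else:
        warnings.warn("no electrode exceeds the critical value", RuntimeWarning)
    return out


def patient_summary_table(
    features: pd.DataFrame, value_column: str, critical_value: float | None = None
) -> pd.DataFrame:
    """Per-patient summary measures from an electrode feature table.

    ``features`` needs columns ``patient``, ``resected`` and
    ``value_column`` (e.g. ``rate`` or ``soz_probability``).
    """
    rows = []
    for patient, grp in features.groupby("patient", sort=True):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            measures = alternative_measures(
                grp[value_column].to_numpy(), grp["resected"].to_numpy(), critical_value
            )
        rows.append({"patient": patient, **measures})
    return pd.DataFrame(rows)


@dataclass
class LogisticReport:
    """Fitted outcome logistic model with inference per covariate."""

    table: pd.DataFrame  # coef, odds_ratio, ci_low, ci_high, p per covariate
    probabilities: np.ndarray  # per-patient P(ILAE class 1)
    penalized_fallback: bool  # True when separation forced a ridge fit
    llf: float


def _design(patients: pd.DataFrame, extra: pd.Series | None):
    X = patients[STANDARD_CARE_COVARIATES].astype(float).copy()
    if extra is not None:
        X = X.assign(**{extra.name or "summary_measure": np.asarray(extra, float)})
    if X.isna().any().any():
        raise ValueError("complete covariates required (NaN present)")
    return X


def standard_care_logistic(
    patients: pd.DataFrame,
    extra_covariate: pd.Series | None = None,
    outcome_column: str = "ilae_class1",
) -> LogisticReport:
    """Maximum-likelihood logistic fit of ILAE class 1 on the ten
    standard-care covariates, plus an optional summary-measure covariate.

    Reports coefficients, odds ratios with 95% CIs, and Wald p-values.
    Perfect separation (or other MLE failure) triggers a penalized ridge
    fallback, flagged on the report; the fallback provides coefficients
    and probabilities but no Wald inference.
    """
    y = patients[outcome_column].astype(int).to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("both outcome classes required")
    X = _design(patients, extra_covariate)
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
        probs = np.asarray(fit.predict(Xc))
        llf, penalized = float(fit.llf), False
        if not np.isfinite(bse).all():
            raise RuntimeError("non-finite standard errors")
    except Exception:
        warnings.warn(
            "logistic MLE failed (likely perfect separation); penalized fallback fit",
            RuntimeWarning,
        )
        fit = sm.Logit(y, Xc).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        params = fit.params
        bse = pd.Series(np.nan, index=params.index)
        pvals = pd.Series(np.nan, index=params.index)
        probs = np.asarray(fit.predict(Xc))
        llf, penalized = float("nan"), True
    z = 1.959963984540054
    table = pd.DataFrame(
        {
            "coef": params,
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(params - z * bse),
            "ci_high": np.exp(params + z * bse),
            "p": pvals,
        }
    )
    return LogisticReport(table=table, probabilities=probs, penalized_fallback=penalized, llf=llf)


@dataclass
class LooResult:
    """Leave-one-patient-out comparison with vs without a summary measure."""

    auroc_with: EvalResult
    auroc_without: EvalResult
    auprc_with: EvalResult
    auprc_without: EvalResult
    delong_p: float
    predictions: pd.DataFrame  # patient, y, p_with, p_without
    n_flagged: int  # held-out fits whose training split lost a class


def loo_outcome_eval(
    patients: pd.DataFrame,
    measure: pd.Series,
    outcome_column: str = "ilae_class1",
) -> LooResult:
    """Leave-one-patient-out outcome classification with and without the
    resection-completeness measure.

    For each patient the logistic model (MLE, unpenalized) is fitted on the
    remaining patients and the held-out probability recorded; AUROC/AUPRC
    are computed on the concatenated held-out predictions and the paired
    AUROC difference is tested with DeLong. Training splits that lose an
    outcome class are flagged and predicted at the training prevalence.
    """
    if len(patients) < 10:
        raise ValueError("leave-one-patient-out requires >= 10 patients")
    y = patients[outcome_column].astype(int).to_numpy()
    X_without = _design(patients, None).to_numpy(dtype=float)
    X_with = _design(patients, measure.rename("summary_measure")).to_numpy(dtype=float)
    n = len(patients)
    p_with = np.empty(n)
    p_without = np.empty(n)
    flagged = 0
    for i in range(n):
        tr = np.arange(n) != i
        if np.unique(y[tr]).size < 2:
            flagged += 1
            p_with[i] = p_without[i] = y[tr].mean()
            continue
        for X, out in ((X_with, p_with), (X_without, p_without)):
            clf = LogisticRegression(C=np.inf, max_iter=2000)  # unpenalized MLE
            clf.fit(X[tr], y[tr])
            out[i] = clf.predict_proba(X[i : i + 1])[0, 1]
    return LooResult(
        auroc_with=auroc(p_with, y),
        auroc_without=auroc(p_without, y),
        auprc_with=auprc(p_with, y),
        auprc_without=auprc(p_without, y),
        delong_p=delong_test(p_with, p_without, y),
        predictions=pd.DataFrame(
            {"patient": patients["id"], "y": y, "p_with": p_with, "p_without": p_without}
        ),
        n_flagged=flagged,
    )


def subgroup_eval(
    patients: pd.DataFrame,
    scores: pd.Series,
    grouping: str = "etiology",
    outcome_column: str = "ilae_class1",
) -> pd.DataFrame:
    """Per-subgroup AUROC of a patient-level score against the outcome.

    Grouping is evaluation-only (no refitting). Groups without at least two
    patients per outcome class are reported with NaN metrics.
    """
    rows = []
    for group, grp in patients.groupby(grouping, sort=True):
        s = np.asarray(scores.loc[grp.index], float)
        y = grp[outcome_column].astype(int).to_numpy()
        row = {"group": group, "n": len(grp), "auroc": np.nan, "auprc": np.nan}
        if min((y == 1).sum(), (y == 0).sum()) >= 2 and not np.isnan(s).any():
            row["auroc"] = auroc(s, y).value
            row["auprc"] = auprc(s, y).value
        rows.append(row)
    return pd.DataFrame(rows)
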