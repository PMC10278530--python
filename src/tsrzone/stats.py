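"""Cohort-level statistics: association tests, paired comparison, rank
correlation, Kaplan-Meier / log-rank, Cox proportional hazards, and
logistic regression for perineural-invasion risk.

Categorical covariates are coded as 0/1 indicators with the conventional
reference levels (male, <60, stage I, well differentiated, non-smoker,
POI/WPOI 1-3, DOI < 5 mm, PNI negative, tumor-high); effects are reported
as ratios with Wald 95% confidence intervals.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
import statsmodels.api as sm

from .core import (
    ContingencyTable,
    EffectEstimate,
    PatientRecord,
    RegressionFit,
    TestResult,
)

ENDPOINTS = ("os", "dfs", "mfs", "rfs")

#: indicator column -> (record field, value mapped to 1)
INDICATOR_CODING = {
    "sex_female": ("sex", "female"),
    "age_ge60": ("age_group", ">=60"),
    "differentiation_modpoor": ("differentiation", "moderate-poor"),
    "smoking_yes": ("smoking", "yes"),
    "poi_high": ("poi", "4-5"),
    "wpoi_high": ("wpoi", "4-5"),
    "doi_ge5": ("doi", ">=5mm"),
    "pni_yes": ("pni", "yes"),
    "inner_group_low": ("group_inner", "tumor_low"),
    "itf_group_low": ("group_itf", "tumor_low"),
}

#: adjustment set of the reference multivariate survival models
MULTIVARIATE_ADJUSTMENT = ("poi_high", "doi_ge5", "pni_yes")

#: predictors of the perineural-invasion logistic models
PNI_PREDICTORS = ("poi_high", "wpoi_high", "doi_ge5", "inner_group_low", "itf_group_low")


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Tidy frame: raw fields plus 0/1 indicator columns and stage dummies."""
    rows = []
    for rec in records:
        row = {
            "id": rec.id,
            "tsr_inner": rec.tsr_inner,
            "tsr_itf": rec.tsr_itf,
            "stage": rec.stage,
        }
        for col, (fld, on_value) in INDICATOR_CODING.items():
            row[col] = int(getattr(rec, fld) == on_value)
        for ep in ENDPOINTS:
            row[f"{ep}_time"] = getattr(rec, f"{ep}_time")
            row[f"{ep}_event"] = getattr(rec, f"{ep}_event")
        rows.append(row)
    frame = pd.DataFrame(rows)
    for level in ("II", "III", "IV"):
        frame[f"stage_{level.lower()}"] = (frame["stage"] == level).astype(int)
    return frame


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------

def chi_square_test(table: ContingencyTable, correction: str = "auto") -> TestResult:
    """Chi-square test of independence.

    2x2 tables get the Yates continuity correction (each |O - E| reduced
    by 0.5, floored at zero, which makes p = 1 exactly attainable);
    larger tables use the plain Pearson statistic with df = (r-1)(c-1).
    ``correction`` may be "auto", "yates" or "none".
    """
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("table has a zero row or column margin")
    if correction == "auto":
        use_yates = counts.shape == (2, 2)
    elif correction in ("yates", "none"):
        use_yates = correction == "yates"
    else:
        raise ValueError("correction must be 'auto', 'yates' or 'none'")
    stat, p, df, _ = sps.chi2_contingency(counts, correction=use_yates)
    method = "chi_square_yates" if use_yates else "chi_square"
    return TestResult(statistic=float(stat), df=int(df), p_value=float(p), method=method)


def fisher_exact_test(table: ContingencyTable) -> TestResult:
    """Optional exact alternative for 2x2 tables."""
    if table.counts.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    res = sps.fisher_exact(table.counts)
    return TestResult(statistic=float(res[0]), df=None, p_value=float(res[1]),
                      method="fisher_exact")


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired t-test on n-1 df; errors on zero-variance diffs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length 1-D samples with n >= 2")
    diff = x - y
    if np.allclose(diff, diff[0]):
        raise ValueError("zero variance of paired differences")
    res = sps.ttest_rel(x, y)
    return TestResult(
        statistic=float(res.statistic),
        df=len(x) - 1,
        p_value=float(res.pvalue),
        method="paired_t",
        extra={"mean_difference": float(diff.mean())},
    )


def spearman_association(u: Sequence[float], v: Sequence[float]) -> TestResult:
    """Spearman rank correlation with a two-sided p-value."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape or u.ndim != 1 or len(u) < 3:
        raise ValueError("need two equal-length 1-D samples with n >= 3")
    if np.allclose(u, u[0]) or np.allclose(v, v[0]):
        raise ValueError("constant input has no rank correlation")
    rho, p = sps.spearmanr(u, v)
    return TestResult(statistic=float(rho), df=None, p_value=float(p), method="spearman")


# ---------------------------------------------------------------------------
# survival analysis
# ---------------------------------------------------------------------------

def km_logrank(
    records: Iterable[PatientRecord], group_field: str, endpoint: str
) -> tuple[TestResult, dict[str, pd.DataFrame]]:
    """Product-limit curves per arm plus the two-sided log-rank test.

    ``group_field`` is an indicator column name (e.g. ``itf_group_low``);
    ``endpoint`` one of os/dfs/mfs/rfs.  Returns the test result and a
    mapping arm-label -> survival-function frame.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if group_field not in frame.columns:
        raise ValueError(f"unknown group field {group_field!r}")
    groups = frame[group_field].unique()
    if len(groups) < 2:
        raise ValueError("need two arms for a log-rank test")
    t, e = f"{endpoint}_time", f"{endpoint}_event"
    arm0 = frame[frame[group_field] == 0]
    arm1 = frame[frame[group_field] == 1]
    if arm0[e].sum() + arm1[e].sum() == 0:
        raise ValueError("no events in either arm")
    res = _ll_logrank(
        arm0[t], arm1[t], event_observed_A=arm0[e], event_observed_B=arm1[e]
    )
    curves = {}
    for label, arm in (("0", arm0), ("1", arm1)):
        kmf = KaplanMeierFitter()
        kmf.fit(arm[t], arm[e], label=label)
        curves[label] = kmf.survival_function_
    test = TestResult(
        statistic=float(res.test_statistic),
        df=1,
        p_value=float(res.p_value),
        method="logrank",
    )
    return test, curves


def cox_fit(
    records: Iterable[PatientRecord],
    covariates: Sequence[str],
    endpoint: str,
) -> RegressionFit:
    """Cox partial-likelihood fit with Wald CIs for the given covariates.

    Pass one covariate for a univariate model; the reference multivariate
    adjustment set is ``MULTIVARIATE_ADJUSTMENT`` plus one TSR group.
    Stage enters through its three dummy columns (``stage_ii`` ...).
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    cols = _expand_stage(covariates, frame)
    t, e = f"{endpoint}_time", f"{endpoint}_event"
    if frame[e].sum() == 0:
        raise ValueError("no events for this endpoint")
    data = frame[cols + [t, e]]
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=t, event_col=e)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    summary = cph.summary
    effects = {
        cov: EffectEstimate(
            covariate=cov,
            effect=float(summary.loc[cov, "exp(coef)"]),
            ci_low=float(summary.loc[cov, "exp(coef) lower 95%"]),
            ci_high=float(summary.loc[cov, "exp(coef) upper 95%"]),
            p_value=float(summary.loc[cov, "p"]),
        )
        for cov in cols
    }
    return RegressionFit(
        model="cox", endpoint=endpoint, effects=effects,
        n=len(data), n_events=int(frame[e].sum()),
    )


def univariate_cox(
    records: Iterable[PatientRecord], covariates: Sequence[str], endpoint: str
) -> dict[str, EffectEstimate]:
    """One single-covariate Cox model per covariate."""
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    out: dict[str, EffectEstimate] = {}
    for cov in covariates:
        fit = cox_fit(frame, [cov], endpoint)
        for name, eff in fit.effects.items():
            out[name] = eff
    return out


def _expand_stage(covariates: Sequence[str], frame: pd.DataFrame) -> list[str]:
    cols: list[str] = []
    for cov in covariates:
        if cov == "stage":
            cols.extend(["stage_ii", "stage_iii", "stage_iv"])
        elif cov in frame.columns:
            cols.append(cov)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return cols


# ---------------------------------------------------------------------------
# logistic models for PNI
# ---------------------------------------------------------------------------

def logistic_pni(
    records: Iterable[PatientRecord],
    predictors: Sequence[str] = PNI_PREDICTORS,
    mode: str = "univariate",
) -> dict[str, EffectEstimate] | RegressionFit:
    """Binary logistic regression of PNI status on histological predictors.

    ``mode='univariate'`` fits one single-predictor model per predictor
    and returns a dict of effects; ``mode='multivariate'`` adjusts for all
    given predictors jointly and returns one fit.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    y = frame["pni_yes"]
    if y.nunique() < 2:
        raise ValueError("PNI outcome is constant")
    if mode == "univariate":
        out = {}
        for pred in predictors:
            out[pred] = _fit_logit(frame, y, [pred]).effects[pred]
        return out
    if mode == "multivariate":
        return _fit_logit(frame, y, list(predictors))
    raise ValueError("mode must be 'univariate' or 'multivariate'")


def _fit_logit(frame: pd.DataFrame, y: pd.Series, cols: list[str]) -> RegressionFit:
    X = sm.add_constant(frame[cols].astype(float))
    try:
        res = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:
        raise RuntimeError(f"logistic model failed: {exc}") from exc
    if not np.isfinite(res.bse[cols]).all() or (res.bse[cols] > 1e3).any():
        raise RuntimeError("logistic model shows (quasi-)complete separation")
    conf = res.conf_int()
    effects = {
        c: EffectEstimate(
            covariate=c,
            effect=float(np.exp(res.params[c])),
            ci_low=float(np.exp(conf.loc[c, 0])),
            ci_high=float(np.exp(conf.loc[c, 1])),
            p_value=float(res.pvalues[c]),
        )
        for c in cols
    }
    return RegressionFit(
        model="logistic", endpoint="pni", effects=effects,
        n=len(frame), n_events=int(y.sum()),
    )


def proportion_summary(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded to 2 decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("need 0 <= numerator <= denominator")
    return round(100.0 * numerator / denominator, 2)
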