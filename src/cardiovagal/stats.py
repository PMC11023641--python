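"""Trial statistics: normality-gated group tests, equivalence, power, models.

Between-group comparisons use a Shapiro-Wilk normality gate (alpha = 0.05,
both groups must pass) choosing between Student's t-test and the two-sided
Mann-Whitney U test; Cohen's d with the pooled sample SD is reported
regardless of which test ran, signed as (taVNS - Sham).  Family-wise error is
controlled by Bonferroni correction, a factor of six for the cardiac family
(HR, QTc, RMSSD, SDNN, and the two HRV factors).

Equivalence uses two one-sided two-sample t-tests (TOST) against +-margin,
with the trial's margins of 5 bpm for heart rate, 50 ms for QT, and 2 mmHg
for blood pressure.  Achieved power and required sample size come from the
noncentral t distribution.  The acute heart-rate biomarker model is a linear
mixed model with a random intercept per subject fit by REML.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA = 0.05
CARDIAC_BONFERRONI = 6
EQUIV_MARGINS = {"hr": 5.0, "qt": 50.0, "bp": 2.0}  # bpm / ms / mmHg


@dataclass
class StatResult:
    test: str
    n1: int
    n2: int
    statistic: float
    p: float
    p_corrected: float
    correction_factor: int
    cohens_d: float
    power: Optional[float] = None
    normal_gate: Optional[tuple] = None  # (shapiro p group1, group2)

    def significant(self, alpha: float = ALPHA) -> bool:
        return self.p_corrected < alpha


@dataclass
class EquivalenceResult:
    margin: float
    t_lower: float
    p_lower: float
    t_upper: float
    p_upper: float
    alpha: float = ALPHA

    @property
    def equivalent(self) -> bool:
        return self.p_lower < self.alpha and self.p_upper < self.alpha


@dataclass
class MixedModelResult:
    params: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    random_intercept_var: float
    converged: bool
    fell_back_to_ols: bool = False


def cohens_d(a, b) -> float:
    """(mean(a) - mean(b)) / pooled sample SD."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = a.size, b.size
    sp = np.sqrt(((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1))
                 / (n1 + n2 - 2))
    if sp == 0:
        return 0.0
    return float((a.mean() - b.mean()) / sp)


def compare_groups(a, b, alpha: float = ALPHA,
                   bonferroni_factor: int = 1) -> StatResult:
    """Shapiro-gated two-group comparison with signed effect size.

    t-test when both groups pass Shapiro-Wilk at 0.05, else two-sided
    Mann-Whitney U (tie-corrected).  ``a`` is the taVNS-style group: the
    reported Cohen's d is mean(a) - mean(b) over the pooled SD.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return StatResult("degenerate", a.size, b.size, 0.0, 1.0, 1.0,
                              bonferroni_factor, 0.0)
        raise ValueError("zero variance in both groups; test undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_sw_a = sps.shapiro(a).pvalue if np.var(a) > 0 else 0.0
        p_sw_b = sps.shapiro(b).pvalue if np.var(b) > 0 else 0.0
    normal = p_sw_a > 0.05 and p_sw_b > 0.05
    if normal:
        res = sps.ttest_ind(a, b)
        name = "t-test"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann-whitney"
    p_corr = min(1.0, res.pvalue * bonferroni_factor)
    return StatResult(
        test=name, n1=a.size, n2=b.size, statistic=float(res.statistic),
        p=float(res.pvalue), p_corrected=float(p_corr),
        correction_factor=bonferroni_factor, cohens_d=cohens_d(a, b),
        power=power_two_sample_t(a.size, b.size, 0.5, alpha),
        normal_gate=(float(p_sw_a), float(p_sw_b)),
    )


def signed_rank_vs_zero(deltas, bonferroni_factor: int = 1) -> StatResult:
    """Two-sided Wilcoxon signed-rank test of paired deltas against zero.

    Zeros are dropped (Wilcoxon convention) before testing.
    """
    d = np.asarray(deltas, float)
    nz = d[d != 0]
    if nz.size < 5:
        raise ValueError("need at least 5 nonzero deltas")
    res = sps.wilcoxon(nz, alternative="two-sided")
    p_corr = min(1.0, res.pvalue * bonferroni_factor)
    sd = np.std(d, ddof=1)
    d_eff = float(np.mean(d) / sd) if sd > 0 else 0.0
    return StatResult(
        test="wilcoxon-signed-rank", n1=d.size, n2=0,
        statistic=float(res.statistic), p=float(res.pvalue),
        p_corrected=float(p_corr), correction_factor=bonferroni_factor,
        cohens_d=d_eff,
    )


def tost_equivalence(a, b, margin: float,
                     alpha: float = ALPHA) -> EquivalenceResult:
    """Two one-sided two-sample t-tests against +-margin.

    Lower bound: H0 diff <= -margin vs H1 diff > -margin (reject with large
    positive t); upper bound: H0 diff >= +margin vs H1 diff < +margin.
    Equivalence is declared iff both one-sided tests reject at ``alpha``.
    """
    if margin <= 0:
        raise ValueError("equivalence margin must be positive")
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = a.size, b.size
    diff = a.mean() - b.mean()
    sp2 = ((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) \
        / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    t_lower = (diff + margin) / se
    t_upper = (diff - margin) / se
    p_lower = float(sps.t.sf(t_lower, df))
    p_upper = float(sps.t.cdf(t_upper, df))
    return EquivalenceResult(margin=margin, t_lower=float(t_lower),
                             p_lower=p_lower, t_upper=float(t_upper),
                             p_upper=p_upper, alpha=alpha)


def power_two_sample_t(n1: int, n2: int, d: float = 0.5,
                       alpha: float = ALPHA) -> float:
    """Achieved power of the two-sided two-sample t-test via noncentral t.

    df = n1 + n2 - 2, noncentrality = d * sqrt(n1*n2/(n1+n2)).
    """
    if min(n1, n2) < 2:
        raise ValueError("need n >= 2 per group")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def required_n(power: float = 0.80, d: float = 0.5,
               alpha: float = ALPHA, n_max: int = 100000) -> int:
    """Smallest equal-arm n per group reaching the target power."""
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    for n in range(2, n_max):
        if power_two_sample_t(n, n, d, alpha) >= power:
            return n
    raise ValueError("no n below n_max reaches the target power")


def interaction_regression(table: pd.DataFrame,
                           response: str = "rmssd_change",
                           day_col: str = "day",
                           arm_col: str = "arm") -> pd.DataFrame:
    """OLS of metric change on Day * Treatment with interaction.

    Returns the coefficient table (estimate, p, CI); the ``day:treatment``
    row is the differential slope of the taVNS arm in units of the response
    per day.
    """
    df = table[[response, day_col, arm_col]].dropna().copy()
    df["treat"] = (df[arm_col] == "taVNS").astype(float)
    x = sm.add_constant(
        pd.DataFrame({
            "day": df[day_col].astype(float),
            "treat": df["treat"],
            "day:treat": df[day_col].astype(float) * df["treat"],
        })
    )
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(df[response].astype(float), x).fit()
    out = pd.DataFrame({
        "coef": fit.params, "p": fit.pvalues,
        "ci_low": fit.conf_int()[0], "ci_high": fit.conf_int()[1],
    })
    return out


def fit_mixed_model(table: pd.DataFrame,
                    response: str = "hr_delta",
                    mrs_col: str = "mrs_change",
                    arm_col: str = "arm",
                    subject_col: str = "subject") -> MixedModelResult:
    """Random-intercept mixed model of session deltas on arm x mRS change.

    response ~ 1 + taVNS + mRS + taVNS:mRS with a per-subject random
    intercept, fit by REML with Wald confidence intervals.  A singular fit
    falls back to OLS with a warning.
    """
    df = table[[response, mrs_col, arm_col, subject_col]].dropna().copy()
    counts = df.groupby(subject_col).size()
    if (counts < 2).all():
        raise ValueError("need >= 2 sessions for at least some subjects")
    df["treat"] = (df[arm_col] == "taVNS").astype(float)
    df = df.rename(columns={response: "y", mrs_col: "mrs"})
    formula = "y ~ treat + mrs + treat:mrs"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(formula, df, groups=df[subject_col])
            fit = md.fit(reml=True)
        singular = not fit.converged or np.isnan(fit.bse).any()
    except (np.linalg.LinAlgError, ValueError):
        singular = True
        fit = None
    if singular:
        logger.warning("mixed model singular; falling back to OLS")
        ols = smf.ols(formula, df).fit()
        ci = ols.conf_int()
        return MixedModelResult(
            params=ols.params, pvalues=ols.pvalues,
            conf_int=ci, random_intercept_var=0.0,
            converged=True, fell_back_to_ols=True,
        )
    ci = fit.conf_int().loc[fit.fe_params.index]
    return MixedModelResult(
        params=fit.fe_params, pvalues=fit.pvalues[fit.fe_params.index],
        conf_int=ci,
        random_intercept_var=float(fit.cov_re.iloc[0, 0]),
        converged=bool(fit.converged),
    )


def ancova_age(table: pd.DataFrame, response: str,
               arm_col: str = "arm", age_col: str = "age") -> pd.DataFrame:
    """Arm effect on a metric change adjusted for age (metric ~ arm + age).

    Age is the decade midpoint from metadata.  A constant age column is
    dropped with a warning (plain arm comparison remains).
    """
    df = table[[response, arm_col, age_col]].dropna().copy()
    df["treat"] = (df[arm_col] == "taVNS").astype(float)
    cols = {"treat": df["treat"]}
    if df[age_col].nunique() > 1:
        cols["age"] = df[age_col].astype(float)
    else:
        logger.warning("constant age; age covariate dropped")
    x = sm.add_constant(pd.DataFrame(cols))
    fit = sm.OLS(df[response].astype(float), x).fit()
    return pd.DataFrame({
        "coef": fit.params, "p": fit.pvalues,
        "ci_low": fit.conf_int()[0], "ci_high": fit.conf_int()[1],
    })


def pearson_corr(x, y) -> tuple:
    """Sample Pearson correlation and its t-test p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
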