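"""Test-retest reliability statistics for the kinematic variables.

Relative reliability is the intraclass correlation from a two-way random
effects single-measure model in its *consistency* form (systematic
between-occasion offsets do not count as error).  Absolute reliability is
the standard error of measurement SEM = SD(test1 − test2)/√2, the
within-subject coefficient of variation CV (same formula on log-transformed
values, back-transformed to percent), and the minimal difference
MD = SEM × 1.96 × √2 — the smallest individual change exceeding measurement
error at 95% confidence.  Heteroscedasticity is probed by correlating
subject means with absolute test-retest differences; a paired t-test checks
for bias between occasions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "ReliabilityReport",
    "icc_consistency",
    "sem",
    "cv",
    "md",
    "heteroscedasticity",
    "bias_test",
    "reliability_report",
    "MD_FACTOR",
]

MD_FACTOR = 1.96 * np.sqrt(2.0)  # 2.77186...


@dataclass
class PairedMeasurements:
    """One variable's values for the same subjects on two occasions."""

    subject_ids: list[str]
    test1: np.ndarray
    test2: np.ndarray
    variable_name: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.test1 = np.asarray(self.test1, float)
        self.test2 = np.asarray(self.test2, float)
        n = len(self.subject_ids)
        if self.test1.shape != (n,) or self.test2.shape != (n,):
            raise ValueError("test1/test2 must be vectors paired with subject_ids")
        if np.isnan(self.test1).any() or np.isnan(self.test2).any():
            raise ValueError("missing pairs are not allowed")

    @property
    def n(self) -> int:
        return self.test1.size

    def log(self) -> "PairedMeasurements":
        if np.any(self.test1 <= 0) or np.any(self.test2 <= 0):
            raise ValueError("log transform requires strictly positive values")
        return PairedMeasurements(
            self.subject_ids,
            np.log(self.test1),
            np.log(self.test2),
            self.variable_name,
            self.group,
        )


@dataclass
class ReliabilityReport:
    variable_name: str
    group: str
    n: int
    icc: float
    icc_ci: tuple[float, float]
    sem: float
    sem_ci: tuple[float, float]
    cv_pct: float
    cv_ci: tuple[float, float]
    md: float
    bias_p: float
    heteroscedasticity_r: float
    heteroscedasticity_p: float
    log_transformed: bool
    test1_mean: float = np.nan
    test1_sd: float = np.nan
    test2_mean: float = np.nan
    test2_sd: float = np.nan


def _two_way_anova(pm: PairedMeasurements) -> tuple[float, float, float]:
    """Mean squares (rows=subjects, columns=occasions, error) of the n×2 table."""
    X = np.column_stack([pm.test1, pm.test2])
    n, k = X.shape
    grand = X.mean()
    ss_rows = k * np.sum((X.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((X.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((X - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_err


def icc_consistency(
    pm: PairedMeasurements, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Single-measure consistency ICC from the two-way subjects × occasions
    ANOVA, with the F-based 95% confidence interval.

    ICC = (MS_subjects − MS_error) / (MS_subjects + (k−1)·MS_error), k = 2.
    """
    if pm.n < 3:
        raise ValueError("need at least 3 subjects for ICC")
    k = 2
    ms_r, _, ms_e = _two_way_anova(pm)
    if ms_r == 0 and ms_e == 0:
        warnings.warn("degenerate data: zero between- and within-subject variance")
        return 1.0, (1.0, 1.0)
    if ms_e == 0:
        return 1.0, (1.0, 1.0)
    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    df1, df2 = pm.n - 1, (pm.n - 1) * (k - 1)
    F = ms_r / ms_e
    f_u = stats.f.ppf(1 - alpha / 2, df1, df2)
    f_l = stats.f.ppf(1 - alpha / 2, df2, df1)
    FL = F / f_u
    FU = F * f_l
    lo = (FL - 1) / (FL + k - 1)
    hi = (FU - 1) / (FU + k - 1)
    return float(icc), (float(lo), float(hi))


def _sd_ci(s: float, df: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = s * np.sqrt(df / stats.chi2.ppf(1 - alpha / 2, df))
    hi = s * np.sqrt(df / stats.chi2.ppf(alpha / 2, df))
    return float(lo), float(hi)


def sem(pm: PairedMeasurements, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """SEM = SD(test1 − test2)/√2 with a χ²-based confidence interval."""
    if pm.n < 2:
        raise ValueError("need at least 2 pairs for SEM")
    s = float(np.std(pm.test1 - pm.test2, ddof=1) / np.sqrt(2.0))
    lo, hi = _sd_ci(s, pm.n - 1, alpha)
    return s, (lo, hi)


def cv(pm: PairedMeasurements, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Within-subject CV in percent: the SEM formula on log-transformed
    values, back-transformed as 100·(eˢ − 1)."""
    if np.any(pm.test1 <= 0) or np.any(pm.test2 <= 0):
        raise ValueError("CV requires strictly positive values")
    s, (lo, hi) = sem(pm.log(), alpha)
    to_pct = lambda x: float(100.0 * np.expm1(x))
    return to_pct(s), (to_pct(lo), to_pct(hi))


def md(sem_value: float) -> float:
    """Minimal difference MD = SEM × 1.96 × √2."""
    if sem_value < 0:
        raise ValueError("SEM must be non-negative")
    return float(sem_value * MD_FACTOR)


def heteroscedasticity(
    pm: PairedMeasurements, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation between subject means and absolute test-retest differences.

    A positive, significant correlation indicates the random error grows with
    the measured magnitude (heteroscedasticity), motivating log-transforming.
    """
    if pm.n < 3:
        raise ValueError("need at least 3 pairs")
    means = (pm.test1 + pm.test2) / 2.0
    adiff = np.abs(pm.test1 - pm.test2)
    if np.std(means) == 0 or np.std(adiff) == 0:
        warnings.warn("zero variance in means or |differences|: correlation undefined")
        return np.nan, np.nan
    if method == "pearson":
        r, p = stats.pearsonr(means, adiff)
    elif method == "spearman":
        r, p = stats.spearmanr(means, adiff)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def bias_test(pm: PairedMeasurements, log_transformed: bool = False) -> float:
    """Two-sided paired t-test p-value for a systematic offset between
    occasions (on log values when the report is log-transformed)."""
    if pm.n < 2:
        raise ValueError("need at least 2 pairs")
    data = pm.log() if log_transformed else pm
    d = data.test1 - data.test2
    if np.std(d, ddof=1) == 0:
        return 1.0 if np.allclose(d, 0) else 0.0
    _, p = stats.ttest_rel(data.test1, data.test2)
    return float(p)


def _needs_log(pm: PairedMeasurements, skew_threshold: float = 1.0) -> bool:
    _, het_p = heteroscedasticity(pm)
    pooled = np.concatenate([pm.test1, pm.test2])
    skew = stats.skew(pooled, bias=False)
    het = (not np.isnan(het_p)) and het_p < 0.05
    return het or abs(skew) > skew_threshold


def reliability_report(
    pm: PairedMeasurements,
    force_log: Optional[bool] = None,
    heteroscedasticity_method: str = "pearson",
    icc_form: str = "consistency",
) -> ReliabilityReport:
    """Assemble all reliability statistics for one variable in one group.

    The ICC (and bias test) are computed on log-transformed values when
    heteroscedasticity is significant (p < 0.05) or pooled skewness exceeds
    |1|, unless ``force_log`` overrides the rule.  SEM and MD stay on the
    original scale; CV is log-based by definition.
    """
    het_r, het_p = heteroscedasticity(pm, method=heteroscedasticity_method)
    log_flag = _needs_log(pm) if force_log is None else force_log
    can_log = np.all(pm.test1 > 0) and np.all(pm.test2 > 0)
    log_flag = bool(log_flag and can_log)
    icc_input = pm.log() if log_flag else pm
    if icc_form == "consistency":
        icc, icc_ci = icc_consistency(icc_input)
    elif icc_form == "agreement":
        icc, icc_ci = icc_agreement(icc_input)
    else:
        raise ValueError(f"unknown ICC form {icc_form!r}")
    sem_val, sem_ci = sem(pm)
    if can_log:
        cv_val, cv_ci = cv(pm)
    else:
        cv_val, cv_ci = np.nan, (np.nan, np.nan)
    return ReliabilityReport(
        variable_name=pm.variable_name,
        group=pm.group,
        n=pm.n,
        icc=icc,
        icc_ci=icc_ci,
        sem=sem_val,
        sem_ci=sem_ci,
        cv_pct=cv_val,
        cv_ci=cv_ci,
        md=md(sem_val),
        bias_p=bias_test(pm, log_transformed=log_flag),
        heteroscedasticity_r=het_r,
        heteroscedasticity_p=het_p,
        log_transformed=log_flag,
        test1_mean=float(pm.test1.mean()),
        test1_sd=float(pm.test1.std(ddof=1)),
        test2_mean=float(pm.test2.mean()),
        test2_sd=float(pm.test2.std(ddof=1)),
    )


def icc_agreement(
    pm: PairedMeasurements, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Absolute-agreement single-measure ICC(2,1): systematic occasion
    offsets count as error.  Provided as an alternative to the default
    consistency form."""
    if pm.n < 3:
        raise ValueError("need at least 3 subjects for ICC")
    n, k = pm.n, 2
    ms_r, ms_c, ms_e = _two_way_anova(pm)
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom == 0:
        return 1.0, (1.0, 1.0)
    icc = (ms_r - ms_e) / denom
    if ms_e <= 0 or icc >= 1:
        return float(icc), (1.0, 1.0)
    # Satterthwaite df for the denominator (McGraw & Wong 1996)
    fj = ms_c / ms_e
    vn = (k - 1) * (n - 1) * (
        k * icc * fj + n * (1 + (k - 1) * icc) - k * icc
    ) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (
        n * (1 + (k - 1) * icc) - k * icc
    ) ** 2
    v = vn / vd
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = (
        n * (ms_r - f_u * ms_e)
        / (f_u * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r)
    )
    hi = (
        n * (f_l * ms_r - ms_e)
        / (k * ms_c + (k * n - k - n) * ms_e + n * f_l * ms_r)
    )
    return float(icc), (float(lo), float(hi))
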