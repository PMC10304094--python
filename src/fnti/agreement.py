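"""Repeatability and reproducibility statistics for paired measurements.

Given matched FNTi measurements from two sessions of one examiner
(repeatability) or from two examiners (reproducibility), this module
computes the paired t-test, Bland–Altman limits of agreement, Cohen's d
effect size and the intraclass correlation coefficient, and bundles them
into an :class:`AgreementReport`.

Conventions
-----------
Differences are first-listed minus second-listed (session 1 − session 2,
examiner 1 − examiner 2), so a positive bias of the second rater shows as a
negative mean difference.  The 95% limits of agreement use the literal
multiplier 1.96 (not a t quantile).  The ICC defaults to ICC(2,1) — two-way
random effects, absolute agreement, single measurement — the standard model
for reliability of a measurement method with interchangeable raters;
ICC(3,1) (consistency) is available via ``model="icc3"``.

Qualitative bands follow the conventional cut-points: Cohen's d negligible
< 0.20, small >= 0.20, medium >= 0.50, large >= 0.80; reliability judged on
the *lower* ICC confidence bound — poor < 0.50, moderate >= 0.50, good
>= 0.75, excellent >= 0.90.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

LOA_MULTIPLIER = 1.96


class AgreementError(ValueError):
    """Insufficient or degenerate paired data."""


@dataclass
class PairedSample:
    """Matched measurements of the same hips by two raters/sessions."""

    values_a: np.ndarray
    values_b: np.ndarray
    unit_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if self.values_a.ndim != 1 or self.values_b.ndim != 1:
            raise AgreementError("paired values must be one-dimensional")
        if len(self.values_a) != len(self.values_b) or len(self.values_a) != len(self.unit_ids):
            raise AgreementError("values_a, values_b and unit_ids must have equal length")
        if len(self.values_a) < 3:
            raise AgreementError("need at least 3 matched pairs")
        if not (np.all(np.isfinite(self.values_a)) and np.all(np.isfinite(self.values_b))):
            raise AgreementError("non-finite measurement values")

    @property
    def n(self) -> int:
        return len(self.values_a)

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b

    def swapped(self) -> "PairedSample":
        return PairedSample(self.values_b.copy(), self.values_a.copy(), list(self.unit_ids))


def limits_of_agreement(mean_diff: float, sd_diff: float) -> tuple[float, float]:
    """95% limits of agreement: mean difference ± 1.96 × SD of differences."""
    return (mean_diff - LOA_MULTIPLIER * sd_diff, mean_diff + LOA_MULTIPLIER * sd_diff)


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_mean_diff: tuple[float, float]
    pair_means: np.ndarray
    pair_diffs: np.ndarray
    unit_ids: Sequence[str]


def bland_altman(sample: PairedSample) -> BlandAltmanResult:
    """Bland–Altman method-comparison summary.

    Emits the mean difference, its SD (n−1 denominator), the 95% limits of
    agreement, the t-based 95% CI of the mean difference, and the per-unit
    (mean, difference) pairs used for the classic scatter plot.
    """
    d = sample.differences
    n = sample.n
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    lo, hi = limits_of_agreement(mean_diff, sd_diff)
    tq = stats.t.ppf(0.975, n - 1)
    half = tq * sd_diff / math.sqrt(n)
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_lower=lo,
        loa_upper=hi,
        ci_mean_diff=(mean_diff - half, mean_diff + half),
        pair_means=(sample.values_a + sample.values_b) / 2.0,
        pair_diffs=d,
        unit_ids=list(sample.unit_ids),
    )


@dataclass
class PairedTResult:
    t_stat: Optional[float]
    df: int
    p_value: Optional[float]
    mean_diff: float
    degenerate: bool = False


def paired_t(sample: PairedSample) -> PairedTResult:
    """Two-sided paired t-test on the differences.

    t = d̄ / (SD_d / √n) on n − 1 degrees of freedom.  When every pair is
    identical the statistic is undefined; the result is flagged degenerate
    and only the mean difference is reported.
    """
    d = sample.differences
    n = sample.n
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return PairedTResult(None, n - 1, None, mean_diff, degenerate=True)
    t = mean_diff / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return PairedTResult(float(t), n - 1, float(p), mean_diff)


def effect_size_band(d: float) -> str:
    if d < 0.20:
        return "negligible"
    if d < 0.50:
        return "small"
    if d < 0.80:
        return "medium"
    return "large"


@dataclass
class CohensDResult:
    d: Optional[float]
    band: Optional[str]
    variant: str
    degenerate: bool = False


def cohens_d(sample: PairedSample, variant: str = "pooled") -> CohensDResult:
    """Cohen's d effect size for the paired comparison.

    ``pooled``: |mean_a − mean_b| divided by the pooled SD of the two sets
    (the default).  ``paired_diff``: |d̄| divided by the SD of differences.
    """
    a, b = sample.values_a, sample.values_b
    if variant == "pooled":
        sa, sb = a.std(ddof=1), b.std(ddof=1)
        denom = math.sqrt((sa**2 + sb**2) / 2.0)
    elif variant == "paired_diff":
        denom = sample.differences.std(ddof=1)
    else:
        raise ValueError(f"unknown Cohen's d variant {variant!r}")
    if denom == 0.0:
        return CohensDResult(None, None, variant, degenerate=True)
    d = abs(float(a.mean() - b.mean())) / denom
    return CohensDResult(d, effect_size_band(d), variant)


def icc_band(lower_ci: float) -> str:
    if lower_ci < 0.50:
        return "poor"
    if lower_ci < 0.75:
        return "moderate"
    if lower_ci < 0.90:
        return "good"
    return "excellent"


@dataclass
class IccResult:
    icc: float
    ci_lower: float
    ci_upper: float
    band: str
    model: str


def _anova_mean_squares(M: np.ndarray) -> tuple[float, float, float]:
    """Two-way (units × raters) ANOVA mean squares: MSR, MSC, MSE."""
    n, k = M.shape
    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = M - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_two_way(
    sample: PairedSample, model: str = "icc2", alpha: float = 0.05
) -> IccResult:
    """Intraclass correlation for a units × 2 raters table.

    ``icc2`` — ICC(2,1), two-way random effects, absolute agreement, single
    measurement:

        ICC = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE) / n)

    with the F-based confidence interval of McGraw & Wong.  ``icc3`` —
    ICC(3,1), two-way mixed, consistency.
    """
    M = np.column_stack([sample.values_a, sample.values_b])
    n, k = M.shape
    msr, msc, mse = _anova_mean_squares(M)
    if msr <= 0 or (msr == 0 and mse == 0):
        raise AgreementError("ICC undefined: no between-unit variance")

    if model == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0:
            raise AgreementError("ICC undefined: zero total variance")
        icc = (msr - mse) / denom
        # McGraw & Wong F-based interval for ICC(A,1)
        a_ = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else math.inf
        b_ = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else math.inf
        if math.isinf(a_):
            lo = hi = 1.0
        else:
            v = (a_ * msc + b_ * mse) ** 2 / (
                (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_lo * mse) / (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f_hi * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_hi * msr)
    elif model == "icc3":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0:
            lo = hi = 1.0
        else:
            f_obs = msr / mse
            df2 = (n - 1) * (k - 1)
            fl = f_obs / stats.f.ppf(1 - alpha / 2, n - 1, df2)
            fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, n - 1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    lo, hi = max(-1.0, min(lo, 1.0)), max(-1.0, min(hi, 1.0))
    return IccResult(float(icc), float(lo), float(hi), icc_band(lo), model)


@dataclass
class AgreementReport:
    """One row of an agreement table: bias, limits, test, effect size, ICC."""

    label: str
    n: int
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_mean_diff: tuple[float, float]
    t_stat: Optional[float]
    t_p: Optional[float]
    cohens_d: Optional[float]
    d_band: Optional[str]
    d_variant: Optional[str]
    icc: float
    icc_ci: tuple[float, float]
    icc_band: str
    bland_altman: BlandAltmanResult = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "ci_mean_diff_lower": self.ci_mean_diff[0],
            "ci_mean_diff_upper": self.ci_mean_diff[1],
            "t_stat": self.t_stat,
            "t_p": self.t_p,
            "cohens_d": self.cohens_d,
            "d_band": self.d_band,
            "d_variant": self.d_variant,
            "icc": self.icc,
            "icc_ci_lower": self.icc_ci[0],
            "icc_ci_upper": self.icc_ci[1],
            "icc_band": self.icc_band,
        }


def analyze_agreement(
    sample: PairedSample,
    label: str = "",
    d_variant: str = "pooled",
    icc_model: str = "icc2",
    alpha: float = 0.05,
) -> AgreementReport:
    """Full paired-agreement analysis for one comparison.

    Cohen's d is reported only when the paired t-test is significant at
    ``alpha``, mirroring the convention of quoting an effect size only for
    significant differences.
    """
    ba = bland_altman(sample)
    tt = paired_t(sample)
    icc = icc_two_way(sample, model=icc_model, alpha=alpha)
    d_res = None
    if tt.p_value is not None and tt.p_value < alpha:
        d_res = cohens_d(sample, variant=d_variant)
    return AgreementReport(
        label=label,
        n=sample.n,
        mean_diff=ba.mean_diff,
        sd_diff=ba.sd_diff,
        loa_lower=ba.loa_lower,
        loa_upper=ba.loa_upper,
        ci_mean_diff=ba.ci_mean_diff,
        t_stat=tt.t_stat,
        t_p=tt.p_value,
        cohens_d=None if d_res is None or d_res.degenerate else d_res.d,
        d_band=None if d_res is None or d_res.degenerate else d_res.band,
        d_variant=None if d_res is None else d_res.variant,
        icc=icc.icc,
        icc_ci=(icc.ci_lower, icc.ci_upper),
        icc_band=icc.band,
        bland_altman=ba,
    )
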