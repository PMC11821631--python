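"""Test-retest reliability of the repeated baseline measurements.

For each twitch parameter measured at the two pre-exercise timepoints the
module quantifies systematic bias (paired t), the standardized difference
(bias-corrected Hedges' g with magnitude band), relative reliability
(ICC: two-way model, absolute agreement, single rating, with F-based 95%
CI and interpretation band), and absolute reliability:

    SEM = SD * sqrt(1 - ICC)        MDC = SEM * 1.96 * sqrt(2)

where SD is the standard deviation of all scores of both baseline
timepoints pooled; SEM% and MDC% are expressed relative to the grand mean
of those scores.  The MDC is what the diagnostics stage later uses as the
threshold separating real change from measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "paired_bias",
    "hedges_g",
    "icc_a1",
    "sem_mdc",
    "effect_size_band",
    "icc_band",
    "reliability_table",
    "ReliabilityReport",
]

# |g| thresholds for small / moderate / large / very large / extremely
# large standardized effects; below the first threshold => trivial.
EFFECT_SIZE_THRESHOLDS = (0.2, 0.6, 1.2, 2.0, 4.0)
EFFECT_SIZE_LABELS = ("trivial", "small", "moderate", "large",
                      "very large", "extremely large")

ICC_THRESHOLDS = (0.5, 0.75, 0.9)
ICC_LABELS = ("poor", "moderate", "good", "excellent")


def _band(value: float, thresholds, labels) -> str:
    if np.isnan(value):
        return "undefined"
    i = int(np.searchsorted(thresholds, abs(value), side="right"))
    return labels[i]


def effect_size_band(g: float) -> str:
    """Magnitude label for a standardized effect size."""
    return _band(g, EFFECT_SIZE_THRESHOLDS, EFFECT_SIZE_LABELS)


def icc_band(icc: float) -> str:
    """Interpretation label for an intraclass correlation."""
    return _band(icc, ICC_THRESHOLDS, ICC_LABELS)


@dataclass
class PairedBias:
    bias: float
    ci: tuple[float, float]
    t: float
    p: float
    n: int
    degenerate: bool = False


def paired_bias(pre1, pre2, alpha: float = 0.05) -> PairedBias:
    """Two-sided paired t-test for a systematic test-retest bias.

    Returns the mean difference (pre1 - pre2) with its t-based CI.  When
    the differences have zero variance the t statistic is degenerate: the
    result is flagged, with t = 0, p = 1 for a zero bias and t = +/-inf,
    p = 0 otherwise.
    """
    x = np.asarray(pre1, dtype=float)
    y = np.asarray(pre2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("pre1 and pre2 must be paired (equal length)")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        t = 0.0 if bias == 0 else math.copysign(math.inf, bias)
        p = 1.0 if bias == 0 else 0.0
        return PairedBias(bias, (bias, bias), t, p, n, degenerate=True)
    se = sd / math.sqrt(n)
    t = bias / se
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    return PairedBias(bias, (bias - tcrit * se, bias + tcrit * se),
                      float(t), float(p), n)


@dataclass
class HedgesG:
    g: float
    ci: tuple[float, float]
    band: str
    n: int


def hedges_g(pre1, pre2, alpha: float = 0.05) -> HedgesG:
    """Bias-corrected standardized mean difference for paired data.

    g = J * (mean1 - mean2) / s_av with s_av the average of the two SDs
    and small-sample correction J = 1 - 3 / (4*(n-1) - 1).  The CI is a
    normal approximation on g's standard error.  A zero s_av yields an
    undefined (NaN) flag.
    """
    x = np.asarray(pre1, dtype=float)
    y = np.asarray(pre2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("pre1 and pre2 must be paired (equal length)")
    n = len(x)
    s_av = (np.std(x, ddof=1) + np.std(y, ddof=1)) / 2.0
    if s_av == 0.0:
        return HedgesG(float("nan"), (float("nan"), float("nan")),
                       "undefined", n)
    j = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    g = j * (np.mean(x) - np.mean(y)) / s_av
    se = math.sqrt(1.0 / n + g ** 2 / (2.0 * n))
    z = stats.norm.ppf(1 - alpha / 2)
    return HedgesG(float(g), (float(g - z * se), float(g + z * se)),
                   effect_size_band(g), n)


def hedges_g_from_summary(mean1: float, sd1: float, mean2: float,
                          sd2: float, n: int) -> float:
    """Point estimate of g from summary statistics (means, SDs, n)."""
    s_av = (sd1 + sd2) / 2.0
    j = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    return j * (mean1 - mean2) / s_av


@dataclass
class IccResult:
    icc: float
    ci: tuple[float, float]
    band: str
    n: int


def icc_a1(pre1, pre2, alpha: float = 0.05) -> IccResult:
    """Intraclass correlation: two-way model, absolute agreement, single
    rating — ICC(A,1) — for two ratings per subject.

    Computed from the mean squares of the subject x rating decomposition
    with the standard F-distribution confidence interval (McGraw & Wong
    convention).  Zero total variance yields an undefined (NaN) flag.
    """
    data = np.column_stack([np.asarray(pre1, float),
                            np.asarray(pre2, float)])
    n, k = data.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = data.mean()
    if np.allclose(data, grand):
        return IccResult(float("nan"), (float("nan"), float("nan")),
                         "undefined", n)
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)      # subjects
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)      # ratings
    sse = np.sum((data - row_means[:, None] - col_means[None, :]
                  + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return IccResult(float("nan"), (float("nan"), float("nan")),
                         "undefined", n)
    icc = (msr - mse) / denom

    # Satterthwaite F interval for ICC(A,1)
    if mse == 0:
        lo, hi = icc, icc
    else:
        fj = msc / mse
        dfe = (n - 1) * (k - 1)
        vn = dfe * (k * icc * fj + n * (1 + (k - 1) * icc)
                    - k * icc) ** 2
        vd = ((n - 1) * k ** 2 * icc ** 2 * fj ** 2
              + (n * (1 + (k - 1) * icc) - k * icc) ** 2)
        v = vn / vd
        f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_u * mse) / (
            f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_l * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_l * msr)
    return IccResult(float(icc), (float(lo), float(hi)), icc_band(icc), n)


def sem_mdc(sd_all: float, icc: float, grand_mean: float
            ) -> tuple[float, float, float, float]:
    """Absolute reliability chain: (SEM, SEM%, MDC, MDC%).

    SEM = sd_all * sqrt(1 - icc); MDC = SEM * 1.96 * sqrt(2); the percent
    versions are relative to the grand mean of all pooled scores.
    """
    if not 0.0 <= icc <= 1.0:
        raise ValueError("icc must be in [0, 1]")
    if sd_all < 0:
        raise ValueError("sd_all must be >= 0")
    sem = sd_all * math.sqrt(1.0 - icc)
    mdc = sem * 1.96 * math.sqrt(2.0)
    if grand_mean == 0:
        return sem, float("nan"), mdc, float("nan")
    return sem, 100.0 * sem / grand_mean, mdc, 100.0 * mdc / grand_mean


@dataclass
class ReliabilityReport:
    """Full test-retest chain for one parameter."""

    parameter: str
    n: int
    mean_pre1: float
    sd_pre1: float
    mean_pre2: float
    sd_pre2: float
    bias: float
    bias_ci: tuple[float, float]
    t: float
    p: float
    g: float
    g_ci: tuple[float, float]
    g_band: str
    icc: float
    icc_ci: tuple[float, float]
    icc_band: str
    sem: float
    sem_pct: float
    mdc: float
    mdc_pct: float


def assess_parameter(pre1, pre2, parameter: str = "") -> ReliabilityReport:
    """Run the full reliability chain on one parameter's paired baselines."""
    x = np.asarray(pre1, dtype=float)
    y = np.asarray(pre2, dtype=float)
    pb = paired_bias(x, y)
    hg = hedges_g(x, y)
    ic = icc_a1(x, y)
    pooled = np.concatenate([x, y])
    icc_for_sem = ic.icc if not np.isnan(ic.icc) else 1.0
    icc_for_sem = min(max(icc_for_sem, 0.0), 1.0)
    sem, sem_pct, mdc, mdc_pct = sem_mdc(
        float(np.std(pooled, ddof=1)), icc_for_sem, float(np.mean(pooled)))
    return ReliabilityReport(
        parameter=parameter, n=len(x),
        mean_pre1=float(np.mean(x)), sd_pre1=float(np.std(x, ddof=1)),
        mean_pre2=float(np.mean(y)), sd_pre2=float(np.std(y, ddof=1)),
        bias=pb.bias, bias_ci=pb.ci, t=pb.t, p=pb.p,
        g=hg.g, g_ci=hg.ci, g_band=hg.band,
        icc=ic.icc, icc_ci=ic.ci, icc_band=ic.band,
        sem=sem, sem_pct=sem_pct, mdc=mdc, mdc_pct=mdc_pct)


def reliability_table(params: pd.DataFrame, parameters=None,
                      pre1: str = "Pre1", pre2: str = "Pre2"
                      ) -> pd.DataFrame:
    """Reliability report for every parameter column of a long-format
    parameter table (columns subject, timepoint, <parameters...>).

    Rows are matched by subject between the two baseline timepoints;
    subjects missing either baseline for a parameter are dropped for that
    parameter.
    """
    from .metrics import ALL_PARAMETERS

    if parameters is None:
        parameters = [p for p in ALL_PARAMETERS if p in params.columns]
    rows = []
    for param in parameters:
        wide = params.pivot(index="subject", columns="timepoint",
                            values=param)
        pair = wide[[pre1, pre2]].dropna()
        rep = assess_parameter(pair[pre1], pair[pre2], parameter=param)
        rows.append({
            "parameter": param, "n": rep.n,
            "mean_pre1": rep.mean_pre1, "sd_pre1": rep.sd_pre1,
            "mean_pre2": rep.mean_pre2, "sd_pre2": rep.sd_pre2,
            "bias": rep.bias, "bias_lo": rep.bias_ci[0],
            "bias_hi": rep.bias_ci[1], "t": rep.t, "p": rep.p,
            "g": rep.g, "g_lo": rep.g_ci[0], "g_hi": rep.g_ci[1],
            "g_band": rep.g_band,
            "icc": rep.icc, "icc_lo": rep.icc_ci[0],
            "icc_hi": rep.icc_ci[1], "icc_band": rep.icc_band,
            "sem": rep.sem, "sem_pct": rep.sem_pct,
            "mdc": rep.mdc, "mdc_pct": rep.mdc_pct,
        })
    return pd.DataFrame(rows)
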