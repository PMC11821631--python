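"""Longitudinal inference over the measurement schedule.

Extreme-value screening (Tukey fences at 3 x IQR), neighbor-mean
interpolation of interior missing values, one-way within-subjects
repeated-measures ANOVA with Greenhouse-Geisser sphericity correction,
Bonferroni-corrected paired post hocs against the baseline timepoint, and
Pearson correlation of percent changes with magnitude banding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reliability import hedges_g

__all__ = [
    "flag_extremes",
    "interpolate_missing",
    "LongitudinalMatrix",
    "AnovaResult",
    "rm_anova",
    "bonferroni_vs_baseline",
    "pearson_assoc",
]

CORRELATION_THRESHOLDS = (0.1, 0.3, 0.5, 0.7, 0.9)
CORRELATION_LABELS = ("trivial", "small", "moderate", "large",
                      "very large", "extremely large")


def flag_extremes(values) -> np.ndarray:
    """Boolean mask of extreme values outside the Tukey fences
    Q1 - 3*IQR and Q3 + 3*IQR.

    Quartiles use the linear-interpolation convention (the default of
    ``numpy.percentile``).  With zero IQR the fences collapse onto the
    quartiles, so a constant vector yields no flags.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 values for Tukey fences")
    q1, q3 = np.percentile(x[~np.isnan(x)], [25, 75])
    iqr = q3 - q1
    with np.errstate(invalid="ignore"):
        return (x < q1 - 3 * iqr) | (x > q3 + 3 * iqr)


def interpolate_missing(series) -> np.ndarray:
    """Fill interior missing values with the mean of the nearest preceding
    and following observed values of the same subject.

    Runs of consecutive missing values all take the mean of the run's two
    flanking observations.  A missing value at either end of the series
    has no such pair and raises ``ValueError``.
    """
    x = np.asarray(series, dtype=float).copy()
    missing = np.isnan(x)
    if not missing.any():
        return x
    if missing[0] or missing[-1]:
        raise ValueError("missing value at series boundary is unresolvable")
    observed = np.flatnonzero(~missing)
    for i in np.flatnonzero(missing):
        prev = observed[observed < i].max()
        nxt = observed[observed > i].min()
        x[i] = 0.5 * (x[prev] + x[nxt])
    return x


@dataclass
class LongitudinalMatrix:
    """Subjects x timepoints values of one parameter."""

    values: np.ndarray
    timepoint_labels: tuple[str, ...]
    baseline_label: str = "Pre2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timepoint_labels = tuple(self.timepoint_labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x timepoints)")
        if self.values.shape[1] != len(self.timepoint_labels):
            raise ValueError("label count must match column count")
        if self.baseline_label not in self.timepoint_labels:
            raise ValueError(
                f"baseline {self.baseline_label!r} not in labels")

    @classmethod
    def from_long(cls, params: pd.DataFrame, parameter: str,
                  baseline_label: str = "Pre2",
                  timepoints=None) -> "LongitudinalMatrix":
        wide = params.pivot(index="subject", columns="timepoint",
                            values=parameter)
        if timepoints is None:
            order = params["timepoint"].drop_duplicates().tolist()
            timepoints = [t for t in order if t in wide.columns]
        wide = wide[list(timepoints)]
        return cls(wide.to_numpy(), tuple(timepoints), baseline_label)

    def interpolated(self) -> "LongitudinalMatrix":
        filled = np.vstack([interpolate_missing(row) for row in self.values])
        return LongitudinalMatrix(filled, self.timepoint_labels,
                                  self.baseline_label)

    def log_transformed(self) -> "LongitudinalMatrix":
        """Natural-log transform, for heavy-tailed parameters that fail
        extreme-value screening; requires strictly positive values."""
        if np.nanmin(self.values) <= 0:
            raise ValueError("log transform requires positive values")
        return LongitudinalMatrix(np.log(self.values),
                                  self.timepoint_labels,
                                  self.baseline_label)


@dataclass
class AnovaResult:
    """``p_value`` carries the Greenhouse-Geisser-corrected p (the primary
    result); ``p_uncorrected`` the sphericity-assuming p as a diagnostic.
    The corrected test is conservative when sphericity actually holds,
    because the epsilon estimate is biased below 1 in small samples."""

    f_stat: float
    df_num: float
    df_den: float
    p_value: float
    partial_eta_sq: float
    epsilon: float
    p_uncorrected: float = float("nan")


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the doubly-centered covariance of
    the timepoint columns; bounded in [1/(k-1), 1]."""
    n, k = data.shape
    s = np.cov(data, rowvar=False)
    c = np.eye(k) - np.ones((k, k)) / k
    sc = c @ s @ c
    tr = np.trace(sc)
    denom = (k - 1) * np.trace(sc @ sc)
    if denom <= 0:
        return 1.0
    eps = tr ** 2 / denom
    return float(min(max(eps, 1.0 / (k - 1)), 1.0))


def rm_anova(matrix: LongitudinalMatrix) -> AnovaResult:
    """One-way within-subjects repeated-measures ANOVA.

    The F statistic comes from the subject x time decomposition; the
    Greenhouse-Geisser epsilon is applied unconditionally to both degrees
    of freedom and hence to the p-value.  Partial eta squared is
    SS_time / (SS_time + SS_error).
    """
    data = matrix.values
    n, k = data.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 timepoints and >= 3 subjects")
    if np.isnan(data).any():
        raise ValueError(
            "matrix contains missing values; run interpolate_missing first")
    grand = data.mean()
    ss_time = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_error = ss_total - ss_time - ss_subj
    df_time = k - 1
    df_error = (n - 1) * (k - 1)
    ms_time = ss_time / df_time
    ms_error = ss_error / df_error
    if ms_error == 0:
        f = math.inf if ms_time > 0 else float("nan")
        p = p_unc = 0.0 if ms_time > 0 else float("nan")
        eps = 1.0
    else:
        f = ms_time / ms_error
        eps = _gg_epsilon(data) if k > 2 else 1.0
        p = float(stats.f.sf(f, eps * df_time, eps * df_error))
        p_unc = float(stats.f.sf(f, df_time, df_error))
    denom = ss_time + ss_error
    peta = float(ss_time / denom) if denom > 0 else float("nan")
    return AnovaResult(float(f), eps * df_time, eps * df_error, p, peta,
                       eps, p_unc)


def bonferroni_vs_baseline(matrix: LongitudinalMatrix,
                           family_size: int | None = None) -> pd.DataFrame:
    """Bonferroni-corrected paired t-tests of every post-baseline timepoint
    against the baseline column, with Hedges' g effect sizes.

    The family size defaults to the number of timepoints after the
    baseline column.  Returns one row per comparison: timepoint, mean
    difference, g with CI and band, raw and adjusted p.
    """
    labels = matrix.timepoint_labels
    base_idx = labels.index(matrix.baseline_label)
    baseline = matrix.values[:, base_idx]
    targets = list(range(base_idx + 1, len(labels)))
    m = family_size if family_size is not None else len(targets)
    rows = []
    for j in targets:
        col = matrix.values[:, j]
        d = col - baseline
        sd = np.std(d, ddof=1)
        if sd == 0:
            t, p = (0.0, 1.0) if np.mean(d) == 0 else (math.inf, 0.0)
        else:
            t, p = stats.ttest_rel(col, baseline)
        hg = hedges_g(col, baseline)
        rows.append({
            "timepoint": labels[j], "diff": float(np.mean(d)),
            "g": hg.g, "g_lo": hg.ci[0], "g_hi": hg.ci[1],
            "g_band": hg.band, "t": float(t), "p_raw": float(p),
            "p_adj": float(min(1.0, p * m)),
        })
    return pd.DataFrame(rows)


@dataclass
class PearsonResult:
    r: float
    p: float
    band: str
    n: int


def pearson_assoc(x, y) -> PearsonResult:
    """Pearson product-moment correlation with magnitude banding
    (thresholds 0.1/0.3/0.5/0.7/0.9).  Zero variance in either input
    yields an undefined (NaN) flag."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return PearsonResult(float("nan"), float("nan"), "undefined", n)
    r, p = stats.pearsonr(x, y)
    i = int(np.searchsorted(CORRELATION_THRESHOLDS, abs(r), side="right"))
    return PearsonResult(float(r), float(p), CORRELATION_LABELS[i], n)
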