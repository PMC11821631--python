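"""MDC-based responder classification and diagnostic accuracy.

Subjects are classified at selected timepoints as potentiated (increase
from baseline exceeding the parameter's minimal detectable change),
fatigued (decrease exceeding the MDC) or unchanged.  Each displacement-
derived parameter is then treated as an index test against the peak-
twitch-torque reference: 2x2 contingency tables, sensitivity/specificity/
predictive values with exact binomial (Clopper-Pearson) CIs, diagnostic
effectiveness, Youden's index, and a rank-based AUROC on the percent
changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import TMG_PARAMETERS, percent_change

__all__ = [
    "classify_change",
    "ContingencyTable",
    "build_contingency",
    "accuracy_metrics",
    "clopper_pearson",
    "roc_auc",
    "auroc_band",
    "DiagnosticReport",
    "classify_cohort",
    "diagnostic_table",
]

POTENTIATED = "potentiated"
FATIGUED = "fatigued"
UNCHANGED = "unchanged"

AUROC_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)
AUROC_LABELS = ("insufficient", "bad", "sufficient", "good", "very good",
                "excellent")


def classify_change(delta: float, mdc: float) -> str:
    """Responder status from a change score and the parameter's MDC.

    Strict exceedance: delta > mdc -> potentiated, delta < -mdc ->
    fatigued, otherwise unchanged (a change exactly equal to the MDC does
    not qualify as real change).
    """
    if mdc < 0:
        raise ValueError("mdc must be >= 0")
    if np.isnan(delta):
        return UNCHANGED
    if delta > mdc:
        return POTENTIATED
    if delta < -mdc:
        return FATIGUED
    return UNCHANGED


@dataclass
class ContingencyTable:
    """2x2 counts of index-test vs reference classification."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.total


def build_contingency(reference, index, condition: str) -> ContingencyTable:
    """Cross-tabulate paired status lists against one condition.

    ``positive`` means carrying ``condition`` (e.g. "fatigued"); the
    reference test defines the true state, the index test the prediction.
    """
    ref = list(reference)
    idx = list(index)
    if len(ref) != len(idx):
        raise ValueError("reference and index lists must be paired")
    ref_pos = np.array([r == condition for r in ref])
    idx_pos = np.array([i == condition for i in idx])
    return ContingencyTable(
        tp=int(np.sum(ref_pos & idx_pos)),
        fp=int(np.sum(~ref_pos & idx_pos)),
        fn=int(np.sum(ref_pos & ~idx_pos)),
        tn=int(np.sum(~ref_pos & ~idx_pos)),
    )


def clopper_pearson(successes: int, trials: int,
                    confidence: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via Beta quantiles.

    The lower bound is exactly 0 when successes = 0 and the upper bound
    exactly 1 when successes = trials.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials, trials >= 1")
    alpha = 1.0 - confidence
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    hi = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return lo, hi


def _ratio(num: int, den: int) -> tuple[float, tuple[float, float]]:
    if den == 0:
        return float("nan"), (float("nan"), float("nan"))
    return num / den, clopper_pearson(num, den)


@dataclass
class DiagnosticReport:
    """Accuracy metrics of one index test at one timepoint.  Members whose
    defining margin is empty are NaN (undefined flag), never silently 0."""

    sn: float
    sp: float
    ppv: float
    npv: float
    de: float
    yi: float
    sn_ci: tuple[float, float]
    sp_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    de_ci: tuple[float, float]
    yi_ci: tuple[float, float]
    auroc: float = float("nan")
    accuracy_band: str = "undefined"
    table: ContingencyTable | None = field(default=None, repr=False)


def accuracy_metrics(table: ContingencyTable) -> DiagnosticReport:
    """Sensitivity, specificity, predictive values, diagnostic
    effectiveness and Youden's index with exact binomial CIs.

    DE is the prevalence-weighted average of Sn and Sp, which equals the
    overall accuracy (tp+tn)/total; when one reference margin is empty
    (prevalence 0 or 1) the accuracy form is used directly, so DE reduces
    to Sn when every subject has the condition.  The Youden CI combines
    the Sn and Sp interval endpoints.
    """
    sn, sn_ci = _ratio(table.tp, table.tp + table.fn)
    sp, sp_ci = _ratio(table.tn, table.fp + table.tn)
    ppv, ppv_ci = _ratio(table.tp, table.tp + table.fp)
    npv, npv_ci = _ratio(table.tn, table.fn + table.tn)
    de, de_ci = _ratio(table.tp + table.tn, table.total)
    if math.isnan(sn) or math.isnan(sp):
        yi, yi_ci = float("nan"), (float("nan"), float("nan"))
    else:
        yi = sn + sp - 1.0
        yi_ci = (sn_ci[0] + sp_ci[0] - 1.0, sn_ci[1] + sp_ci[1] - 1.0)
    return DiagnosticReport(sn=sn, sp=sp, ppv=ppv, npv=npv, de=de, yi=yi,
                            sn_ci=sn_ci, sp_ci=sp_ci, ppv_ci=ppv_ci,
                            npv_ci=npv_ci, de_ci=de_ci, yi_ci=yi_ci,
                            table=table)


def roc_auc(scores, labels, positive: str) -> float:
    """Rank-based AUROC: the probability that a randomly chosen positive
    subject's score exceeds a negative subject's, ties counting 1/2
    (Mann-Whitney formulation).  NaN when only one class is present.

    Callers orient ``scores`` so that larger means more indicative of the
    positive condition (for fatigue: the negated change from baseline).
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray([l == positive for l in labels])
    n_pos, n_neg = int(lab.sum()), int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(s)
    u = ranks[lab].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auroc_band(auroc: float) -> str:
    """Interpretation label for an AUROC value."""
    if np.isnan(auroc):
        return "undefined"
    i = int(np.searchsorted(AUROC_THRESHOLDS, auroc, side="right"))
    return AUROC_LABELS[i]


# --------------------------------------------------------------------------
# Cohort-level assessment
# --------------------------------------------------------------------------

def classify_cohort(params: pd.DataFrame, mdc_table: pd.DataFrame,
                    timepoint: str, parameter: str,
                    baseline_label: str = "Pre2") -> pd.DataFrame:
    """Per-subject change, percent change and responder status of one
    parameter at one timepoint.

    ``mdc_table`` is the reliability table (columns parameter, mdc).
    """
    mdc = float(
        mdc_table.set_index("parameter").loc[parameter, "mdc"])
    wide = params.pivot(index="subject", columns="timepoint",
                        values=parameter)
    base = wide[baseline_label]
    now = wide[timepoint]
    delta = now - base
    rows = []
    for subj in wide.index:
        d = float(delta.loc[subj])
        rows.append({
            "subject": subj, "delta": d,
            "pct_change": percent_change(float(now.loc[subj]),
                                         float(base.loc[subj])),
            "status": classify_change(d, mdc),
        })
    return pd.DataFrame(rows)


def diagnostic_table(params: pd.DataFrame, mdc_table: pd.DataFrame,
                     conditions: dict[str, str] | None = None,
                     parameters=None,
                     reference: str = "Pt",
                     baseline_label: str = "Pre2") -> pd.DataFrame:
    """Diagnostic accuracy of every index parameter at every assessed
    timepoint, against the reference parameter's MDC classification.

    ``conditions`` maps timepoint -> condition assessed there (default:
    Set1 potentiated, Post1 and Post15 fatigued).  Returns one row per
    (timepoint, parameter) with counts, metrics, CIs and AUROC.
    """
    if conditions is None:
        conditions = {"Set1": POTENTIATED, "Post1": FATIGUED,
                      "Post15": FATIGUED}
    if parameters is None:
        parameters = [p for p in TMG_PARAMETERS if p in params.columns]
    rows = []
    for timepoint, condition in conditions.items():
        ref_cls = classify_cohort(params, mdc_table, timepoint, reference,
                                  baseline_label)
        for param in parameters:
            idx_cls = classify_cohort(params, mdc_table, timepoint, param,
                                      baseline_label)
            merged = ref_cls.merge(idx_cls, on="subject",
                                   suffixes=("_ref", "_idx"))
            table = build_contingency(merged["status_ref"],
                                      merged["status_idx"], condition)
            rep = accuracy_metrics(table)
            sign = -1.0 if condition == FATIGUED else 1.0
            auroc = roc_auc(sign * merged["pct_change_idx"].to_numpy(),
                            merged["status_ref"], condition)
            rows.append({
                "timepoint": timepoint, "condition": condition,
                "parameter": param,
                "tp": table.tp, "fp": table.fp,
                "fn": table.fn, "tn": table.tn,
                "prevalence": table.prevalence,
                "sn": rep.sn, "sn_lo": rep.sn_ci[0], "sn_hi": rep.sn_ci[1],
                "sp": rep.sp, "sp_lo": rep.sp_ci[0], "sp_hi": rep.sp_ci[1],
                "ppv": rep.ppv, "ppv_lo": rep.ppv_ci[0],
                "ppv_hi": rep.ppv_ci[1],
                "npv": rep.npv, "npv_lo": rep.npv_ci[0],
                "npv_hi": rep.npv_ci[1],
                "de": rep.de, "de_lo": rep.de_ci[0], "de_hi": rep.de_ci[1],
                "yi": rep.yi, "yi_lo": rep.yi_ci[0], "yi_hi": rep.yi_ci[1],
                "auroc": auroc, "accuracy_band": auroc_band(auroc),
            })
    return pd.DataFrame(rows)
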