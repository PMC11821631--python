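"""End-to-end orchestration: simulate -> extract -> derive -> analyze.

A pipeline run produces, inside one run directory:

    parameters.csv     long-format per-twitch parameters plus derived Vc
    fatigue_index.csv  per-subject MVIC fatigue indices
    reliability.csv    per-parameter test-retest chain (bias, g, ICC,
                       SEM, MDC)
    anova.csv          sphericity-corrected RM-ANOVA per parameter
    posthoc.csv        Bonferroni-corrected comparisons vs baseline
    diagnostics.csv    MDC-classification accuracy of the displacement
                       parameters against peak twitch torque
    summary.json       machine-readable headline numbers
    provenance.json    config hash, seed, package version

Reruns with the same configuration and seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import diagnostic_table
from .inference import (
    LongitudinalMatrix,
    bonferroni_vs_baseline,
    flag_extremes,
    rm_anova,
)
from .metrics import ALL_PARAMETERS, add_derived_columns, percent_change
from .reliability import reliability_table
from .signals import extract_cohort, extract_fatigue_indices
from .synthetic import SimulationConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("tmgkit")


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs.

    Extraction settings mirror the acquisition chain: low-pass filter
    order/cutoff for the twitch torque, rolling-median window and torque
    floor for the MVIC, pre-stimulus baseline window.  Analysis settings
    pick the significance level, the baseline timepoint, and the
    timepoints at which diagnostic accuracy is assessed.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filter_cutoff: float = 15.0
    filter_order: int = 4
    mvic_window: int = 501
    mvic_floor: float = 20.0
    baseline_ms: float = 50.0
    analysis_window_ms: float = 500.0
    min_displacement: float = 0.1
    alpha: float = 0.05
    baseline_label: str = "Pre2"
    diagnostic_timepoints: dict[str, str] = field(default_factory=lambda: {
        "Set1": "potentiated", "Post1": "fatigued", "Post15": "fatigued"})
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.seed != self.simulation.seed:
            self.simulation = self.simulation.with_(seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["schedule"] = list(d["simulation"]["schedule"])
        d["simulation"]["n_mvic_per_set"] = list(
            d["simulation"]["n_mvic_per_set"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if "schedule" in sim:
            sim["schedule"] = tuple(sim["schedule"])
        if "n_mvic_per_set" in sim:
            sim["n_mvic_per_set"] = tuple(sim["n_mvic_per_set"])
        return cls(simulation=SimulationConfig(**sim), **d)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run all stages and write every result table into ``out_dir``.

    Returns the summary dictionary that is also written to summary.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage simulate: %d subjects, %d timepoints",
             config.simulation.n_subjects, len(config.simulation.schedule))
    cohort = simulate_cohort(config.simulation)

    log.info("stage extract")
    params = extract_cohort(
        cohort, analysis_window_ms=config.analysis_window_ms,
        baseline_ms=config.baseline_ms, cutoff=config.filter_cutoff,
        order=config.filter_order, min_displacement=config.min_displacement)
    n_flagged = int(params[["Dm", "Td", "Tc"]].isna().any(axis=1).sum())
    if n_flagged:
        log.info("  %d twitches carry a no-displacement flag", n_flagged)
    fi = extract_fatigue_indices(cohort, window=config.mvic_window,
                                 floor=config.mvic_floor)

    log.info("stage derive")
    params = add_derived_columns(params)
    _write_csv(params, out / "parameters.csv")
    _write_csv(fi, out / "fatigue_index.csv")

    log.info("stage reliability")
    rel = reliability_table(params)
    _write_csv(rel, out / "reliability.csv")

    log.info("stage inference")
    anova_rows, posthoc_frames = [], []
    schedule = list(config.simulation.schedule)
    for param in [p for p in ALL_PARAMETERS if p in params.columns]:
        n_extreme = int(params.groupby("timepoint")[param].transform(
            lambda s: flag_extremes(s.to_numpy())
            if s.notna().sum() >= 4 else s.notna() & False).sum())
        if n_extreme:
            log.info("  %s: %d extreme value(s) outside 3xIQR fences",
                     param, n_extreme)
        mat = LongitudinalMatrix.from_long(
            params, param, baseline_label=config.baseline_label,
            timepoints=schedule).interpolated()
        res = rm_anova(mat)
        anova_rows.append({
            "parameter": param, "n": mat.values.shape[0],
            "df_num": res.df_num, "df_den": res.df_den,
            "f": res.f_stat, "p": res.p_value,
            "partial_eta_sq": res.partial_eta_sq,
            "epsilon": res.epsilon,
        })
        ph = bonferroni_vs_baseline(mat)
        ph.insert(0, "parameter", param)
        posthoc_frames.append(ph)
    anova = pd.DataFrame(anova_rows)
    posthoc = pd.concat(posthoc_frames, ignore_index=True)
    _write_csv(anova, out / "anova.csv")
    _write_csv(posthoc, out / "posthoc.csv")

    log.info("stage diagnostics")
    diag = diagnostic_table(params, rel,
                            conditions=config.diagnostic_timepoints,
                            baseline_label=config.baseline_label)
    _write_csv(diag, out / "diagnostics.csv")

    # Cohort-mean percent change of peak twitch torque along the schedule
    pt_wide = params.pivot(index="subject", columns="timepoint",
                           values="Pt")[schedule]
    base = pt_wide[config.baseline_label]
    pt_pct = {tp: float(np.mean([
        percent_change(v, b) for v, b in zip(pt_wide[tp], base)]))
        for tp in schedule}

    summary = {
        "n_subjects": config.simulation.n_subjects,
        "pt_percent_change": pt_pct,
        "fatigue_index_mean": float(fi["fi"].mean()),
        "fatigue_index_sd": float(fi["fi"].std(ddof=1)),
        "reliability": {
            row["parameter"]: {"icc": row["icc"], "sem": row["sem"],
                               "sem_pct": row["sem_pct"],
                               "mdc": row["mdc"],
                               "mdc_pct": row["mdc_pct"]}
            for _, row in rel.iterrows()},
        "anova_p": {row["parameter"]: row["p"]
                    for _, row in anova.iterrows()},
        "diagnostics_de": {
            f'{row["timepoint"]}:{row["parameter"]}': row["de"]
            for _, row in diag.iterrows()},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "tmgkit_version": __version__,
        "config": config.to_dict(),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    log.info("run complete: %s", out)
    return summary
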