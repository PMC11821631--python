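"""Derived per-twitch and per-session scalars.

The four rate-of-displacement concepts summarize how fast the muscle belly
displaces over stated fractions of its rise to the maximal displacement Dm:

    Vc0-10%  = 0.1 * Dm / Td * 1000            (mm/s)
    Vc0-90%  = 0.9 * Dm / (Td + Tc) * 1000     (mm/s)
    Vc10-90% = 0.8 * Dm / Tc * 1000            (mm/s)
    Vcnorm   = 0.8 / Tc * 1000                 (1/s, amplitude-normalized)

with Td and Tc in ms.  Vcnorm is independent of Dm, so Vc10-90% = Dm * Vcnorm
identically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "vc_parameters",
    "fatigue_index",
    "percent_change",
    "add_derived_columns",
    "TMG_PARAMETERS",
    "ALL_PARAMETERS",
]

# Index-test (displacement-derived) parameters, and the full parameter set
# including the torque reference.
TMG_PARAMETERS = ("Dm", "Td", "Tc", "Vc0_10", "Vc0_90", "Vc10_90", "Vcnorm")
ALL_PARAMETERS = ("Pt",) + TMG_PARAMETERS


def vc_parameters(dm: float, td: float, tc: float) -> dict[str, float]:
    """Rate-of-displacement parameters from Dm (mm), Td (ms), Tc (ms)."""
    if not (td > 0 and tc > 0):
        raise ValueError("Td and Tc must be > 0")
    if dm < 0:
        raise ValueError("Dm must be >= 0")
    return {
        "Vc0_10": 0.1 * dm / td * 1000.0,
        "Vc0_90": 0.9 * dm / (td + tc) * 1000.0,
        "Vc10_90": 0.8 * dm / tc * 1000.0,
        "Vcnorm": 0.8 / tc * 1000.0,
    }


def fatigue_index(first_mvic: float, last_mvic: float) -> float:
    """Percent decline in MVIC torque from the first to the last voluntary
    contraction: 100 * (first - last) / first."""
    if not first_mvic > 0:
        raise ValueError("first MVIC must be > 0")
    return 100.0 * (first_mvic - last_mvic) / first_mvic


def percent_change(value: float, baseline: float) -> float:
    """Percent change from baseline: 100 * (value - baseline) / baseline.
    NaN (undefined flag) when the baseline is zero."""
    if baseline == 0:
        return float("nan")
    return 100.0 * (value - baseline) / baseline


def add_derived_columns(params: pd.DataFrame) -> pd.DataFrame:
    """Append the Vc columns to a long-format parameter table with columns
    subject, timepoint, Pt, Dm, Td, Tc.  Rows with a no-displacement flag
    (NaN Dm/Td/Tc) get NaN derived values."""
    out = params.copy()
    dm = out["Dm"].to_numpy(dtype=float)
    td = out["Td"].to_numpy(dtype=float)
    tc = out["Tc"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["Vc0_10"] = 0.1 * dm / td * 1000.0
        out["Vc0_90"] = 0.9 * dm / (td + tc) * 1000.0
        out["Vc10_90"] = 0.8 * dm / tc * 1000.0
        out["Vcnorm"] = 0.8 / tc * 1000.0
    return out
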