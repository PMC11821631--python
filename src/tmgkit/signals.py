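"""Signal extraction: raw session traces -> per-twitch scalars.

Covers calibration of the dynamometer voltage signal, stimulus-trigger
detection, rolling-median MVIC extraction, zero-phase Butterworth filtering
of twitch torque, peak twitch torque (Pt), and the tensiomyographic
displacement parameters Dm (maximal displacement), Td (delay time, stimulus
to 10% of Dm) and Tc (contraction time, 10% to 90% of Dm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synthetic import ConfigurationError, SessionRecording, TwitchRecording

__all__ = [
    "TwitchParams",
    "calibrate_torque",
    "detect_triggers",
    "extract_mvic",
    "filter_twitch",
    "twitch_peak_torque",
    "displacement_params",
    "extract_session",
    "extract_cohort",
]


@dataclass
class TwitchParams:
    """Per-twitch scalar summary.  Timing parameters are NaN when the
    displacement is absent (no-displacement flag)."""

    Pt: float
    Dm: float
    Td: float
    Tc: float


def calibrate_torque(voltage_trace: np.ndarray,
                     calibration_factor: float) -> np.ndarray:
    """Convert an analogue voltage trace to torque (Nm) by elementwise
    scaling with a daily calibration factor (Nm/V)."""
    if calibration_factor <= 0:
        raise ConfigurationError("calibration factor must be > 0")
    return np.asarray(voltage_trace, dtype=float) * calibration_factor


def detect_triggers(trigger_trace: np.ndarray,
                    threshold: float = 0.5) -> list[int]:
    """Indices of rising edges: first sample >= threshold preceded by a
    sample < threshold (index 0 counts if already above).  Sorted
    ascending; empty when no crossing."""
    x = np.asarray(trigger_trace, dtype=float)
    above = x >= threshold
    if not above.any():
        return []
    rising = above & ~np.concatenate([[False], above[:-1]])
    return list(np.flatnonzero(rising))


def extract_mvic(torque_trace: np.ndarray, window: int = 501,
                 floor: float = 20.0) -> float:
    """MVIC torque: the highest centered rolling median (full windows only)
    whose window center lies in the period where torque exceeds ``floor``.

    Returns NaN (missing-MVIC flag) when the torque never exceeds the
    floor.  The 501-sample default window is ~0.5 s at 1 kHz, which
    suppresses brief spikes while tracking the contraction plateau.
    """
    x = np.asarray(torque_trace, dtype=float)
    if len(x) < window:
        raise ConfigurationError(
            f"trace of {len(x)} samples shorter than window {window}")
    supra = x > floor
    if not supra.any():
        return float("nan")
    med = pd.Series(x).rolling(window, center=True).median().to_numpy()
    valid = ~np.isnan(med) & supra
    if not valid.any():
        return float("nan")
    return float(np.nanmax(med[valid]))


def filter_twitch(torque_trace: np.ndarray, sample_rate: float,
                  cutoff: float = 15.0, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) low-pass Butterworth filter.

    Zero-phase application preserves the timing of the twitch peak; the
    effective magnitude response is the square of the single-pass design.
    """
    if cutoff >= sample_rate / 2:
        raise ConfigurationError("cutoff must be below the Nyquist rate")
    sos = sps.butter(order, cutoff, btype="low", fs=sample_rate,
                     output="sos")
    return sps.sosfiltfilt(sos, np.asarray(torque_trace, dtype=float))


def _baseline(trace: np.ndarray, stim_index: int, sample_rate: float,
              baseline_ms: float) -> float:
    n_base = int(round(baseline_ms * sample_rate / 1000.0))
    start = max(stim_index - n_base, 0)
    if start == stim_index:
        return 0.0
    return float(np.mean(trace[start:stim_index]))


def twitch_peak_torque(recording: TwitchRecording,
                       analysis_window_ms: float = 500.0,
                       baseline_ms: float = 50.0,
                       cutoff: float = 15.0, order: int = 4) -> float:
    """Peak twitch torque Pt (Nm).

    The torque trace is low-pass filtered (zero-phase Butterworth), the
    mean of the ``baseline_ms`` preceding the stimulus is subtracted, and
    Pt is the maximum within ``analysis_window_ms`` after the stimulus.
    """
    fs = recording.sample_rate
    n_win = int(round(analysis_window_ms * fs / 1000.0))
    stop = recording.stim_index + n_win + 1
    if stop > len(recording.torque):
        raise ConfigurationError("analysis window exceeds trace length")
    filt = filter_twitch(recording.torque, fs, cutoff=cutoff, order=order)
    base = _baseline(filt, recording.stim_index, fs, baseline_ms)
    return float(np.max(filt[recording.stim_index:stop]) - base)


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float,
                     start: int, stop: int) -> float:
    """Time of the first upward crossing of ``level`` in [start, stop),
    linearly interpolated between straddling samples."""
    for j in range(start, stop):
        if y[j] >= level:
            if j == start or y[j - 1] >= level:
                return float(t[j])
            frac = (level - y[j - 1]) / (y[j] - y[j - 1])
            return float(t[j - 1] + frac * (t[j] - t[j - 1]))
    return float("nan")


def displacement_params(recording: TwitchRecording,
                        baseline_ms: float = 50.0,
                        min_displacement: float = 0.1,
                        noise_floor: float = 0.05
                        ) -> tuple[float, float, float]:
    """Displacement parameters (Dm mm, Td ms, Tc ms) of one twitch.

    Dm is the height of the first local maximum of the baseline-subtracted
    displacement after the stimulus, where a qualifying peak must have
    prominence above ``max(noise_floor, 5% of the global maximum)``;
    earliest peak wins ties, and the global maximum is the fallback when no
    local peak qualifies.  Td is the time from the stimulus to the first
    upward crossing of 0.10*Dm; Tc from that crossing to the first upward
    crossing of 0.90*Dm.  Crossings are linearly interpolated between
    samples, giving sub-sample resolution.

    Returns ``(nan, nan, nan)`` (no-displacement flag) when Dm falls below
    ``min_displacement`` — the behaviour of a sensor that detects no radial
    displacement.
    """
    fs = recording.sample_rate
    y = np.asarray(recording.displacement, dtype=float).copy()
    y -= _baseline(y, recording.stim_index, fs, baseline_ms)
    post = y[recording.stim_index:]
    t_ms = np.arange(len(post)) * 1000.0 / fs

    gmax = float(np.max(post)) if len(post) else 0.0
    if gmax < min_displacement:
        return (float("nan"), float("nan"), float("nan"))
    prominence = max(noise_floor, 0.05 * gmax)
    peaks, _ = sps.find_peaks(post, prominence=prominence)
    peak_idx = int(peaks[0]) if len(peaks) else int(np.argmax(post))
    dm = float(post[peak_idx])
    if dm < min_displacement:
        return (float("nan"), float("nan"), float("nan"))

    t10 = _interp_crossing(t_ms, post, 0.10 * dm, 0, peak_idx + 1)
    t90 = _interp_crossing(t_ms, post, 0.90 * dm, 0, peak_idx + 1)
    return (dm, t10, t90 - t10)


# --------------------------------------------------------------------------
# Session-level extraction
# --------------------------------------------------------------------------

def extract_session(session: SessionRecording,
                    analysis_window_ms: float = 500.0,
                    baseline_ms: float = 50.0,
                    cutoff: float = 15.0, order: int = 4,
                    min_displacement: float = 0.1) -> pd.DataFrame:
    """Extract the per-twitch parameter table of one session.

    Returns a long-format frame with columns subject, timepoint, Pt, Dm,
    Td, Tc — one row per scheduled timepoint.
    """
    rows = []
    for label, rec in session.recordings.items():
        pt = twitch_peak_torque(rec, analysis_window_ms, baseline_ms,
                                cutoff, order)
        dm, td, tc = displacement_params(
            rec, baseline_ms, min_displacement=min_displacement)
        rows.append({"subject": session.subject_id, "timepoint": label,
                     "Pt": pt, "Dm": dm, "Td": td, "Tc": tc})
    return pd.DataFrame(rows)


def extract_cohort(cohort: list[SessionRecording],
                   **kwargs) -> pd.DataFrame:
    """Concatenate :func:`extract_session` over a cohort."""
    return pd.concat([extract_session(s, **kwargs) for s in cohort],
                     ignore_index=True)


def extract_fatigue_indices(cohort: list[SessionRecording],
                            window: int = 501,
                            floor: float = 20.0) -> pd.DataFrame:
    """Per-subject fatigue index from the first and last MVIC trace."""
    from .metrics import fatigue_index

    rows = []
    for session in cohort:
        first = extract_mvic(session.mvic_traces[0].torque, window, floor)
        last = extract_mvic(session.mvic_traces[-1].torque, window, floor)
        rows.append({"subject": session.subject_id,
                     "first_mvic": first, "last_mvic": last,
                     "fi": fatigue_index(first, last)})
    return pd.DataFrame(rows)
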