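"""Synthetic twitch-session generator.

Produces per-subject recordings of an electrically evoked twitch protocol:
stimulus-triggered torque (Nm) and radial muscle-belly displacement (mm)
traces at every timepoint of a potentiation/fatigue schedule, plus the
voluntary-contraction (MVIC) torque traces of the exercise itself.

The generator is calibrated so that the *downstream* pipeline recovers
realistic baselines (peak twitch torque ~19.4 +/- 8.5 Nm, displacement
~3.0 +/- 1.8 mm) and a potentiation-to-fatigue trajectory of peak twitch
torque: +44.1% after the first exercise set, -32.9% after the last set,
and -26.4% residual depression 15 min post-exercise.  Displacement
amplitudes follow the same trajectory attenuated by ``displacement_coupling``,
emulating the empirical finding that radial displacement responds less to
potentiation and fatigue than torque does.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TwitchShape",
    "SimulationConfig",
    "SessionRecording",
    "MvicTrace",
    "DEFAULT_SCHEDULE",
    "DEFAULT_BASELINE_MEANS",
    "DEFAULT_BASELINE_SDS",
    "generate_twitch_waveform",
    "trajectory_multiplier",
    "simulate_cohort",
    "write_cohort",
    "read_signal_csv",
]


class ConfigurationError(ValueError):
    """Invalid simulator or extraction configuration."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TwitchShape:
    """Bi-exponential twitch waveform parameters.

    The waveform is zero before ``onset_delay`` and follows
    ``A * (exp(-(t-d)/tau_decay) - exp(-(t-d)/tau_rise))`` afterwards,
    rescaled so its maximum equals ``amplitude``.

    Parameters
    ----------
    amplitude
        Peak value in native units (Nm for torque, mm for displacement).
    tau_rise, tau_decay
        Rise and decay time constants in ms; ``tau_decay > tau_rise > 0``.
    onset_delay
        Latency from the stimulus to contraction onset, ms.
    """

    amplitude: float
    tau_rise: float
    tau_decay: float
    onset_delay: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be >= 0")
        if not (self.tau_decay > self.tau_rise > 0):
            raise ConfigurationError("need tau_decay > tau_rise > 0")
        if self.onset_delay < 0:
            raise ConfigurationError("onset_delay must be >= 0")

    @property
    def peak_time(self) -> float:
        """Analytic time of the waveform maximum, ms from the stimulus."""
        r, d = self.tau_rise, self.tau_decay
        return self.onset_delay + (r * d / (d - r)) * np.log(d / r)


DEFAULT_SCHEDULE: tuple[str, ...] = (
    "Pre1", "Pre2",
    "Set1", "Set2", "Set3", "Set4", "Set5", "Set6", "Set7",
    "Post0", "Post1", "Post3", "Post5", "Post7", "Post9",
    "Post11", "Post13", "Post15",
)

# Baseline (first pre-exercise measurement) population means and SDs of the
# four extracted twitch parameters: peak twitch torque Pt (Nm), maximal
# displacement Dm (mm), delay time Td (ms), contraction time Tc (ms).
DEFAULT_BASELINE_MEANS: dict[str, float] = {
    "Pt": 19.47, "Dm": 3.06, "Td": 20.45, "Tc": 21.64,
}
DEFAULT_BASELINE_SDS: dict[str, float] = {
    "Pt": 8.49, "Dm": 1.86, "Td": 4.21, "Tc": 2.41,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a simulated potentiation/fatigue session.

    ``potentiation_peak``, ``fatigue_floor`` and ``recovery_residual`` are the
    fractional changes of peak twitch torque at the first exercise set, the
    last exercise set and the final recovery timepoint.  Displacement
    amplitudes receive the attenuated multiplier
    ``1 + displacement_coupling * (m - 1)``.

    ``between_subject_sd`` scales the population SDs used for per-subject
    baselines (1.0 reproduces the default spread); ``within_subject_sd`` is
    the coefficient of variation of the multiplicative lognormal trial-to-
    trial noise on twitch amplitudes and timing, and is what limits
    test-retest reliability downstream.
    """

    n_subjects: int = 16
    sample_rate: float = 1000.0
    schedule: tuple[str, ...] = DEFAULT_SCHEDULE
    baseline_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_MEANS))
    baseline_sds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_SDS))
    between_subject_sd: float = 1.0
    within_subject_sd: float = 0.03
    potentiation_peak: float = 0.441
    fatigue_floor: float = 0.329
    recovery_residual: float = 0.264
    displacement_coupling: float = 0.5
    mvic_start: float = 200.0
    fi_mean: float = 39.8
    fi_sd: float = 11.5
    trace_noise_torque: float = 0.05
    trace_noise_displacement: float = 0.005
    twitch_duration_ms: float = 1000.0
    pre_stimulus_ms: float = 100.0
    mvic_duration_s: float = 2.0
    n_mvic_per_set: tuple[int, ...] = (5, 5, 10, 10, 10, 10, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be > 0")
        for name in ("potentiation_peak", "fatigue_floor",
                     "recovery_residual", "displacement_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        labels = list(self.schedule)
        if "Pre1" not in labels or "Pre2" not in labels:
            raise ConfigurationError("schedule must contain Pre1 and Pre2")
        if not any(lbl.startswith("Post") for lbl in labels):
            raise ConfigurationError(
                "schedule must contain at least one post-exercise label")
        if len(set(labels)) != len(labels):
            raise ConfigurationError("schedule labels must be unique")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class TwitchRecording:
    """One stimulus-locked trial: synchronized torque, trigger and
    displacement traces plus the stimulus sample index."""

    torque: np.ndarray
    displacement: np.ndarray
    trigger: np.ndarray
    sample_rate: float
    stim_index: int

    def __post_init__(self) -> None:
        n = len(self.torque)
        if len(self.displacement) != n or len(self.trigger) != n:
            raise ConfigurationError("all traces must share one length")
        if not 0 <= self.stim_index < n:
            raise ConfigurationError("stim_index outside trace")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be > 0")


@dataclass
class MvicTrace:
    """One voluntary contraction: torque trace plus its (set, rep) label."""

    torque: np.ndarray
    set_index: int
    rep_index: int


@dataclass
class SessionRecording:
    """All recordings of one subject's session, keyed by timepoint label."""

    subject_id: str
    recordings: dict[str, TwitchRecording]
    mvic_traces: list[MvicTrace]
    sample_rate: float


# --------------------------------------------------------------------------
# Waveform synthesis
# --------------------------------------------------------------------------

def generate_twitch_waveform(shape: TwitchShape, duration_ms: float,
                             sample_rate: float) -> np.ndarray:
    """Sample a bi-exponential twitch waveform.

    The trace is zero before ``shape.onset_delay`` and rescaled so that the
    continuous-time maximum equals ``shape.amplitude``.

    Parameters
    ----------
    shape
        Waveform parameters.
    duration_ms
        Trace length, ms; must contain the peak
        (``>= 5 * tau_decay + onset_delay``).
    sample_rate
        Sampling rate, Hz.
    """
    if sample_rate <= 0:
        raise ConfigurationError("sample_rate must be > 0")
    if duration_ms < 5 * shape.tau_decay + shape.onset_delay:
        raise ConfigurationError(
            "duration too short: need >= 5*tau_decay + onset_delay")
    n = int(round(duration_ms * sample_rate / 1000.0))
    t = np.arange(n) * 1000.0 / sample_rate  # ms
    out = np.zeros(n)
    if shape.amplitude == 0:
        return out
    s = t - shape.onset_delay
    active = s > 0
    r, d = shape.tau_rise, shape.tau_decay
    raw = np.exp(-s[active] / d) - np.exp(-s[active] / r)
    # rescale by the sampled maximum so the trace's own peak equals the
    # configured amplitude exactly regardless of grid placement
    out[active] = shape.amplitude * raw / raw.max()
    return out


def _normalized_crossings(ratio: float) -> tuple[float, float]:
    """10% and 90% upward crossing times of the unit-tau_rise bi-exponential
    with tau_decay = ratio, measured from onset (unit: tau_rise)."""
    shape = TwitchShape(amplitude=1.0, tau_rise=1.0, tau_decay=ratio)
    s_peak = shape.peak_time
    peak_val = np.exp(-s_peak / ratio) - np.exp(-s_peak)

    def f(s: float, level: float) -> float:
        return (np.exp(-s / ratio) - np.exp(-s)) / peak_val - level

    t10 = brentq(f, 1e-9, s_peak, args=(0.1,))
    t90 = brentq(f, t10, s_peak, args=(0.9,))
    return t10, t90


def shape_from_targets(amplitude: float, td_ms: float, tc_ms: float,
                       decay_ratio: float = 3.0) -> TwitchShape:
    """Invert the waveform family: choose (tau_rise, onset_delay) so that the
    extracted delay time (stimulus to 10% of peak) equals ``td_ms`` and the
    contraction time (10% to 90% of peak) equals ``tc_ms``.

    ``decay_ratio`` fixes tau_decay / tau_rise.  The onset delay is clipped
    at zero, so very short target delay times may extract slightly long.
    """
    t10, t90 = _normalized_crossings(decay_ratio)
    tau_rise = tc_ms / (t90 - t10)
    onset = max(td_ms - tau_rise * t10, 0.0)
    return TwitchShape(amplitude=amplitude, tau_rise=tau_rise,
                       tau_decay=decay_ratio * tau_rise, onset_delay=onset)


# --------------------------------------------------------------------------
# Trajectory
# --------------------------------------------------------------------------

def _schedule_positions(schedule: tuple[str, ...]):
    sets = sorted((lbl for lbl in schedule if lbl.startswith("Set")),
                  key=lambda s: int(s[3:]))
    posts = sorted((lbl for lbl in schedule if lbl.startswith("Post")),
                   key=lambda s: int(s[4:]))
    return sets, posts


def trajectory_multiplier(timepoint: str, config: SimulationConfig) -> float:
    """Deterministic peak-twitch-torque multiplier at one timepoint.

    Pre-exercise timepoints map to 1.  The first exercise set carries the
    potentiation peak (``1 + potentiation_peak``); subsequent sets decline
    linearly in set number to the fatigue floor (``1 - fatigue_floor``) at
    the last set.  Recovery is linear in minutes post-exercise from the
    fatigue floor to the residual (``1 - recovery_residual``) at the last
    post label.
    """
    if timepoint not in config.schedule:
        raise KeyError(f"unknown timepoint label: {timepoint!r}")
    if timepoint.startswith("Pre"):
        return 1.0
    sets, posts = _schedule_positions(config.schedule)
    peak = 1.0 + config.potentiation_peak
    floor = 1.0 - config.fatigue_floor
    residual = 1.0 - config.recovery_residual
    if timepoint.startswith("Set"):
        if len(sets) == 1:
            return peak
        i = sets.index(timepoint)
        return peak + (floor - peak) * i / (len(sets) - 1)
    # Post-exercise recovery, linear in minutes
    minutes = np.array([float(p[4:]) for p in posts])
    m = float(timepoint[4:])
    last = minutes.max()
    if last == 0:
        return floor
    return floor + (residual - floor) * m / last


# --------------------------------------------------------------------------
# Cohort simulation
# --------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, size: int) -> np.ndarray:
    """Normal draws redrawn until above ``low`` (rejection sampling)."""
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = out <= low
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, low + 1e-9, None)


def _lognormal_factor(rng: np.random.Generator, cv: float,
                      size=None) -> np.ndarray | float:
    """Unit-median multiplicative noise with coefficient of variation cv."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv ** 2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def _mvic_trace(rng: np.random.Generator, plateau: float, config:
                SimulationConfig) -> np.ndarray:
    """A single voluntary contraction: ramp up, noisy plateau, ramp down."""
    fs = config.sample_rate
    n = int(round(config.mvic_duration_s * fs))
    n_ramp = max(int(round(0.25 * fs)), 2)
    n_plateau = n - 2 * n_ramp
    trace = np.concatenate([
        np.linspace(0.0, plateau, n_ramp, endpoint=False),
        np.full(n_plateau, plateau),
        np.linspace(plateau, 0.0, n_ramp),
    ])
    trace += rng.normal(0.0, config.trace_noise_torque, len(trace))
    return trace


# Torque twitch timing: time-to-peak of an evoked knee-extensor twitch is on
# the order of 75 ms; these taus put the analytic peak near that value.
_TORQUE_TAU_RISE = 25.0
_TORQUE_DECAY_RATIO = 3.0
_TORQUE_ONSET_MS = 10.0


def simulate_cohort(config: SimulationConfig) -> list[SessionRecording]:
    """Simulate a full cohort of potentiation/fatigue sessions.

    Per subject: baseline twitch parameters are drawn from the configured
    population distributions; at every scheduled timepoint a twitch torque
    and displacement waveform pair is synthesized with amplitude = baseline
    x trajectory multiplier x lognormal trial noise; MVIC plateaus decline
    linearly through the exercise so the fatigue index (percent decline from
    first to last MVIC) follows the configured distribution truncated to
    [0, 100].

    Deterministic for a given config (including ``config.seed``).
    """
    rng = np.random.default_rng(config.seed)
    means, sds = config.baseline_means, config.baseline_sds
    bss = config.between_subject_sd
    n = config.n_subjects

    pt0 = _truncated_normal(rng, means["Pt"], bss * sds["Pt"], 1.0, n)
    dm0 = _truncated_normal(rng, means["Dm"], bss * sds["Dm"], 0.2, n)
    td0 = _truncated_normal(rng, means["Td"], bss * sds["Td"], 5.0, n)
    tc0 = _truncated_normal(rng, means["Tc"], bss * sds["Tc"], 8.0, n)
    fi = np.clip(rng.normal(config.fi_mean, config.fi_sd, n), 0.0, 100.0)
    mvic0 = _truncated_normal(rng, config.mvic_start,
                              0.15 * config.mvic_start, 50.0, n)

    fs = config.sample_rate
    n_samples = int(round(config.twitch_duration_ms * fs / 1000.0))
    stim_index = int(round(config.pre_stimulus_ms * fs / 1000.0))
    pulse_len = max(int(round(0.001 * fs)), 1)  # 1 ms stimulus pulse
    cv = config.within_subject_sd

    cohort: list[SessionRecording] = []
    for i in range(n):
        recordings: dict[str, TwitchRecording] = {}
        for label in config.schedule:
            m = trajectory_multiplier(label, config)
            md = 1.0 + config.displacement_coupling * (m - 1.0)
            pt = pt0[i] * m * _lognormal_factor(rng, cv)
            dm = dm0[i] * md * _lognormal_factor(rng, cv)
            td = td0[i] * _lognormal_factor(rng, cv)
            tc = tc0[i] * _lognormal_factor(rng, cv)

            torque_shape = TwitchShape(
                amplitude=pt, tau_rise=_TORQUE_TAU_RISE,
                tau_decay=_TORQUE_TAU_RISE * _TORQUE_DECAY_RATIO,
                onset_delay=_TORQUE_ONSET_MS)
            disp_shape = shape_from_targets(dm, td, tc)

            span = config.twitch_duration_ms - config.pre_stimulus_ms
            torque = np.zeros(n_samples)
            disp = np.zeros(n_samples)
            torque[stim_index:] = generate_twitch_waveform(
                torque_shape, span, fs)[:n_samples - stim_index]
            disp[stim_index:] = generate_twitch_waveform(
                disp_shape, span, fs)[:n_samples - stim_index]
            torque += rng.normal(0.0, config.trace_noise_torque, n_samples)
            disp += rng.normal(0.0, config.trace_noise_displacement,
                               n_samples)
            trigger = np.zeros(n_samples)
            trigger[stim_index:stim_index + pulse_len] = 1.0
            recordings[label] = TwitchRecording(
                torque=torque, displacement=disp, trigger=trigger,
                sample_rate=fs, stim_index=stim_index)

        # MVIC plateaus decline linearly from first to last contraction
        n_total = sum(config.n_mvic_per_set)
        first, last = mvic0[i], mvic0[i] * (1.0 - fi[i] / 100.0)
        plateaus = np.linspace(first, last, n_total)
        mvic_traces: list[MvicTrace] = []
        k = 0
        for set_idx, n_reps in enumerate(config.n_mvic_per_set, start=1):
            for rep in range(1, n_reps + 1):
                mvic_traces.append(MvicTrace(
                    torque=_mvic_trace(rng, plateaus[k], config),
                    set_index=set_idx, rep_index=rep))
                k += 1

        cohort.append(SessionRecording(
            subject_id=f"S{i + 1:02d}", recordings=recordings,
            mvic_traces=mvic_traces, sample_rate=fs))
    return cohort


# --------------------------------------------------------------------------
# External interfaces: CSV writer / reader
# --------------------------------------------------------------------------

SIGNAL_COLUMNS = ("time_s", "torque_Nm", "trigger", "displacement_mm")


def _signal_frame(rec: TwitchRecording):
    import pandas as pd

    t = np.arange(len(rec.torque)) / rec.sample_rate
    return pd.DataFrame({
        "time_s": t, "torque_Nm": rec.torque,
        "trigger": rec.trigger, "displacement_mm": rec.displacement,
    })


def write_cohort(cohort: list[SessionRecording], out_dir: str | Path,
                 config: SimulationConfig | None = None) -> Path:
    """Write one CSV per (subject, timepoint) plus a cohort manifest.

    Returns the manifest path.  If ``config`` is given it is stored next to
    the manifest as a flat key-value text file.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for session in cohort:
        for label, rec in session.recordings.items():
            fname = f"{session.subject_id}_{label}.csv"
            _signal_frame(rec).to_csv(out_dir / fname, index=False)
            rows.append({"subject_id": session.subject_id,
                         "timepoint": label, "path": fname})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if config is not None:
        with open(out_dir / "simulation_config.txt", "w") as fh:
            for key in ("n_subjects", "sample_rate", "within_subject_sd",
                        "between_subject_sd", "potentiation_peak",
                        "fatigue_floor", "recovery_residual",
                        "displacement_coupling", "fi_mean", "fi_sd", "seed"):
                fh.write(f"{key} = {getattr(config, key)}\n")
            fh.write("schedule = " + ",".join(config.schedule) + "\n")
    return manifest


def read_signal_csv(path_or_buf: str | Path | io.IOBase,
                    trigger_threshold: float = 0.5) -> TwitchRecording:
    """Read one signal CSV (columns time_s, torque_Nm, trigger,
    displacement_mm) back into a TwitchRecording.

    The stimulus index is the first rising edge of the trigger channel.
    """
    import pandas as pd

    from .signals import detect_triggers

    df = pd.read_csv(path_or_buf)
    missing = set(SIGNAL_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"signal CSV missing columns: {missing}")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ConfigurationError("signal CSV must have >= 2 samples")
    fs = 1.0 / np.median(np.diff(t))
    trig = df["trigger"].to_numpy()
    edges = detect_triggers(trig, trigger_threshold)
    if not edges:
        raise ConfigurationError("no stimulus trigger found in recording")
    return TwitchRecording(
        torque=df["torque_Nm"].to_numpy(),
        displacement=df["displacement_mm"].to_numpy(),
        trigger=trig, sample_rate=float(fs), stim_index=edges[0])
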