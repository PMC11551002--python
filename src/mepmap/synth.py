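"""Synthetic TMS-EMG experiment generator with known ground truth.

The generator embodies the statistical structure the downstream analysis
assumes, via a minimal mechanistic model of corticospinal recruitment:

* an effective *drive* combining stimulation intensity, Gaussian decay of
  effective stimulation with scalp distance from the FDI hotspot, and a
  von-Mises-shaped coil-orientation tuning factor peaking at the preferred
  induced-current direction (45 deg, "North-East");
* a sigmoidal recruitment of mean MEP amplitude above a task-dependent
  threshold — during natural dynamic movement the threshold drops to a
  fixed fraction (default 0.61) of the resting threshold;
* MEP latency decreasing from ``latency_max_ms`` to ``latency_min_ms``
  along the same sigmoid (stronger effective stimulation recruits faster
  pathways), plus Gaussian trial jitter;
* task-dependent background EMG (band-limited 10-500 Hz noise at the
  task's RMS, amplitude-modulated at 0.5-3 Hz for the dynamic task to
  mimic movement bursts) with a damped-sinusoid biphasic MEP template
  added at trigger + latency.

Only the template's peak-to-peak amplitude and onset are contractually
meaningful; its exact shape is cosmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal
from scipy.special import expit

from .emg import ContinuousRecord, EpochSet

__all__ = [
    "TASKS",
    "GeneratorConfig",
    "ExperimentDesign",
    "drive",
    "tuning",
    "task_threshold",
    "mean_amplitude",
    "mean_latency",
    "mep_amplitude_and_latency",
    "mep_template",
    "generate_continuous",
    "generate_experiment",
]

TASKS = ("rest", "isotonic", "dynamic")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic corticospinal-excitability model.

    Intensity and ``rmt_drive`` share a %MSO-like unitless scale: at the
    hotspot with the preferred coil orientation, drive equals intensity, so
    ``rmt_drive`` is the resting recruitment threshold in stimulator-output
    units.  ``slope`` is the sigmoid slope on that scale.
    """

    sampling_rate: float = 5000.0           # Hz
    hotspot_xy: tuple[float, float] = (-51.0, 1.0)  # mm, Cz-referenced (left M1-hand)
    sigma_space: float = 42.0               # mm spatial decay of effective stimulation
    theta_pref: float = 45.0                # deg, preferred induced-current direction (NE)
    kappa_orient: float = 2.0               # orientation-tuning concentration
    rmt_drive: float = 55.0                 # resting threshold on the drive (%MSO) scale
    active_threshold_ratio: float = 0.61    # dynamic-task threshold / resting threshold
    slope: float = 2.0                      # sigmoid slope (drive units)
    amp_max_mV: float = 2.0                 # maximal mean MEP amplitude
    latency_min_ms: float = 21.5
    latency_max_ms: float = 25.5
    latency_jitter_ms: float = 1.0          # per-trial Gaussian SD
    background_rms_mV: dict = field(
        default_factory=lambda: {"rest": 0.005, "isotonic": 0.05, "dynamic": 0.1}
    )
    burst_mod: float = 0.8                  # amplitude-modulation depth, dynamic task
    trial_noise_sigma: float = 0.5          # log-normal SD of per-trial amplitude
    hotspot_jitter_mm: float = 7.0          # per-participant hotspot SD per axis
    rmt_jitter: float = 5.0                 # per-participant resting-threshold SD
    participant_latency_sd_ms: float = 1.0  # per-participant latency offset SD
    template_freq_hz: float = 120.0
    template_decay_ms: float = 3.0
    template_dur_ms: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate < 1000:
            raise ValueError("sampling_rate must be >= 1000 Hz")
        if not 0 < self.active_threshold_ratio <= 1:
            raise ValueError("active_threshold_ratio must be in (0, 1]")
        if not self.latency_min_ms < self.latency_max_ms:
            raise ValueError("latency_min_ms must be < latency_max_ms")
        if any(v < 0 for v in self.background_rms_mV.values()):
            raise ValueError("background RMS values must be >= 0")
        if self.sigma_space <= 0 or self.slope <= 0 or self.amp_max_mV <= 0:
            raise ValueError("sigma_space, slope and amp_max_mV must be > 0")


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial design: tasks x locations x orientations x intensities.

    ``locations`` is a list of ``(id, x_mm, y_mm)`` scalp sites;
    ``intensities`` are interpreted per ``intensity_unit``: absolute
    "%MSO", or "%RMT" relative to each simulated participant's own resting
    threshold (as experiments calibrate intensity to the measured RMT).
    """

    n_participants: int
    tasks: tuple[str, ...]
    locations: tuple[tuple[object, float, float], ...]
    orientations: tuple[float, ...]
    intensities: tuple[float, ...]
    n_trials: int
    intensity_unit: str = "%RMT"
    muscles: tuple[str, ...] = ("FDI_R",)

    def __post_init__(self) -> None:
        if (
            self.n_participants < 1
            or not self.tasks
            or not self.locations
            or not self.orientations
            or not self.intensities
            or self.n_trials < 1
        ):
            raise ValueError("design must be non-empty in every factor")
        if self.intensity_unit not in ("%MSO", "%RMT"):
            raise ValueError("intensity_unit must be '%MSO' or '%RMT'")
        bad = set(self.tasks) - set(TASKS)
        if bad:
            raise ValueError(f"unknown task(s): {sorted(bad)}")


# ---------------------------------------------------------------------------
# the drive model


def tuning(theta_deg, config: GeneratorConfig):
    """Von-Mises-shaped orientation factor in (0, 1], 1 at theta_pref."""
    d = np.deg2rad(np.asarray(theta_deg, dtype=float) - config.theta_pref)
    return np.exp(config.kappa_orient * (np.cos(d) - 1.0))


def drive(intensity, coil_xy, theta_deg, config: GeneratorConfig):
    """Effective corticospinal drive of a pulse.

    drive = intensity * exp(-||coil - hotspot||^2 / (2 sigma^2)) * tuning(theta)
    """
    coil = np.asarray(coil_xy, dtype=float)
    hot = np.asarray(config.hotspot_xy, dtype=float)
    d2 = np.sum((coil - hot) ** 2, axis=-1)
    return (
        np.asarray(intensity, dtype=float)
        * np.exp(-d2 / (2.0 * config.sigma_space**2))
        * tuning(theta_deg, config)
    )


def task_threshold(task: str, config: GeneratorConfig, rmt_drive: float | None = None) -> float:
    """Recruitment threshold for a task state (dynamic movement lowers it)."""
    rmt = config.rmt_drive if rmt_drive is None else rmt_drive
    if task in ("rest", "isotonic"):
        return rmt
    if task == "dynamic":
        return rmt * config.active_threshold_ratio
    raise ValueError(f"unknown task state: {task!r}")


def mean_amplitude(drive_value, task, config, rmt_drive=None):
    t = task_threshold(task, config, rmt_drive)
    return config.amp_max_mV * expit((np.asarray(drive_value, dtype=float) - t) / config.slope)


def mean_latency(drive_value, task, config, rmt_drive=None):
    t = task_threshold(task, config, rmt_drive)
    s = expit((np.asarray(drive_value, dtype=float) - t) / config.slope)
    return config.latency_max_ms - (config.latency_max_ms - config.latency_min_ms) * s


def mep_amplitude_and_latency(drive_value, task, config, rng, rmt_drive=None):
    """Draw per-trial MEP amplitude (mV) and latency (ms).

    amplitude = mean * LogNormal(0, trial_noise_sigma);
    latency = mean latency + Gaussian jitter.
    """
    d = np.asarray(drive_value, dtype=float)
    amp = mean_amplitude(d, task, config, rmt_drive) * rng.lognormal(
        0.0, config.trial_noise_sigma, size=d.shape
    )
    lat = mean_latency(d, task, config, rmt_drive) + rng.normal(
        0.0, config.latency_jitter_ms, size=d.shape
    )
    return amp, lat


# ---------------------------------------------------------------------------
# waveform synthesis


def mep_template(config: GeneratorConfig) -> np.ndarray:
    """Damped-sinusoid biphasic MEP waveform, normalised to peak-to-peak 1."""
    fs = config.sampling_rate
    t = np.arange(0.0, config.template_dur_ms / 1000.0, 1.0 / fs)
    w = np.sin(2 * np.pi * config.template_freq_hz * t) * np.exp(
        -t / (config.template_decay_ms / 1000.0)
    )
    return w / (w.max() - w.min())


@lru_cache(maxsize=8)
def _background_filter(fs: float):
    """Online-acquisition emulation: 10-500 Hz band-limited noise shaping.

    Returns (sos, gain) where gain is the output RMS of unit white noise
    through the zero-phase filter, computed from the frequency response.
    """
    high = min(500.0, 0.45 * fs)
    sos = signal.butter(2, [10.0, high], btype="bandpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=8192)
    gain = float(np.sqrt(np.mean(np.abs(h) ** 4)))  # filtfilt applies |H|^2
    return sos, gain


def _background(rng, shape, task, config: GeneratorConfig, times_s=None):
    rms = config.background_rms_mV[task]
    if rms == 0:
        return np.zeros(shape)
    sos, gain = _background_filter(config.sampling_rate)
    x = signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1) * (rms / gain)
    if task == "dynamic" and config.burst_mod > 0:
        if times_s is None:
            times_s = np.arange(shape[-1]) / config.sampling_rate
        f = rng.uniform(0.5, 3.0, size=shape[:-1] + (1,))
        phi = rng.uniform(0, 2 * np.pi, size=shape[:-1] + (1,))
        env = 1.0 + config.burst_mod * np.sin(2 * np.pi * f * times_s + phi)
        x = x * env / np.sqrt(1.0 + config.burst_mod**2 / 2.0)
    return x


def _add_template(traces, onsets_ms, amps, template, fs, t0_idx):
    """Add amp-scaled templates at t0 + onset per trial, in place."""
    n = traces.shape[-1]
    for i in range(traces.shape[0]):
        j = t0_idx + int(round(onsets_ms[i] / 1000.0 * fs))
        if j >= n or j < 0:
            continue
        seg = min(template.size, n - j)
        traces[i, j : j + seg] += amps[i] * template[:seg]


def generate_continuous(
    task: str,
    n_triggers: int,
    inter_trigger_s: float,
    config: GeneratorConfig,
    coil_xy=None,
    theta: float | None = None,
    intensity: float | None = None,
    rng=None,
):
    """Continuous single-channel record with triggers and ground truth.

    Pulses are delivered at the hotspot with the preferred orientation at
    110% of the resting threshold unless overridden.  The record covers all
    triggers with a 300 ms margin at both ends.
    """
    if n_triggers < 1:
        raise ValueError("n_triggers must be >= 1")
    if task not in TASKS:
        raise ValueError(f"unknown task state: {task!r}")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    coil_xy = config.hotspot_xy if coil_xy is None else coil_xy
    theta = config.theta_pref if theta is None else theta
    intensity = 1.1 * config.rmt_drive if intensity is None else intensity

    fs = config.sampling_rate
    margin = 0.3
    triggers = margin + np.arange(n_triggers) * inter_trigger_s
    n_samp = int(round((triggers[-1] + margin) * fs)) + 1
    d = float(drive(intensity, coil_xy, theta, config))
    amps, lats = mep_amplitude_and_latency(np.full(n_triggers, d), task, config, rng)

    data = _background(rng, (1, n_samp), task, config)[0]
    template = mep_template(config)
    for k in range(n_triggers):
        j = int(round((triggers[k] + lats[k] / 1000.0) * fs))
        seg = min(template.size, n_samp - j)
        if seg > 0:
            data[j : j + seg] += amps[k] * template[:seg]

    record = ContinuousRecord(data[None, :], fs, ["FDI_R"], triggers)
    truth = pd.DataFrame(
        {
            "trigger": np.arange(n_triggers),
            "task": task,
            "drive": d,
            "true_amp_mV": amps,
            "true_latency_ms": lats,
        }
    )
    return record, truth


# ---------------------------------------------------------------------------
# full factorial experiments


def _participant_rng(config: GeneratorConfig, p_index: int):
    # one global stream per dataset, split per participant by seed offset,
    # so each participant's data are reproducible in isolation
    return np.random.default_rng([int(config.seed), int(p_index)])


def generate_experiment(design: ExperimentDesign, config: GeneratorConfig):
    """Generate the full factorial EpochSet plus per-trigger ground truth.

    Per participant the hotspot and resting threshold are jittered around
    the config values (SDs ``hotspot_jitter_mm`` per axis, ``rmt_jitter``),
    and a latency offset is drawn, emulating anatomical variation.
    """
    fs = config.sampling_rate
    n_pre = int(round(fs * 0.2))
    n_time = 2 * n_pre + 1
    times_ms = (np.arange(n_time) - n_pre) / fs * 1000.0
    times_s = np.arange(n_time) / fs
    template = mep_template(config)

    all_epochs, meta_rows, truth_rows = [], [], []
    trigger_id = 0
    for p in range(design.n_participants):
        rng = _participant_rng(config, p)
        hotspot_p = np.asarray(config.hotspot_xy) + rng.normal(
            0.0, config.hotspot_jitter_mm, size=2
        )
        rmt_p = max(20.0, config.rmt_drive + rng.normal(0.0, config.rmt_jitter))
        lat_off_p = rng.normal(0.0, config.participant_latency_sd_ms)
        cfg_p = replace(config, hotspot_xy=tuple(hotspot_p))
        pid = f"P{p + 1:02d}"

        for task in design.tasks:
            for loc_id, x, y in design.locations:
                for theta in design.orientations:
                    for inten in design.intensities:
                        i_mso = (
                            inten
                            if design.intensity_unit == "%MSO"
                            else inten / 100.0 * rmt_p
                        )
                        d = float(drive(i_mso, (x, y), theta, cfg_p))
                        for muscle in design.muscles:
                            amps, lats = mep_amplitude_and_latency(
                                np.full(design.n_trials, d), task, config, rng,
                                rmt_drive=rmt_p,
                            )
                            lats = lats + lat_off_p
                            traces = _background(
                                rng, (design.n_trials, n_time), task, config, times_s
                            )
                            _add_template(traces, lats, amps, template, fs, n_pre)
                            all_epochs.append(traces)
                            for k in range(design.n_trials):
                                meta_rows.append(
                                    {
                                        "trigger": trigger_id,
                                        "participant": pid,
                                        "muscle": muscle,
                                        "task": task,
                                        "location": loc_id,
                                        "orientation": theta,
                                        "intensity": inten,
                                        "intensity_mso": i_mso,
                                    }
                                )
                                truth_rows.append(
                                    {
                                        "trigger": trigger_id,
                                        "participant": pid,
                                        "drive": d,
                                        "true_amp_mV": amps[k],
                                        "true_latency_ms": lats[k],
                                        "rmt_drive": rmt_p,
                                        "hotspot_x": hotspot_p[0],
                                        "hotspot_y": hotspot_p[1],
                                    }
                                )
                                trigger_id += 1

    epochs = np.concatenate(all_epochs, axis=0)
    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    return EpochSet(epochs, times_ms, meta, fs), truth
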