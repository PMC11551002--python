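"""Continuous EMG handling: filtering, epoching and event-related averaging.

The conventions follow standard TMS-EMG practice: continuous surface EMG in
mV with hardware trigger times marking TMS pulses, epochs cut 200 ms either
side of the pulse, and offline zero-phase band-pass filtering at 25-250 Hz
(a forward-backward second-order Butterworth, effective order four).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

log = logging.getLogger(__name__)

__all__ = [
    "ContinuousRecord",
    "EpochSet",
    "bandpass",
    "bandpass_epochs",
    "segment",
    "event_related_average",
]


@dataclass
class ContinuousRecord:
    """Multi-channel continuous EMG with TMS trigger times.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        EMG in mV.
    sampling_rate : float
        Hz; surface EMG for MEP work is digitised at 1-20 kHz.
    channels : list of str
        Muscle labels, one per row of ``data``.
    triggers_s : ndarray
        TMS pulse times in seconds, strictly increasing.
    """

    data: np.ndarray
    sampling_rate: float
    channels: list[str]
    triggers_s: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.triggers_s = np.asarray(self.triggers_s, dtype=float)
        if not (1000 <= self.sampling_rate <= 20000):
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz outside [1000, 20000]"
            )
        if self.data.shape[0] != len(self.channels):
            raise ValueError("one channel label per data row required")
        if self.triggers_s.size and np.any(np.diff(self.triggers_s) <= 0):
            raise ValueError("trigger times must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.sampling_rate

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) / self.sampling_rate


@dataclass
class EpochSet:
    """Trials of EMG time-locked to the TMS pulse at t = 0 ms.

    ``epochs`` is (n_trials, n_samples); ``meta`` has one row per trial with
    the full condition labels (participant, muscle, task, location,
    orientation, intensity, ...).  All trials share ``times_ms``.
    """

    epochs: np.ndarray
    times_ms: np.ndarray
    meta: pd.DataFrame
    sampling_rate: float

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.epochs.shape[1] != self.times_ms.size:
            raise ValueError("epochs and time axis lengths differ")
        if len(self.meta) != self.epochs.shape[0]:
            raise ValueError("one metadata row per trial required")
        if not np.isclose(np.abs(self.times_ms).min(), 0.0):
            raise ValueError("time axis must include 0 (the TMS pulse)")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask of samples with window[0] <= t <= window[1] ms."""
        lo, hi = window
        return (self.times_ms >= lo) & (self.times_ms <= hi)

    def select(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            self.epochs[np.asarray(mask)],
            self.times_ms,
            self.meta.loc[np.asarray(mask)].reset_index(drop=True),
            self.sampling_rate,
        )


def _butter_sos(low: float, high: float, order: int, fs: float):
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got {low}, {high}")
    if high >= fs / 2:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {fs / 2} Hz")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(
    record: ContinuousRecord,
    low: float = 25.0,
    high: float = 250.0,
    order: int = 2,
    zero_phase: bool = True,
) -> ContinuousRecord:
    """Band-pass filter a continuous record per channel.

    With ``zero_phase`` the Butterworth is run forward and backward
    (filtfilt), doubling the effective order and cancelling phase delay so
    MEP onset latencies are preserved.
    """
    sos = _butter_sos(low, high, order, record.sampling_rate)
    if zero_phase:
        out = signal.sosfiltfilt(sos, record.data, axis=-1)
    else:
        out = signal.sosfilt(sos, record.data, axis=-1)
    return ContinuousRecord(out, record.sampling_rate, list(record.channels), record.triggers_s)


def bandpass_epochs(
    epoch_set: EpochSet,
    low: float = 25.0,
    high: float = 250.0,
    order: int = 2,
) -> EpochSet:
    """Zero-phase band-pass applied epoch-wise (for data stored as epochs)."""
    sos = _butter_sos(low, high, order, epoch_set.sampling_rate)
    out = signal.sosfiltfilt(sos, epoch_set.epochs, axis=-1)
    return EpochSet(out, epoch_set.times_ms, epoch_set.meta.copy(), epoch_set.sampling_rate)


def segment(
    record: ContinuousRecord,
    pre_ms: float = 200.0,
    post_ms: float = 200.0,
    trial_meta: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut one epoch per trigger, the sample nearest the trigger at t = 0.

    Triggers too close to a record edge to admit the full window are dropped
    with a logged warning (mirroring offline trial-removal practice for
    missed hardware triggers).  ``trial_meta`` may carry one row per trigger
    with condition labels; rows of dropped triggers are dropped with them.
    Channels are stacked trial-wise with a ``muscle`` metadata column.
    """
    fs = record.sampling_rate
    n_pre = int(round(fs * pre_ms / 1000.0))
    n_post = int(round(fs * post_ms / 1000.0))
    n_samp = record.data.shape[1]
    times_ms = (np.arange(n_pre + n_post + 1) - n_pre) / fs * 1000.0

    # nearest sample, ties toward the earlier sample
    idx = np.ceil(record.triggers_s * fs - 0.5).astype(int)
    ok = (idx - n_pre >= 0) & (idx + n_post < n_samp)
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("segment: rejected %d trigger(s) too close to a record edge", n_bad)
        warnings.warn(f"rejected {n_bad} trigger(s) too close to a record edge", stacklevel=2)
    idx = idx[ok]

    epochs, rows = [], []
    for ch, label in enumerate(record.channels):
        for k, i0 in enumerate(idx):
            epochs.append(record.data[ch, i0 - n_pre : i0 + n_post + 1])
            row = {"trigger": int(np.flatnonzero(ok)[k]), "muscle": label,
                   "trigger_time_s": record.triggers_s[ok][k]}
            rows.append(row)
    epochs = np.array(epochs) if epochs else np.empty((0, times_ms.size))
    meta = pd.DataFrame(rows) if rows else pd.DataFrame(columns=["trigger", "muscle", "trigger_time_s"])
    if trial_meta is not None and len(meta):
        extra = trial_meta.reset_index(drop=True).loc[meta["trigger"].to_numpy()]
        extra = extra.reset_index(drop=True)
        for col in extra.columns:
            if col not in meta.columns:
                meta[col] = extra[col].to_numpy()
    return EpochSet(epochs, times_ms, meta, fs)


def event_related_average(epoch_set: EpochSet, group_by: list[str]) -> EpochSet:
    """Point-wise mean across trials within each metadata group.

    Averaging time-locked epochs suppresses background EMG that is not
    phase-locked to the pulse (the event-related average MEP).  The output
    has one trace per group with an ``n_trials`` column.  Empty groups
    cannot arise from groupby; an empty input is a signalled error.
    """
    if epoch_set.n_trials == 0:
        raise ValueError("cannot average an empty EpochSet")
    missing = [k for k in group_by if k not in epoch_set.meta.columns]
    if missing:
        raise KeyError(f"group_by keys missing from metadata: {missing}")
    traces, rows = [], []
    for keys, sub in epoch_set.meta.groupby(list(group_by), sort=True, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        sel = sub.index.to_numpy()
        traces.append(epoch_set.epochs[sel].mean(axis=0))
        row = dict(zip(group_by, keys))
        row["n_trials"] = len(sel)
        rows.append(row)
    return EpochSet(np.array(traces), epoch_set.times_ms, pd.DataFrame(rows), epoch_set.sampling_rate)
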