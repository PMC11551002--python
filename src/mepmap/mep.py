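"""MEP quantification on averaged EMG traces.

Peak-to-peak amplitude in fixed windows (+10..+50 ms after the pulse for
the MEP, -50..-10 ms as the matched pre-TMS control), baseline
threshold-crossing counts, per-participant normalisation, and automatic
onset-latency estimation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .emg import EpochSet, event_related_average

__all__ = [
    "POST_WINDOW",
    "PRE_WINDOW",
    "BASELINE_WINDOW",
    "peak_to_peak",
    "crossing_count_contrast",
    "auto_latency",
    "measure",
    "single_trial_measures",
    "normalize",
]

POST_WINDOW = (10.0, 50.0)
PRE_WINDOW = (-50.0, -10.0)
BASELINE_WINDOW = (-200.0, -50.0)

# normalisation scopes: maximum taken per group of these metadata columns
SCOPES = {
    "participant_muscle": ["participant", "muscle"],
    "participant_muscle_task": ["participant", "muscle", "task"],
}


def _window_slice(times_ms: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    mask = (times_ms >= lo) & (times_ms <= hi)
    if not mask.any():
        raise ValueError(f"window {window} ms contains no samples")
    return mask


def peak_to_peak(trace: np.ndarray, times_ms: np.ndarray, window: tuple[float, float]) -> float:
    """max - min of the trace within the window (endpoints inclusive)."""
    seg = np.asarray(trace, dtype=float)[_window_slice(np.asarray(times_ms), window)]
    return float(seg.max() - seg.min())


def crossing_count_contrast(
    trace: np.ndarray,
    times_ms: np.ndarray,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    post_window: tuple[float, float] = POST_WINDOW,
    pre_window: tuple[float, float] = PRE_WINDOW,
    z: float = 1.96,
):
    """Count samples outside the baseline tolerance band, post vs pre TMS.

    The band is mean +/- z * SD of the baseline samples (a tolerance band
    for individual samples, not a confidence interval of the mean).  A
    degenerate all-constant baseline collapses the band to the mean; the
    counts remain defined.  Returns ``(n_post, n_pre, (lo, hi))``.
    """
    trace = np.asarray(trace, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    base = trace[_window_slice(times_ms, baseline_window)]
    mu, sd = float(base.mean()), float(base.std(ddof=0))
    lo, hi = mu - z * sd, mu + z * sd

    def count(window):
        seg = trace[_window_slice(times_ms, window)]
        return int(np.sum((seg < lo) | (seg > hi)))

    return count(post_window), count(pre_window), (lo, hi)


def auto_latency(
    trace: np.ndarray,
    times_ms: np.ndarray,
    k_sd: float = 3.0,
    hold_ms: float = 2.0,
    rel_floor: float = 0.25,
    search_window: tuple[float, float] = POST_WINDOW,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
) -> float | None:
    """Earliest sustained baseline departure in the MEP search window.

    The onset is the first time in (10, 50) ms where |trace - baseline
    mean| exceeds the detection threshold continuously for ``hold_ms``.
    Returns None when no such crossing exists (absence is a value, not an
    error).

    The threshold is the larger of ``k_sd`` baseline SDs and ``rel_floor``
    times the maximum deviation within the search window.  The relative
    floor guards against the acausal precursor of zero-phase band-pass
    filtering, which spreads a large biphasic MEP several ms backward at
    up to ~20% of its peak: a purely noise-referenced detector locks onto
    that ripple and reports amplitude-dependent, spuriously early onsets.
    """
    trace = np.asarray(trace, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    base = trace[_window_slice(times_ms, baseline_window)]
    mu, sd = float(base.mean()), float(base.std(ddof=0))
    thresh = k_sd * sd

    lo, hi = search_window
    peak_dev = float(np.max(np.abs(trace[_window_slice(times_ms, search_window)] - mu)))
    thresh = max(thresh, rel_floor * peak_dev)
    mask = (times_ms > lo) & (times_ms < hi)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None
    dt_ms = float(np.median(np.diff(times_ms)))
    hold_n = max(1, int(round(hold_ms / dt_ms)))
    above = np.abs(trace[idx] - mu) > thresh
    run = 0
    for k, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= hold_n:
            return float(times_ms[idx[k - hold_n + 1]])
    return None


def measure(
    epoch_set: EpochSet,
    group_by: list[str] = (
        "participant",
        "muscle",
        "task",
        "location",
        "orientation",
        "intensity",
    ),
    post_window: tuple[float, float] = POST_WINDOW,
    pre_window: tuple[float, float] = PRE_WINDOW,
    latency: bool = True,
) -> pd.DataFrame:
    """Event-related average per condition cell, then quantify the MEP.

    Returns the MEP table: one row per cell with ``amplitude_post``,
    ``amplitude_pre`` (mV, peak-to-peak), ``latency_ms`` (or NaN), and
    ``n_trials``.
    """
    group_by = [k for k in group_by if k in epoch_set.meta.columns]
    avg = event_related_average(epoch_set, group_by)
    rows = []
    for i in range(avg.n_trials):
        trace = avg.epochs[i]
        row = avg.meta.iloc[i].to_dict()
        row["amplitude_post"] = peak_to_peak(trace, avg.times_ms, post_window)
        row["amplitude_pre"] = peak_to_peak(trace, avg.times_ms, pre_window)
        if latency:
            lat = auto_latency(trace, avg.times_ms, search_window=post_window)
            row["latency_ms"] = np.nan if lat is None else lat
        rows.append(row)
    return pd.DataFrame(rows)


def single_trial_measures(
    epoch_set: EpochSet,
    post_window: tuple[float, float] = POST_WINDOW,
    pre_window: tuple[float, float] = PRE_WINDOW,
) -> pd.DataFrame:
    """Per-trial peak-to-peak measures (for threshold-rule evidence)."""
    post_mask = _window_slice(epoch_set.times_ms, post_window)
    pre_mask = _window_slice(epoch_set.times_ms, pre_window)
    out = epoch_set.meta.copy()
    post_seg = epoch_set.epochs[:, post_mask]
    pre_seg = epoch_set.epochs[:, pre_mask]
    out["p2p_post"] = post_seg.max(axis=1) - post_seg.min(axis=1)
    out["p2p_pre"] = pre_seg.max(axis=1) - pre_seg.min(axis=1)
    return out


def normalize(
    mep_table: pd.DataFrame,
    scope: str | list[str] = "participant_muscle",
) -> pd.DataFrame:
    """Rescale amplitudes by the maximum post-TMS MEP within each scope.

    After normalisation the maximum ``amp_norm`` in every scope group is
    exactly 1; pre-TMS amplitudes are divided by the same factor so the
    post/pre contrast stays on a common scale.  Idempotent: re-running on
    an already-normalised table leaves values unchanged.
    """
    cols = SCOPES[scope] if isinstance(scope, str) else list(scope)
    cols = [c for c in cols if c in mep_table.columns]
    out = mep_table.copy()
    if not cols:
        factor = out["amplitude_post"].max()
        if not factor > 0:
            raise ValueError("all-zero amplitude group cannot be normalised")
        out["amp_norm"] = out["amplitude_post"] / factor
        out["amp_pre_norm"] = out["amplitude_pre"] / factor
        out["norm_scope"] = "all"
        return out
    factors = out.groupby(cols)["amplitude_post"].transform("max")
    if not (factors > 0).all():
        bad = out.loc[~(factors > 0), cols].drop_duplicates()
        raise ValueError(f"all-zero amplitude group(s) cannot be normalised:\n{bad}")
    out["amp_norm"] = out["amplitude_post"] / factors
    out["amp_pre_norm"] = out["amplitude_pre"] / factors
    out["norm_scope"] = "x".join(cols)
    return out
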