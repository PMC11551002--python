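"""Motor-threshold rules, recruitment (input-output) curves, and
matched-amplitude latency comparison.

Thresholds follow the standard offline evaluation of the clinical rules
over a supplied intensity ladder:

* resting motor threshold (Rossini-style): the lowest tested intensity at
  which at least 5 of the last 10 trials exceed the 50 uV peak-to-peak
  criterion;
* active motor threshold during a dexterity task: the lowest intensity at
  which either that count rule holds or the event-related average exceeds
  the criterion.

The rule functions operate on caller-supplied per-trial evidence values.
During movement the raw post-TMS peak-to-peak saturates on background EMG
alone, so the pipeline feeds the post-minus-pre contrast with a noise
guard (see ``detection_criterion_uv``), automating the experimenter's
"is an MEP visible?" judgment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "ThresholdEstimate",
    "RecruitmentCurve",
    "rmt_rossini",
    "amt_pegboard",
    "detection_criterion_uv",
    "build_curve",
    "matched_amplitude_latency",
]

CRITERION_UV = 50.0


@dataclass(frozen=True)
class ThresholdEstimate:
    """A motor-threshold estimate with its per-intensity evidence."""

    kind: str  # "RMT_Rossini94" or "AMT_pegboard"
    value: float | None  # one of the tested intensities, or None
    evidence: pd.DataFrame  # intensity, n_trials, n_supra, avg_uv, passes


def _count_supra(values_uv: np.ndarray, criterion_uv: float, n_last: int):
    """Count of the last ``n_last`` trials above criterion; None if < n_last."""
    v = np.asarray(values_uv, dtype=float)
    if v.size < n_last:
        return None
    return int(np.sum(v[-n_last:] > criterion_uv))


def rmt_rossini(
    trials_by_intensity: dict[float, np.ndarray],
    criterion_uv: float = CRITERION_UV,
    k: int = 5,
    n_last: int = 10,
) -> ThresholdEstimate:
    """Lowest intensity with >= k of the last n trials above criterion.

    ``trials_by_intensity`` maps tested intensity to per-trial evidence in
    uV.  Intensities with fewer than ``n_last`` trials are skipped with a
    warning.  Returns value None when no intensity satisfies the rule.
    """
    rows, value = [], None
    for inten in sorted(trials_by_intensity):
        n = _count_supra(trials_by_intensity[inten], criterion_uv, n_last)
        if n is None:
            log.warning("rmt_rossini: intensity %s skipped (<%d trials)", inten, n_last)
            warnings.warn(f"intensity {inten} skipped: fewer than {n_last} trials", stacklevel=2)
            continue
        passes = n >= k
        rows.append(
            {"intensity": inten, "n_trials": len(trials_by_intensity[inten]),
             "n_supra": n, "passes": passes}
        )
        if passes and value is None:
            value = float(inten)
    return ThresholdEstimate("RMT_Rossini94", value, pd.DataFrame(rows))


def amt_pegboard(
    avg_p2p_by_intensity: dict[float, float],
    trials_by_intensity: dict[float, np.ndarray],
    criterion_uv: float = CRITERION_UV,
    k: int = 5,
    n_last: int = 10,
) -> ThresholdEstimate:
    """Active threshold: count rule OR averaged-trace amplitude rule.

    The lowest intensity at which either >= k of the last n trials exceed
    the criterion or the event-related average peak-to-peak evidence (uV)
    exceeds it.
    """
    rows, value = [], None
    for inten in sorted(set(avg_p2p_by_intensity) | set(trials_by_intensity)):
        trials = trials_by_intensity.get(inten, np.array([]))
        n = _count_supra(trials, criterion_uv, n_last)
        if n is None:
            log.warning("amt_pegboard: intensity %s skipped (<%d trials)", inten, n_last)
            warnings.warn(f"intensity {inten} skipped: fewer than {n_last} trials", stacklevel=2)
            continue
        avg = float(avg_p2p_by_intensity.get(inten, np.nan))
        passes = (n >= k) or (np.isfinite(avg) and avg > criterion_uv)
        rows.append(
            {"intensity": inten, "n_trials": len(trials), "n_supra": n,
             "avg_uv": avg, "passes": passes}
        )
        if passes and value is None:
            value = float(inten)
    return ThresholdEstimate("AMT_pegboard", value, pd.DataFrame(rows))


def detection_criterion_uv(
    pre_p2p_uv: np.ndarray, criterion_uv: float = CRITERION_UV, z: float = 1.96
) -> float:
    """Noise-guarded detection criterion for contrasted evidence.

    max(criterion, z * SD of the pre-window peak-to-peak across trials):
    in quiet recordings this is the plain 50 uV rule; in active tasks it
    rises with the background so that chance fluctuations of the
    post-minus-pre contrast do not count as MEPs.
    """
    sd = float(np.std(np.asarray(pre_p2p_uv, dtype=float), ddof=1)) if len(pre_p2p_uv) > 1 else 0.0
    return max(criterion_uv, z * sd)


@dataclass
class RecruitmentCurve:
    """Input-output curve for one site and task state.

    ``table`` holds one row per participant x intensity with amplitudes
    (mV and normalised), latency (ms, NaN when undetected) and detection
    flags; ``summary`` aggregates per intensity with means, 95% CIs and
    the number of contributing participants (which varies, as MEPs are
    not detectable in everyone at every intensity).
    """

    site: object
    task: str
    table: pd.DataFrame
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    first_significant_intensity: float | None = None


def build_curve(
    per_participant: pd.DataFrame,
    site,
    task: str,
    alpha: float = 0.05,
    detect_col: str = "detected",
) -> RecruitmentCurve:
    """Assemble a recruitment curve and find the first significant intensity.

    ``per_participant`` needs columns participant, intensity (%RMT),
    amp_norm, amp_pre_norm, latency_ms and (optionally) a boolean
    ``detected`` column.  Per intensity the group mean and 95% CI of the
    post-pre contrast are computed; the first significant intensity is the
    lowest at which MEPs were detected in more than half of the
    contributing participants and a one-sample t on the contrast rejects
    zero (two-tailed ``alpha``) with a positive mean.  Intensities are
    tested independently, uncorrected, as map/intensity sweeps are
    reported descriptively.
    """
    req = {"participant", "intensity", "amp_norm", "amp_pre_norm"}
    missing = req - set(per_participant.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    df = per_participant.copy()
    if detect_col not in df.columns:
        df[detect_col] = True
    if len(df["intensity"].unique()) < 2:
        raise ValueError("need >= 2 intensities for a recruitment curve")

    rows, first_sig = [], None
    for inten in sorted(df["intensity"].unique()):
        sub = df[df["intensity"] == inten]
        diffs = (sub["amp_norm"] - sub["amp_pre_norm"]).to_numpy(dtype=float)
        n = diffs.size
        mean = float(diffs.mean()) if n else np.nan
        if n >= 2 and diffs.std(ddof=1) > 0:
            t, p = stats.ttest_1samp(diffs, 0.0)
            sem = diffs.std(ddof=1) / np.sqrt(n)
            ci = stats.t.ppf(1 - alpha / 2, n - 1) * sem
        else:
            t, p, ci = np.nan, np.nan, np.nan
        det_frac = float(sub[detect_col].mean()) if n else 0.0
        lat = sub["latency_ms"].dropna() if "latency_ms" in sub else pd.Series(dtype=float)
        sig = bool(np.isfinite(p) and p < alpha and mean > 0 and det_frac > 0.5)
        rows.append(
            {
                "intensity": inten,
                "n": n,
                "mean_contrast": mean,
                "ci95": ci,
                "t": float(t) if np.isfinite(t) else np.nan,
                "p": float(p) if np.isfinite(p) else np.nan,
                "detected_fraction": det_frac,
                "mean_latency_ms": float(lat.mean()) if len(lat) else np.nan,
                "n_latency": int(len(lat)),
                "significant": sig,
            }
        )
        if sig and first_sig is None:
            first_sig = float(inten)
    return RecruitmentCurve(site, task, df, pd.DataFrame(rows), first_sig)


def matched_amplitude_latency(
    curve_a: RecruitmentCurve,
    curve_b: RecruitmentCurve,
    n_pairs: int = 2,
    min_participants: int = 10,
) -> pd.DataFrame:
    """Compare latencies at intensity pairs with the most similar amplitudes.

    Candidate intensities are those with latencies from at least
    ``min_participants`` participants in each curve.  Pairs (one intensity
    per curve) are ranked by |mean amplitude difference|; for the best
    ``n_pairs`` disjoint pairs, paired t tests across the common
    participants are run on amplitudes (a check that the match succeeded)
    and on latencies (the question of interest: one shared source predicts
    no difference).  Returns one row per pair.
    """
    def candidates(curve):
        t = curve.table
        ok = []
        for inten in sorted(t["intensity"].unique()):
            sub = t[(t["intensity"] == inten) & t["latency_ms"].notna()]
            if sub["participant"].nunique() >= min_participants:
                ok.append(inten)
        return ok

    ca, cb = candidates(curve_a), candidates(curve_b)
    if not ca or not cb:
        raise ValueError(
            f"no candidate intensities with >= {min_participants} participants"
        )

    def group_mean(curve, inten):
        sub = curve.table[curve.table["intensity"] == inten]
        return float(sub["amp_norm"].mean())

    pairs = sorted(
        ((abs(group_mean(curve_a, ia) - group_mean(curve_b, ib)), ia, ib)
         for ia in ca for ib in cb),
        key=lambda x: x[0],
    )
    results, used_a, used_b = [], set(), set()
    for gap, ia, ib in pairs:
        if len(results) >= n_pairs:
            break
        if ia in used_a or ib in used_b:
            continue
        sa = curve_a.table[curve_a.table["intensity"] == ia].set_index("participant")
        sb = curve_b.table[curve_b.table["intensity"] == ib].set_index("participant")
        common = sa.index.intersection(sb.index)
        common = [
            p for p in common
            if np.isfinite(sa.loc[p, "latency_ms"]) and np.isfinite(sb.loc[p, "latency_ms"])
        ]
        if len(common) < 2:
            continue
        amp_a = sa.loc[common, "amp_norm"].to_numpy(dtype=float)
        amp_b = sb.loc[common, "amp_norm"].to_numpy(dtype=float)
        lat_a = sa.loc[common, "latency_ms"].to_numpy(dtype=float)
        lat_b = sb.loc[common, "latency_ms"].to_numpy(dtype=float)

        def paired(x, y):
            d = x - y
            if np.allclose(d.std(ddof=1), 0.0):
                return 0.0, 1.0
            t, p = stats.ttest_rel(x, y)
            return float(t), float(p)

        amp_t, amp_p = paired(amp_a, amp_b)
        lat_t, lat_p = paired(lat_a, lat_b)
        results.append(
            {
                "intensity_a": ia,
                "intensity_b": ib,
                "n": len(common),
                "mean_amp_a": float(amp_a.mean()),
                "mean_amp_b": float(amp_b.mean()),
                "amp_t": amp_t,
                "amp_p": amp_p,
                "mean_latency_a": float(lat_a.mean()),
                "mean_latency_b": float(lat_b.mean()),
                "latency_t": lat_t,
                "latency_p": lat_p,
            }
        )
        used_a.add(ia)
        used_b.add(ib)
    if not results:
        raise ValueError("no common participants at any candidate intensity pair")
    return pd.DataFrame(results)
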