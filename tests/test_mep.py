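"""MEP quantification: peak-to-peak, crossing counts, normalisation, latency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mepmap.mep import (
    auto_latency,
    crossing_count_contrast,
    measure,
    normalize,
    peak_to_peak,
)
from mepmap.emg import EpochSet

TIMES = np.arange(-400, 401) / 2.0  # 2 kHz, -200..200 ms


def trace_with(points: dict) -> np.ndarray:
    t = np.zeros_like(TIMES)
    for ms, val in points.items():
        t[np.argmin(np.abs(TIMES - ms))] = val
    return t


class TestPeakToPeak:
    def test_flat_trace_is_zero(self):
        assert peak_to_peak(np.zeros_like(TIMES), TIMES, (10, 50)) == 0.0

    def test_two_extrema(self):
        tr = trace_with({20.0: 1.0, 25.0: -0.5})
        assert peak_to_peak(tr, TIMES, (10, 50)) == pytest.approx(1.5)

    def test_injected_template_amplitude_recovered(self, fast_config):
        from mepmap.synth import mep_template

        tpl = mep_template(fast_config) * 2.0  # known p2p 2.0 mV
        tr = np.zeros_like(TIMES)
        onset = np.argmin(np.abs(TIMES - 22.0))
        tr[onset : onset + tpl.size] = tpl
        assert peak_to_peak(tr, TIMES, (10, 50)) == pytest.approx(2.0, abs=1e-9)

    @given(offset=st.floats(-5, 5))
    def test_translation_invariance(self, offset):
        tr = trace_with({20.0: 1.0, 30.0: -1.0})
        assert peak_to_peak(tr + offset, TIMES, (10, 50)) == pytest.approx(
            peak_to_peak(tr, TIMES, (10, 50))
        )

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            peak_to_peak(np.zeros_like(TIMES), TIMES, (500, 600))


class TestCrossingContrast:
    def test_flat_trace_counts_zero(self):
        n_post, n_pre, _ = crossing_count_contrast(np.zeros_like(TIMES), TIMES)
        assert (n_post, n_pre) == (0, 0)

    def test_post_window_mep_dominates(self, rng):
        tr = rng.normal(0, 0.01, TIMES.size)
        sel = (TIMES > 20) & (TIMES < 35)
        tr[sel] += 1.0
        n_post, n_pre, _ = crossing_count_contrast(tr, TIMES)
        assert n_post > n_pre

    def test_equal_sample_counts_in_both_windows(self):
        tr = np.ones_like(TIMES) * 5.0  # constant, degenerate baseline
        n_post, n_pre, (lo, hi) = crossing_count_contrast(tr, TIMES)
        assert lo == hi == 5.0
        assert n_post == n_pre == 0

    def test_pure_noise_contrast_unbiased(self, rng):
        """Under stationary noise the post-pre crossing-count difference is
        mean-zero (Monte-Carlo null, 1000 traces)."""
        diffs = []
        for _ in range(1000):
            tr = rng.normal(0, 1.0, TIMES.size)
            n_post, n_pre, _ = crossing_count_contrast(tr, TIMES)
            diffs.append(n_post - n_pre)
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 2 * se + 1e-9


class TestNormalize:
    def _table(self, rows):
        return pd.DataFrame(rows)

    def test_single_measure_becomes_one(self):
        t = self._table(
            [{"participant": "P1", "muscle": "FDI", "task": "rest",
              "amplitude_post": 0.8, "amplitude_pre": 0.2}]
        )
        out = normalize(t)
        assert out["amp_norm"].iloc[0] == pytest.approx(1.0)
        assert out["amp_pre_norm"].iloc[0] == pytest.approx(0.25)

    def test_two_measures_scale_to_half_and_one(self):
        t = self._table(
            [{"participant": "P1", "muscle": "FDI", "task": "rest",
              "amplitude_post": a, "amplitude_pre": 0.0} for a in (2.0, 4.0)]
        )
        out = normalize(t)
        assert sorted(out["amp_norm"]) == pytest.approx([0.5, 1.0])

    def test_condition_scope_is_more_stringent(self):
        # maximal within its condition but not overall
        rows = [
            {"participant": "P1", "muscle": "FDI", "task": "rest",
             "amplitude_post": 1.0, "amplitude_pre": 0.0},
            {"participant": "P1", "muscle": "FDI", "task": "dynamic",
             "amplitude_post": 4.0, "amplitude_pre": 0.0},
        ]
        pooled = normalize(self._table(rows), "participant_muscle")
        per_cond = normalize(self._table(rows), "participant_muscle_task")
        rest_pooled = pooled.loc[pooled["task"] == "rest", "amp_norm"].iloc[0]
        rest_cond = per_cond.loc[per_cond["task"] == "rest", "amp_norm"].iloc[0]
        assert rest_cond == pytest.approx(1.0)
        assert rest_pooled < 1.0

    def test_idempotent(self):
        t = self._table(
            [{"participant": "P1", "muscle": "FDI", "task": "rest",
              "amplitude_post": a, "amplitude_pre": a / 2} for a in (1.0, 3.0)]
        )
        once = normalize(t)
        twice = normalize(once)
        assert np.allclose(once["amp_norm"], twice["amp_norm"])

    def test_all_zero_group_rejected(self):
        t = self._table(
            [{"participant": "P1", "muscle": "FDI", "task": "rest",
              "amplitude_post": 0.0, "amplitude_pre": 0.0}]
        )
        with pytest.raises(ValueError, match="zero"):
            normalize(t)

    def test_max_is_exactly_one_per_scope(self, rng):
        rows = [
            {"participant": f"P{p}", "muscle": "FDI", "task": "rest",
             "amplitude_post": rng.uniform(0.1, 3), "amplitude_pre": 0.1}
            for p in range(4) for _ in range(5)
        ]
        out = normalize(self._table(rows))
        assert np.allclose(out.groupby("participant")["amp_norm"].max(), 1.0)


class TestAutoLatency:
    def _trace_with_template(self, onset_ms, amp, noise_sd=0.0, seed=0):
        from mepmap.synth import GeneratorConfig, mep_template

        cfg = GeneratorConfig(sampling_rate=2000.0)
        tr = np.random.default_rng(seed).normal(0, noise_sd, TIMES.size)
        tpl = mep_template(cfg) * amp
        j = np.argmin(np.abs(TIMES - onset_ms))
        tr[j : j + tpl.size] += tpl
        return tr

    def test_flat_trace_has_no_latency(self):
        assert auto_latency(np.zeros_like(TIMES), TIMES) is None

    def test_high_snr_onset_recovered(self):
        tr = self._trace_with_template(21.0, 1.0, noise_sd=0.01)
        lat = auto_latency(tr, TIMES)
        assert lat == pytest.approx(21.0, abs=0.5)

    def test_latency_non_increasing_as_amplitude_doubles(self):
        lats = []
        for amp in (0.5, 1.0, 2.0):
            tr = self._trace_with_template(23.0, amp, noise_sd=0.02, seed=9)
            lats.append(auto_latency(tr, TIMES))
        assert all(l is not None for l in lats)
        assert all(b <= a + 1e-9 for a, b in zip(lats, lats[1:]))


class TestMeasurePipeline:
    def test_pure_noise_amplitude_falls_with_sqrt_n_trials(self, rng):
        """The averaged-trace post-window p2p of pure noise scales like
        1/sqrt(n_trials) (within Monte-Carlo tolerance)."""

        def mean_amp(n_trials, reps=40):
            amps = []
            for r in range(reps):
                eps = rng.normal(0, 1.0, size=(n_trials, TIMES.size))
                meta = pd.DataFrame({"participant": ["P"] * n_trials,
                                     "muscle": ["m"] * n_trials,
                                     "task": ["rest"] * n_trials,
                                     "location": [1] * n_trials,
                                     "orientation": [45] * n_trials,
                                     "intensity": [100] * n_trials})
                es = EpochSet(eps, TIMES, meta, 2000.0)
                amps.append(measure(es, latency=False)["amplitude_post"].iloc[0])
            return np.mean(amps)

        a4, a64 = mean_amp(4), mean_amp(64)
        assert a64 / a4 == pytest.approx(np.sqrt(4 / 64), rel=0.25)
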