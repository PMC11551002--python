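"""Generator model: drive closed forms, recruitment behaviour, determinism."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from mepmap.synth import (
    ExperimentDesign,
    GeneratorConfig,
    drive,
    generate_continuous,
    generate_experiment,
    mean_amplitude,
    mep_amplitude_and_latency,
    mep_template,
)


@pytest.fixture
def cfg():
    return GeneratorConfig(sampling_rate=2000.0, seed=3)


class TestDrive:
    def test_hotspot_preferred_orientation_is_identity(self, cfg):
        assert drive(42.0, cfg.hotspot_xy, cfg.theta_pref, cfg) == pytest.approx(42.0)

    def test_two_sigma_distance_attenuates_by_e_minus_two(self, cfg):
        coil = (cfg.hotspot_xy[0] + 2 * cfg.sigma_space, cfg.hotspot_xy[1])
        expected = 10.0 * np.exp(-2.0)
        assert drive(10.0, coil, cfg.theta_pref, cfg) == pytest.approx(expected)

    def test_radially_non_increasing(self, cfg):
        radii = np.linspace(0, 120, 100)
        coils = np.c_[cfg.hotspot_xy[0] + radii, np.full(100, cfg.hotspot_xy[1])]
        d = np.array([drive(60.0, c, cfg.theta_pref, cfg) for c in coils])
        assert np.all(np.diff(d) <= 1e-12)

    @given(theta=st.floats(-720, 720))
    def test_tuning_bounded_and_maximal_at_preference(self, theta):
        cfg = GeneratorConfig()
        d = drive(1.0, cfg.hotspot_xy, theta, cfg)
        assert 0 < d <= 1.0 + 1e-12
        assert d <= drive(1.0, cfg.hotspot_xy, cfg.theta_pref, cfg) + 1e-12


class TestAmplitudeLatency:
    def test_zero_drive_amplitude_negligible(self, cfg, rng):
        amp, _ = mep_amplitude_and_latency(np.zeros(200), "rest", cfg, rng)
        # sub-threshold sigmoid tail: mean far below 1% of the maximum
        assert mean_amplitude(0.0, "rest", cfg) < 0.01 * cfg.amp_max_mV
        assert amp.mean() < 0.05 * cfg.amp_max_mV

    def test_saturation_reaches_max_amplitude_and_min_latency(self, cfg, rng):
        d = np.full(500, cfg.rmt_drive * 3)
        amp, lat = mep_amplitude_and_latency(d, "dynamic", cfg, rng)
        assert mean_amplitude(d[0], "dynamic", cfg) == pytest.approx(cfg.amp_max_mV, rel=1e-6)
        assert np.median(lat) == pytest.approx(cfg.latency_min_ms, abs=3 * cfg.latency_jitter_ms)

    def test_unknown_task_state_rejected(self, cfg, rng):
        with pytest.raises(ValueError, match="task"):
            mep_amplitude_and_latency(10.0, "jogging", cfg, rng)

    def test_movement_lowers_50uv_crossing_by_threshold_ratio(self, cfg):
        """The intensity at which the mean amplitude first exceeds 50 uV is
        lower during dynamic movement than at rest by roughly the active
        threshold ratio."""

        def crossing(task):
            f = lambda i: mean_amplitude(drive(i, cfg.hotspot_xy, 45.0, cfg), task, cfg) - 0.05
            return brentq(f, 1.0, 200.0)

        ratio = crossing("dynamic") / crossing("rest")
        assert ratio == pytest.approx(cfg.active_threshold_ratio, abs=0.08)

    def test_mean_amplitude_monotone_in_intensity(self, cfg):
        intensities = np.linspace(0, 120, 200)
        amps = mean_amplitude(
            drive(intensities, cfg.hotspot_xy, cfg.theta_pref, cfg), "rest", cfg
        )
        assert np.all(np.diff(amps) >= 0)


class TestContinuous:
    def test_zero_background_zero_drive_gives_flat_record(self, cfg):
        quiet = dataclasses.replace(
            cfg, background_rms_mV={"rest": 0.0, "isotonic": 0.0, "dynamic": 0.0}
        )
        rec, _ = generate_continuous("rest", 3, 1.0, quiet, intensity=0.0)
        assert np.allclose(rec.data, 0.0)

    def test_same_seed_identical_records(self, cfg):
        rec1, truth1 = generate_continuous("dynamic", 5, 1.0, cfg)
        rec2, truth2 = generate_continuous("dynamic", 5, 1.0, cfg)
        assert np.array_equal(rec1.data, rec2.data)
        assert truth1.equals(truth2)

    def test_rest_background_rms_matches_configuration(self, cfg):
        rec, _ = generate_continuous("rest", 60, 1.0, cfg, intensity=0.0)
        rms = float(np.sqrt(np.mean(rec.data**2)))
        assert rms == pytest.approx(cfg.background_rms_mV["rest"], rel=0.05)

    def test_template_peak_to_peak_is_unity(self, cfg):
        t = mep_template(cfg)
        assert t.max() - t.min() == pytest.approx(1.0)


class TestExperiment:
    def test_factorial_epoch_count(self, cfg):
        design = ExperimentDesign(
            n_participants=2, tasks=("rest",),
            locations=((1, 0.0, 0.0), (2, 10.0, 0.0), (3, 20.0, 0.0)),
            orientations=(0.0, 45.0, 90.0, 135.0),
            intensities=(100.0,), n_trials=5,
        )
        es, truth = generate_experiment(design, cfg)
        assert es.n_trials == 2 * 3 * 4 * 5
        assert len(truth) == es.n_trials

    def test_zero_intensity_gives_near_zero_true_amplitudes(self, cfg):
        design = ExperimentDesign(
            n_participants=2, tasks=("rest",), locations=((1, *cfg.hotspot_xy),),
            orientations=(45.0,), intensities=(0.0,), n_trials=10,
            intensity_unit="%MSO",
        )
        _, truth = generate_experiment(design, cfg)
        assert truth["true_amp_mV"].max() < 0.01 * cfg.amp_max_mV

    def test_same_seed_identical_dataset(self, cfg):
        design = ExperimentDesign(
            n_participants=2, tasks=("dynamic",), locations=((1, -51.0, 1.0),),
            orientations=(45.0,), intensities=(110.0,), n_trials=4,
        )
        es1, t1 = generate_experiment(design, cfg)
        es2, t2 = generate_experiment(design, cfg)
        assert np.array_equal(es1.epochs, es2.epochs)
        assert t1.equals(t2)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ExperimentDesign(
                n_participants=0, tasks=("rest",), locations=((1, 0.0, 0.0),),
                orientations=(45.0,), intensities=(100.0,), n_trials=1,
            )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(active_threshold_ratio=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig(latency_min_ms=30.0, latency_max_ms=20.0)
        with pytest.raises(ValueError):
            GeneratorConfig(sampling_rate=500.0)

    def test_remote_sites_silent_at_rest(self):
        """No site beyond 55 mm + 2 sigma yields a mean amplitude above
        50 uV at rest at 1.1x the resting threshold."""
        cfg = GeneratorConfig()
        dist = 55.0 + 2 * cfg.sigma_space
        for ang in np.linspace(0, 2 * np.pi, 13):
            coil = (
                cfg.hotspot_xy[0] + dist * np.cos(ang),
                cfg.hotspot_xy[1] + dist * np.sin(ang),
            )
            d = drive(1.1 * cfg.rmt_drive, coil, cfg.theta_pref, cfg)
            assert mean_amplitude(d, "rest", cfg) < 0.05
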