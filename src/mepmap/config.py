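"""Run configuration: every stage's parameters in one YAML-round-trippable
mapping with strict (unknown keys rejected) validation."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "save_config", "merge_config"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "verbosity": 1,
    "generator": {
        "sampling_rate": 2000.0,
        "hotspot_xy": [-51.0, 1.0],
        "sigma_space": 42.0,
        "theta_pref": 45.0,
        "kappa_orient": 2.0,
        "rmt_drive": 55.0,
        "active_threshold_ratio": 0.61,
        "slope": 2.0,
        "amp_max_mV": 2.0,
        "latency_min_ms": 21.5,
        "latency_max_ms": 25.5,
        "latency_jitter_ms": 1.0,
        "background_rms_mV": {"rest": 0.005, "isotonic": 0.05, "dynamic": 0.1},
        "burst_mod": 0.8,
        "trial_noise_sigma": 0.5,
        "hotspot_jitter_mm": 7.0,
        "rmt_jitter": 5.0,
    },
    "design": {
        "n_participants": 12,
        "tasks": ["rest", "dynamic"],
        "layout": "grid27",
        "orientations": [45.0],
        "intensities": [110.0],
        "intensity_unit": "%RMT",
        "n_trials": 10,
    },
    "filter": {"low_hz": 25.0, "high_hz": 250.0, "order": 2},
    "windows": {
        "post_ms": [10.0, 50.0],
        "pre_ms": [-50.0, -10.0],
        "baseline_ms": [-200.0, -50.0],
    },
    "normalization": {"scope": "participant_muscle"},
    "map": {"t_crit": 2.20, "resolution_mm": 1.0},
    "thresholds": {"criterion_uv": 50.0, "k": 5, "n_last": 10},
    "sweep": {"min_vm": 0.0, "max_vm": 79.0, "step_vm": 1.0},
    "screen": {"brain_cutoff_mm": 42.0, "scalp_cutoff_mm": 55.0},
    "power": {"alpha": 0.05, "power": 0.80, "tails": 2},
}


def merge_config(base: dict, override: dict, _path: str = "") -> dict:
    """Deep-merge ``override`` into ``base``, rejecting unknown keys."""
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{_path}.{key}" if _path else str(key)
        if key not in base:
            raise KeyError(f"unknown configuration key: {where}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = merge_config(base[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Defaults merged with an optional YAML file; unknown keys rejected."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    loaded = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(loaded, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return merge_config(DEFAULT_CONFIG, loaded)


def save_config(config: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config, sort_keys=True))
    return path
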