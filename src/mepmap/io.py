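"""On-disk formats: epoch tables, continuous records, MEP tables, rasters.

Everything is plain text: CSV for tables and sample matrices, a JSON
sidecar for acquisition metadata (sampling rate, time axis, condition
keys, config hash and seed), NIfTI for 3-D volumes.  Values round-trip
exactly (floats are written with 17 significant digits).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .emg import ContinuousRecord, EpochSet

__all__ = [
    "config_hash",
    "write_epochs",
    "read_epochs",
    "write_continuous",
    "read_continuous",
    "write_table",
    "read_table",
    "write_raster",
]

FLOAT_FMT = "%.17g"
_EPOCH_META_KEYS = ("sampling_rate", "n_samples", "t0_index", "meta_columns")


class SchemaError(ValueError):
    """Raised when an on-disk file does not match the documented schema."""


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(sidecar: dict, provenance: dict | None) -> dict:
    if provenance:
        sidecar["provenance"] = {k: str(v) for k, v in provenance.items()}
    return sidecar


def write_epochs(epoch_set: EpochSet, directory, provenance: dict | None = None) -> Path:
    """Write an EpochSet as samples.csv + meta.csv + sidecar.json.

    samples.csv holds one row per trial (columns s0..sN in mV); meta.csv
    one row per trial with the condition labels; the sidecar carries the
    sampling rate and time-axis definition.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    n_samples = epoch_set.times_ms.size
    t0_index = int(np.argmin(np.abs(epoch_set.times_ms)))
    samples = pd.DataFrame(
        epoch_set.epochs, columns=[f"s{i}" for i in range(n_samples)]
    )
    samples.to_csv(d / "samples.csv", index=False, float_format=FLOAT_FMT)
    epoch_set.meta.to_csv(d / "meta.csv", index=False)
    sidecar = {
        "sampling_rate": epoch_set.sampling_rate,
        "n_samples": n_samples,
        "t0_index": t0_index,
        "meta_columns": list(epoch_set.meta.columns),
    }
    _provenance(sidecar, provenance)
    (d / "sidecar.json").write_text(json.dumps(sidecar, indent=1))
    return d


def read_epochs(directory) -> EpochSet:
    d = Path(directory)
    sidecar_path = d / "sidecar.json"
    if not sidecar_path.exists():
        raise SchemaError(f"missing sidecar.json in {d}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in _EPOCH_META_KEYS:
        if key not in sidecar:
            raise SchemaError(f"sidecar.json missing required key {key!r}")
    samples = pd.read_csv(d / "samples.csv", float_precision="round_trip")
    meta = pd.read_csv(d / "meta.csv")
    missing = [c for c in sidecar["meta_columns"] if c not in meta.columns]
    if missing:
        raise SchemaError(f"meta.csv missing column(s): {missing}")
    fs = float(sidecar["sampling_rate"])
    n = int(sidecar["n_samples"])
    if samples.shape[1] != n:
        raise SchemaError(
            f"samples.csv has {samples.shape[1]} sample columns, sidecar says {n}"
        )
    t0 = int(sidecar["t0_index"])
    times_ms = (np.arange(n) - t0) / fs * 1000.0
    return EpochSet(samples.to_numpy(dtype=float), times_ms, meta, fs)


def write_continuous(record: ContinuousRecord, directory, provenance: dict | None = None) -> Path:
    """Continuous record: samples.csv (one column per channel) + sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(record.data.T, columns=record.channels).to_csv(
        d / "samples.csv", index=False, float_format=FLOAT_FMT
    )
    sidecar = {
        "sampling_rate": record.sampling_rate,
        "channels": list(record.channels),
        "triggers_s": [float(t) for t in record.triggers_s],
    }
    _provenance(sidecar, provenance)
    (d / "sidecar.json").write_text(json.dumps(sidecar, indent=1))
    return d


def read_continuous(directory) -> ContinuousRecord:
    d = Path(directory)
    sidecar_path = d / "sidecar.json"
    if not sidecar_path.exists():
        raise SchemaError(f"missing sidecar.json in {d}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("sampling_rate", "channels", "triggers_s"):
        if key not in sidecar:
            raise SchemaError(f"sidecar.json missing required key {key!r}")
    samples = pd.read_csv(d / "samples.csv", float_precision="round_trip")
    missing = [c for c in sidecar["channels"] if c not in samples.columns]
    if missing:
        raise SchemaError(f"samples.csv missing channel column(s): {missing}")
    data = samples[sidecar["channels"]].to_numpy(dtype=float).T
    return ContinuousRecord(
        data,
        float(sidecar["sampling_rate"]),
        list(sidecar["channels"]),
        np.asarray(sidecar["triggers_s"], dtype=float),
    )


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> Path:
    """Flat CSV with an optional provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            for k, v in provenance.items():
                fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_raster(raster, path) -> Path:
    """Interpolated map as a plain-matrix text file with an axis header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"x0={raster.x_mm[0]} y0={raster.y_mm[0]} "
        f"resolution_mm={raster.resolution} shape={raster.values.shape}"
    )
    np.savetxt(path, raster.values, fmt=FLOAT_FMT, header=header)
    return path
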