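"""Distances, motor-confound proximity screening, E-field linking, and
inverse-distance-weighted MEP volumes.

The screening rule reflects the empirical reach of TMS during natural
movement: MEPs were evoked with the coil up to 55 mm away on the scalp
from the M1 hand hotspot, corresponding to ~42 mm between targets within
the brain, so stimulation sites inside those cutoffs carry a motor
activation confound risk.  Modeled electric-field magnitudes are consumed
as an input table (field simulation itself is out of scope here).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "BRAIN_CUTOFF_MM",
    "SCALP_CUTOFF_MM",
    "M1_MNI",
    "BrainCoordinate",
    "MepVolume",
    "mni_distance",
    "scalp_distance",
    "proximity_screen",
    "efield_threshold_sweep",
    "idw_volume",
]

BRAIN_CUTOFF_MM = 42.0
SCALP_CUTOFF_MM = 55.0
M1_MNI = (-38.0, -15.0, 58.0)  # left M1 hand area, MNI mm


@dataclass(frozen=True)
class BrainCoordinate:
    """A labelled point in MNI space (mm)."""

    x: float
    y: float
    z: float
    label: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError("MNI coordinates must be finite")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


def _as_xyz(p) -> np.ndarray:
    if isinstance(p, BrainCoordinate):
        return p.xyz
    return np.asarray(p, dtype=float)


def mni_distance(a, b) -> float:
    """Euclidean distance (mm) between two MNI points."""
    return float(np.linalg.norm(_as_xyz(a) - _as_xyz(b)))


def scalp_distance(a, b) -> float:
    """Straight-line distance (mm) in the Cz tape-measure scalp plane."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(a[:2] - b[:2]))


def proximity_screen(
    targets: list[dict],
    m1_brain=M1_MNI,
    m1_scalp=(0.0, 0.0),
    brain_cutoff_mm: float = BRAIN_CUTOFF_MM,
    scalp_cutoff_mm: float = SCALP_CUTOFF_MM,
) -> pd.DataFrame:
    """Flag stimulation targets within the motor-confound cutoffs.

    Each target is a dict with a ``label`` and either ``mni`` (x, y, z) or
    ``scalp`` (x, y) coordinates (or both; each space is screened against
    its own cutoff, and a target is flagged if any applicable space flags
    it).  Rows are sorted by distance.  A target with neither coordinate
    type is a signalled error.
    """
    rows = []
    for t in targets:
        if "mni" not in t and "scalp" not in t:
            raise ValueError(f"target {t.get('label', t)!r} has no coordinates")
        label = t.get("label", "")
        if "mni" in t:
            d = mni_distance(t["mni"], m1_brain)
            rows.append(
                {"label": label, "space": "brain", "distance_mm": d,
                 "cutoff_mm": brain_cutoff_mm, "flagged": d <= brain_cutoff_mm}
            )
        if "scalp" in t:
            d = scalp_distance(t["scalp"], m1_scalp)
            rows.append(
                {"label": label, "space": "scalp", "distance_mm": d,
                 "cutoff_mm": scalp_cutoff_mm, "flagged": d <= scalp_cutoff_mm}
            )
    return pd.DataFrame(rows).sort_values("distance_mm", ignore_index=True)


def efield_threshold_sweep(
    field_table: pd.DataFrame,
    thresholds=None,
    field_col: str = "field_vm",
    mep_col: str = "mep",
):
    """Correlate modeled field with MEP amplitude over a threshold sweep.

    For each threshold, points with field >= threshold are retained and
    the Pearson correlation between field and MEP is computed when at
    least 3 pairs remain (thresholds leaving fewer pairs, or a constant
    subset, are absent from the profile).  The best threshold is the
    smallest one attaining the maximum correlation — excluding low-field
    points below the effective MEP threshold typically strengthens the
    linear field-response relation up to an optimum.

    Returns ``(best_threshold, profile)`` with profile columns
    threshold, n, r.
    """
    if thresholds is None:
        thresholds = np.arange(0.0, 80.0, 1.0)
    f = field_table[field_col].to_numpy(dtype=float)
    m = field_table[mep_col].to_numpy(dtype=float)
    if f.size < 4:
        raise ValueError("need >= 4 paired points for the sweep")
    rows = []
    for thr in thresholds:
        sel = f >= thr
        if sel.sum() < 3:
            continue
        fs, ms = f[sel], m[sel]
        if np.allclose(fs.std(), 0) or np.allclose(ms.std(), 0):
            log.warning("sweep: constant subset at threshold %.1f, skipped", thr)
            warnings.warn(f"constant subset at threshold {thr}; skipped", stacklevel=2)
            continue
        r, _ = stats.pearsonr(fs, ms)
        rows.append({"threshold": float(thr), "n": int(sel.sum()), "r": float(r)})
    profile = pd.DataFrame(rows)
    if profile.empty:
        raise ValueError("no threshold left a correlatable subset")
    best = float(profile.loc[profile["r"].idxmax(), "threshold"])
    # smallest threshold attaining the maximum (idxmax returns first max)
    return best, profile


@dataclass
class MepVolume:
    """MEP amplitudes interpolated on a 3-D voxel grid (unitless)."""

    values: np.ndarray  # (nx, ny, nz)
    origin: np.ndarray  # mm coordinates of voxel (0,0,0)
    spacing: float  # mm, isotropic
    threshold: float | None = None

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.spacing
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self):
        import nibabel as nib

        return nib.Nifti1Image(self.values.astype(np.float32), self.affine)


def idw_volume(
    locations_3d,
    mep_values,
    shape: tuple[int, int, int],
    origin=(0.0, 0.0, 0.0),
    spacing: float = 1.0,
    threshold_rule: str | None = "mean",
    rescale: bool = True,
) -> MepVolume:
    """Inverse-distance-weighted MEP volume on a regular voxel grid.

    Every voxel value is the convex combination sum_i w_i * mep_i with
    weights w_i proportional to 1 / distance(voxel, site_i), normalised to
    sum to 1 per voxel (so values are independent of grid extent and lie
    within [min mep, max mep]).  A voxel coincident with a site takes that
    site's value.  With ``threshold_rule='mean'`` voxels below the volume
    mean are zeroed and, with ``rescale``, the survivors are divided by
    the maximum so the volume spans (0, 1].
    """
    locs = np.atleast_2d(np.asarray(locations_3d, dtype=float))
    meps = np.asarray(mep_values, dtype=float)
    if locs.shape[0] < 1:
        raise ValueError("need >= 1 location")
    if locs.shape[0] != meps.size:
        raise ValueError("one MEP value per location required")
    if min(shape) < 1:
        raise ValueError("empty grid")
    nx, ny, nz = shape
    origin = np.asarray(origin, dtype=float)
    gx, gy, gz = np.meshgrid(
        origin[0] + spacing * np.arange(nx),
        origin[1] + spacing * np.arange(ny),
        origin[2] + spacing * np.arange(nz),
        indexing="ij",
    )
    vox = np.c_[gx.ravel(), gy.ravel(), gz.ravel()]
    d = np.linalg.norm(vox[:, None, :] - locs[None, :, :], axis=2)  # (N, M)
    vals = np.empty(vox.shape[0])
    hit = d < 1e-12
    any_hit = hit.any(axis=1)
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    w[~np.isfinite(w)] = 0.0
    denom = w.sum(axis=1)
    safe = ~any_hit
    vals[safe] = (w[safe] @ meps) / denom[safe]
    for i in np.flatnonzero(any_hit):
        vals[i] = meps[np.argmax(hit[i])]
    values = vals.reshape(shape)

    threshold = None
    if threshold_rule == "mean":
        threshold = float(values.mean())
        values = np.where(values >= threshold, values, 0.0)
        if rescale and values.max() > 0:
            values = values / values.max()
    elif threshold_rule is not None:
        raise ValueError(f"unknown threshold_rule: {threshold_rule!r}")
    return MepVolume(values, origin, spacing, threshold)
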