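"""Scalp stimulation-site layouts and thresholded t-statistic maps.

Coordinates are tape-measure scalp millimetres relative to the vertex
Cz = (0, 0): x positive toward the right preauricular point (lateral,
negative = left hemisphere), y positive toward the nasion (anterior).

Maps are built by computing, per stimulated location, a paired t statistic
across participants on the post- minus pre-TMS MEP amplitude contrast,
interpolating linearly on a triangulation of the locations (exact at the
nodes, no overshoot, hence no spurious significant islands), and measuring
the area above the significance threshold with sub-cell (marching-squares)
contouring.  No correction for multiple comparisons is applied across
locations: neighbouring locations are strongly autocorrelated and the maps
are descriptive; significance claims rest on hypothesis-driven site tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import griddata
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "ScalpLayout",
    "Raster",
    "ScalpTMap",
    "make_layout",
    "location_t",
    "interpolate",
    "contour_area",
    "build_tmap",
    "T_CRIT_DEFAULT",
]

# two-tailed alpha = .05 critical t for the canonical 12-participant group
T_CRIT_DEFAULT = 2.20


@dataclass(frozen=True)
class ScalpLayout:
    """Stimulation sites: (id, x mm, y mm) relative to Cz."""

    kind: str
    locations: tuple[tuple[object, float, float], ...]

    def __post_init__(self) -> None:
        ids = [i for i, _, _ in self.locations]
        if len(set(ids)) != len(ids):
            raise ValueError("location ids must be unique")
        xy = np.array([(x, y) for _, x, y in self.locations], dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("coordinates must be finite")

    @property
    def ids(self) -> list:
        return [i for i, _, _ in self.locations]

    @property
    def xy(self) -> np.ndarray:
        return np.array([(x, y) for _, x, y in self.locations], dtype=float)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.locations, columns=["location", "x_mm", "y_mm"])


def _ring(center, radius, n, start_deg=90.0):
    ang = np.deg2rad(start_deg + 360.0 * np.arange(n) / n)
    return np.c_[center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]


def _grid27(center):
    """Idealised 27-site arrangement centred on the M1 hotspot.

    Approximate geometry: the centre plus concentric rings of 8, 8 and 10
    sites at 25, 50 and 75 mm (middle ring rotated half a step), giving
    homogeneous coverage out to 75 mm.  The published per-participant site
    tables are not reproduced; this fixture is an idealisation.
    """
    pts = [np.array([center])]
    pts.append(_ring(center, 25.0, 8, start_deg=90.0))
    pts.append(_ring(center, 50.0, 8, start_deg=112.5))
    pts.append(_ring(center, 75.0, 10, start_deg=90.0))
    return np.vstack(pts)


def make_layout(kind: str, **params) -> ScalpLayout:
    """Construct a named stimulation-site layout.

    kinds
    -----
    ``line5``      : ``start`` to ``end`` with 3 equidistant interior points
                     (the M1-to-SMG line).
    ``circles17``  : ``center`` plus 8 sites at 35 mm and 8 at 70 mm,
                     45 deg spacing, first site toward North.
    ``grid27``     : idealised 27-site map centred on ``center``.
    ``search_grid``: ``n`` x ``m`` grid at ``spacing`` mm (default 10)
                     centred on ``center`` (hotspot-hunting grid).
    """
    if kind == "line5":
        start = np.asarray(params["start"], dtype=float)
        end = np.asarray(params["end"], dtype=float)
        pts = [start + (end - start) * k / 4.0 for k in range(5)]
        locs = tuple((i + 1, float(p[0]), float(p[1])) for i, p in enumerate(pts))
    elif kind == "circles17":
        center = np.asarray(params.get("center", (0.0, 0.0)), dtype=float)
        pts = np.vstack([[center], _ring(center, 35.0, 8), _ring(center, 70.0, 8)])
        locs = tuple((i + 1, float(p[0]), float(p[1])) for i, p in enumerate(pts))
    elif kind == "grid27":
        center = np.asarray(params.get("center", (0.0, 0.0)), dtype=float)
        pts = _grid27(center)
        locs = tuple((i + 1, float(p[0]), float(p[1])) for i, p in enumerate(pts))
    elif kind == "search_grid":
        n = int(params.get("n", 5))
        m = int(params.get("m", n))
        spacing = float(params.get("spacing", 10.0))
        center = np.asarray(params.get("center", (0.0, 0.0)), dtype=float)
        xs = (np.arange(n) - (n - 1) / 2.0) * spacing + center[0]
        ys = (np.arange(m) - (m - 1) / 2.0) * spacing + center[1]
        locs = tuple(
            (i * m + j + 1, float(xs[i]), float(ys[j]))
            for i in range(n)
            for j in range(m)
        )
    else:
        raise ValueError(f"unknown layout kind: {kind!r}")
    return ScalpLayout(kind, locs)


def location_t(
    mep_table: pd.DataFrame,
    location,
    value_post: str = "amp_norm",
    value_pre: str = "amp_pre_norm",
) -> tuple[float, int]:
    """Paired t across participants on the post - pre amplitude contrast."""
    sub = mep_table[mep_table["location"] == location]
    per_p = sub.groupby("participant")[[value_post, value_pre]].mean()
    diffs = (per_p[value_post] - per_p[value_pre]).to_numpy()
    if diffs.size < 2:
        raise ValueError(f"need >= 2 participants at location {location!r}")
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise ValueError(f"zero-variance contrast at location {location!r}")
    t, _ = stats.ttest_1samp(diffs, 0.0)
    return float(t), diffs.size - 1


@dataclass
class Raster:
    """Values interpolated on a regular mm grid; NaN outside the hull."""

    values: np.ndarray  # (ny, nx)
    x_mm: np.ndarray
    y_mm: np.ndarray

    @property
    def resolution(self) -> float:
        return float(self.x_mm[1] - self.x_mm[0])


def interpolate(layout: ScalpLayout, values, resolution_mm: float = 1.0) -> Raster:
    """Piecewise-linear interpolation on a triangulation of the sites.

    Exact at the nodes, clipped to the convex hull (no extrapolation).
    Collinear layouts cannot be triangulated and are a signalled error
    (line maps are reported per location only).
    """
    pts = layout.xy
    vals = np.asarray(values, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need >= 3 locations to interpolate")
    try:
        ConvexHull(pts)
    except QhullError as e:
        raise ValueError("layout is collinear; cannot interpolate a 2-D map") from e
    if vals.shape[0] != pts.shape[0]:
        raise ValueError("one value per location required")
    x0, y0 = np.floor(pts.min(axis=0))
    x1, y1 = np.ceil(pts.max(axis=0))
    xs = np.arange(x0, x1 + resolution_mm / 2, resolution_mm)
    ys = np.arange(y0, y1 + resolution_mm / 2, resolution_mm)
    gx, gy = np.meshgrid(xs, ys)
    grid = griddata(pts, vals, (gx, gy), method="linear")
    return Raster(grid, xs, ys)


def _cell_polygon_area(u00, u10, u11, u01):
    """Area fraction of {u > 0} in a unit cell, linear along the edges.

    Walks the cell boundary (corners in circular order), inserting edge
    crossings, and applies the shoelace formula to the super-threshold
    polygon.  This is the marching-squares decomposition with the saddle
    resolved by the boundary-walk orientation.
    """
    corners = ((0.0, 0.0, u00), (1.0, 0.0, u10), (1.0, 1.0, u11), (0.0, 1.0, u01))
    poly = []
    for k in range(4):
        x0, y0, v0 = corners[k]
        x1, y1, v1 = corners[(k + 1) % 4]
        if v0 > 0:
            poly.append((x0, y0))
        if (v0 > 0) != (v1 > 0):
            t = v0 / (v0 - v1)
            poly.append((x0 + t * (x1 - x0), y0 + t * (y1 - y0)))
    if len(poly) < 3:
        return 0.0
    area = 0.0
    for k in range(len(poly)):
        xa, ya = poly[k]
        xb, yb = poly[(k + 1) % len(poly)]
        area += xa * yb - xb * ya
    return abs(area) / 2.0


def contour_area(raster: Raster, t_crit: float = T_CRIT_DEFAULT):
    """Area (mm^2) of {raster > t_crit} with sub-cell contouring.

    NaN cells (outside the hull) count as below threshold.  Returns
    ``(area_mm2, contours)`` where ``contours`` is a list of (n, 2)
    polylines in mm coordinates for plotting; an empty super-threshold
    region yields area 0 and no contours.
    """
    v = raster.values
    u = np.where(np.isfinite(v), v - t_crit, -1.0e30)
    res = raster.resolution
    ny, nx = u.shape
    c00 = u[:-1, :-1]
    c10 = u[:-1, 1:]
    c11 = u[1:, 1:]
    c01 = u[1:, :-1]
    pos = np.stack([c00 > 0, c10 > 0, c11 > 0, c01 > 0])
    n_pos = pos.sum(axis=0)
    area = float(np.sum(n_pos == 4)) * res * res
    mixed = np.argwhere((n_pos > 0) & (n_pos < 4))
    for iy, ix in mixed:
        area += (
            _cell_polygon_area(c00[iy, ix], c10[iy, ix], c11[iy, ix], c01[iy, ix])
            * res
            * res
        )

    contours = []
    if (u > 0).any() and not (u > 0).all():
        from skimage import measure

        for c in measure.find_contours(np.nan_to_num(u, nan=-1.0e30), 0.0):
            xy = np.c_[raster.x_mm[0] + c[:, 1] * res, raster.y_mm[0] + c[:, 0] * res]
            contours.append(xy)
    return area, contours


@dataclass
class ScalpTMap:
    """Per-location t statistics with the interpolated, thresholded map."""

    layout: ScalpLayout
    t_values: pd.DataFrame  # columns: location, x_mm, y_mm, t, df
    t_crit: float
    raster: Raster
    area_mm2: float
    contours: list = field(default_factory=list)

    @property
    def significant_ids(self) -> list:
        return self.t_values.loc[self.t_values["t"] > self.t_crit, "location"].tolist()


def build_tmap(
    mep_table: pd.DataFrame,
    layout: ScalpLayout,
    t_crit: float = T_CRIT_DEFAULT,
    resolution_mm: float = 1.0,
) -> ScalpTMap:
    """Group t map over a layout from a normalised MEP table."""
    rows = []
    for loc, x, y in layout.locations:
        t, df = location_t(mep_table, loc)
        rows.append({"location": loc, "x_mm": x, "y_mm": y, "t": t, "df": df})
    tvals = pd.DataFrame(rows)
    raster = interpolate(layout, tvals["t"].to_numpy(), resolution_mm)
    area, contours = contour_area(raster, t_crit)
    return ScalpTMap(layout, tvals, t_crit, raster, area, contours)
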