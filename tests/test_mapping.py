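"""Layouts, per-location t statistics, interpolation and contour areas."""

import numpy as np
import pandas as pd
import pytest

from mepmap.mapping import (
    Raster,
    build_tmap,
    contour_area,
    interpolate,
    location_t,
    make_layout,
)


class TestLayouts:
    def test_line5_interior_points(self):
        lay = make_layout("line5", start=(0, 0), end=(40, -40))
        assert lay.xy.tolist() == [[0, 0], [10, -10], [20, -20], [30, -30], [40, -40]]

    def test_circles17_radii(self):
        lay = make_layout("circles17", center=(0, 0))
        r = np.linalg.norm(lay.xy, axis=1)
        assert lay.xy.shape[0] == 17
        assert np.sum(np.isclose(r, 0)) == 1
        assert np.sum(np.isclose(r, 35.0)) == 8
        assert np.sum(np.isclose(r, 70.0)) == 8
        # first ring point toward North
        assert lay.xy[1] == pytest.approx([0.0, 35.0])

    def test_search_grid_span(self):
        lay = make_layout("search_grid", n=5, spacing=10.0)
        assert lay.xy.shape[0] == 25
        assert lay.xy[:, 0].max() - lay.xy[:, 0].min() == pytest.approx(40.0)
        assert lay.xy[:, 1].max() - lay.xy[:, 1].min() == pytest.approx(40.0)

    def test_grid27_has_27_unique_sites(self):
        lay = make_layout("grid27", center=(-51, 1))
        assert lay.xy.shape[0] == 27
        assert len({tuple(np.round(p, 6)) for p in lay.xy}) == 27

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown layout"):
            make_layout("hexagon")


class TestLocationT:
    def _table(self, diffs):
        rows = []
        for i, d in enumerate(diffs):
            rows.append({"participant": f"P{i}", "location": 1,
                         "amp_norm": d, "amp_pre_norm": 0.0})
        return pd.DataFrame(rows)

    def test_identical_post_pre_is_degenerate(self):
        t = self._table([0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="zero-variance"):
            location_t(t, 1)

    def test_hand_computed_value(self):
        t, df = location_t(self._table([1.0, 2.0, 3.0]), 1)
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert df == 2

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError, match="participants"):
            location_t(self._table([1.0]), 1)

    def test_null_calibration(self, rng):
        """|t| > 2.20 in about 5% of null replicates at n = 12."""
        n_rej = 0
        reps = 2000
        for _ in range(reps):
            d = rng.normal(size=12)
            t = d.mean() / (d.std(ddof=1) / np.sqrt(12))
            n_rej += abs(t) > 2.200985
        assert n_rej / reps == pytest.approx(0.05, abs=0.015)


class TestInterpolate:
    def test_constant_values_give_constant_raster(self):
        lay = make_layout("grid27")
        r = interpolate(lay, np.full(27, 3.7))
        vals = r.values[np.isfinite(r.values)]
        assert np.allclose(vals, 3.7)

    def test_nodes_reproduced_exactly(self):
        lay = make_layout("search_grid", n=3, spacing=10.0)
        vals = np.arange(9, dtype=float)
        r = interpolate(lay, vals)
        for (loc, x, y), v in zip(lay.locations, vals):
            ix = np.argmin(np.abs(r.x_mm - x))
            iy = np.argmin(np.abs(r.y_mm - y))
            assert r.values[iy, ix] == pytest.approx(v, abs=1e-9)

    def test_linear_field_reproduced_everywhere(self):
        lay = make_layout("grid27")
        a, b, c = 0.03, -0.07, 1.5
        vals = a * lay.xy[:, 0] + b * lay.xy[:, 1] + c
        r = interpolate(lay, vals)
        gx, gy = np.meshgrid(r.x_mm, r.y_mm)
        expected = a * gx + b * gy + c
        mask = np.isfinite(r.values)
        assert np.allclose(r.values[mask], expected[mask], atol=1e-9)

    def test_collinear_layout_rejected(self):
        lay = make_layout("line5", start=(0, 0), end=(40, -40))
        with pytest.raises(ValueError, match="collinear"):
            interpolate(lay, np.arange(5.0))


def disc_raster(radius=20.0, extent=30, res=1.0, t_crit=2.20):
    xs = np.arange(-extent, extent + res / 2, res)
    gx, gy = np.meshgrid(xs, xs)
    vals = t_crit + (radius**2 - (gx**2 + gy**2)) / 100.0
    return Raster(vals, xs, xs)


class TestContourArea:
    def test_all_below_threshold_is_zero(self):
        xs = np.arange(0, 11.0)
        r = Raster(np.zeros((11, 11)), xs, xs)
        area, contours = contour_area(r, 2.2)
        assert area == 0.0
        assert contours == []

    def test_all_above_threshold_covers_grid(self):
        xs = np.arange(0, 11.0)
        r = Raster(np.full((11, 11), 5.0), xs, xs)
        area, _ = contour_area(r, 2.2)
        assert area == pytest.approx(100.0)

    def test_analytic_disc_area(self):
        area, contours = contour_area(disc_raster(), 2.20)
        assert area == pytest.approx(np.pi * 400.0, rel=0.02)
        assert len(contours) >= 1

    def test_monotone_non_increasing_in_threshold(self):
        r = disc_raster()
        areas = [contour_area(r, t)[0] for t in np.linspace(1.0, 6.0, 12)]
        assert all(b <= a + 1e-9 for a, b in zip(areas, areas[1:]))

    def test_agrees_with_quarter_mm_pixel_counting(self, rng):
        """Marching-squares area vs brute-force pixel counting of the
        bilinearly refined field at 0.25 mm, on random smooth fields."""
        from scipy.interpolate import RegularGridInterpolator

        xs = np.arange(-30, 31.0)
        gx, gy = np.meshgrid(xs, xs)
        for _ in range(5):
            field = np.zeros_like(gx, dtype=float)
            for _ in range(4):
                cx, cy = rng.uniform(-20, 20, 2)
                w = rng.uniform(8, 18)
                field += rng.uniform(1, 5) * np.exp(
                    -((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * w**2)
                )
            r = Raster(field, xs, xs)
            t_crit = float(np.percentile(field, 70))
            area, _ = contour_area(r, t_crit)
            interp = RegularGridInterpolator((xs, xs), field.T)
            fine = np.arange(-30, 30.001, 0.25)
            fx, fy = np.meshgrid(fine, fine)
            pix = np.count_nonzero(
                interp(np.c_[fx.ravel(), fy.ravel()]) > t_crit
            ) * 0.25**2
            assert area == pytest.approx(pix, rel=0.02)


class TestBuildTmap:
    def test_flat_generated_table_gives_no_significant_sites(self, rng):
        lay = make_layout("search_grid", n=3, spacing=20.0)
        rows = []
        for loc, _, _ in lay.locations:
            for p in range(12):
                rows.append({"participant": f"P{p}", "location": loc,
                             "amp_norm": rng.normal(0.5, 0.1),
                             "amp_pre_norm": rng.normal(0.5, 0.1)})
        tmap = build_tmap(pd.DataFrame(rows), lay, t_crit=5.0)
        assert tmap.area_mm2 == 0.0
        assert tmap.significant_ids == []
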