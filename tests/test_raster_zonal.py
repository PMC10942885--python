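"""Raster I/O round-trips and zonal-mean extraction."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Point, box

from agbsat.raster import (
    SceneRaster,
    SpectralTable,
    attach_agb,
    read_scene,
    write_scene,
    zonal_means,
)


def make_raster(values, pixel=1.0, x0=0.0, ytop=None):
    values = np.asarray(values, dtype=np.float32)
    if values.ndim == 2:
        values = values[None]
    ytop = values.shape[1] * pixel if ytop is None else ytop
    names = tuple(f"b{i}" for i in range(values.shape[0]))
    return SceneRaster(values, names, (x0, pixel, 0.0, ytop, 0.0, -pixel))


class TestIO:
    def test_roundtrip_preserves_values_and_order(self, small_scene, tmp_path):
        path = write_scene(small_scene.raster, tmp_path / "s.tif")
        back = read_scene(path)
        assert back.band_names == small_scene.raster.band_names
        assert back.transform == pytest.approx(small_scene.raster.transform)
        assert np.array_equal(back.values, small_scene.raster.values)

    def test_band_count_mismatch_warns_not_fails(self, tmp_path):
        r = make_raster(np.zeros((3, 4, 5)))
        path = write_scene(r, tmp_path / "three.tif")
        with pytest.warns(UserWarning, match="expected 8 bands"):
            back = read_scene(path, expect_bands=8)
        assert back.n_bands == 3

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_scene(tmp_path / "nope.tif")


class TestZonalMeans:
    def test_constant_field_any_polygon(self):
        r = make_raster(np.full((6, 8), 0.4))
        poly = Point(4.0, 3.0).buffer(2.3)
        table = zonal_means(r, [("p", poly)])
        assert table.bands.loc["p", "b0"] == pytest.approx(0.4)

    def test_hand_mean_two_pixels(self):
        vals = np.zeros((1, 4))
        vals[0, 1] = 0.2
        vals[0, 2] = 0.4
        r = make_raster(vals)
        # covers the centers of columns 1 and 2 only
        poly = box(1.0, 0.0, 3.0, 1.0)
        table = zonal_means(r, [("p", poly)])
        assert table.bands.loc["p", "b0"] == pytest.approx(0.3)

    def test_polygon_outside_dropped_with_warning(self, caplog):
        r = make_raster(np.ones((4, 4)))
        with caplog.at_level("WARNING"):
            table = zonal_means(
                r, [("in", box(0, 0, 4, 4)), ("out", box(10, 10, 12, 12))]
            )
        assert list(table.bands.index) == ["in"]
        assert "out" in caplog.text

    def test_shared_edge_ownership_is_exclusive(self):
        """Adjacent plots sharing an edge never share a pixel center."""
        vals = np.arange(16, dtype=float).reshape(4, 4)
        r = make_raster(vals, pixel=2.0)  # centers at odd coordinates
        left = box(0.0, 0.0, 3.0, 8.0)  # boundary x=3 passes through centers
        right = box(3.0, 0.0, 8.0, 8.0)
        table = zonal_means(r, [("L", left), ("R", right)])
        # 16 pixels total, split exclusively between the two plots
        n_left = ((np.indices((4, 4))[1] * 2 + 1) <= 3).sum()
        assert table.bands.loc["L", "b0"] * n_left + table.bands.loc[
            "R", "b0"
        ] * (16 - n_left) == pytest.approx(vals.sum())

    def test_matches_bruteforce_enumeration(self, rng):
        """Oracle: per-pixel loop with point-in-polygon, same tie rule."""
        for trial in range(20):
            nrows, ncols = rng.integers(3, 8, 2)
            vals = rng.random((2, nrows, ncols))
            r = make_raster(vals, pixel=1.0)
            pts = rng.uniform(-1, max(nrows, ncols) + 1, (6, 2))
            poly = shapely.convex_hull(shapely.multipoints(pts))
            xs, ys = r.pixel_centers()
            acc = []
            for i in range(nrows):
                for j in range(ncols):
                    p = Point(xs[j], ys[i])
                    inside = poly.contains(p)
                    if not inside and poly.intersects(p):
                        inside = poly.contains(
                            Point(xs[j] - 1e-9, ys[i] + 1e-9)
                        )
                    if inside:
                        acc.append(vals[:, i, j])
            table = zonal_means(r, [("p", poly)])
            if not acc:
                assert "p" not in table.bands.index
                continue
            expected = np.mean(acc, axis=0)
            got = table.bands.loc["p"].to_numpy()
            assert np.allclose(got, expected, atol=1e-12)

    def test_translation_invariance(self, rng):
        vals = rng.random((1, 5, 7))
        poly = Point(3.1, 2.4).buffer(1.7)
        t0 = zonal_means(make_raster(vals), [("p", poly)])
        shift = 13.25
        r2 = make_raster(vals, x0=shift, ytop=5 + shift)
        poly2 = shapely.transform(poly, lambda xy: xy + shift)
        t1 = zonal_means(r2, [("p", poly2)])
        assert np.allclose(
            t0.bands.to_numpy(), t1.bands.to_numpy(), atol=1e-9
        )


class TestAttachAGB:
    @staticmethod
    def table(ids):
        df = pd.DataFrame(
            {"b0": np.linspace(0.1, 0.9, len(ids))}, index=pd.Index(ids, name="plot_id")
        )
        return SpectralTable(df)

    def test_full_match_keeps_all_rows(self):
        agb = pd.DataFrame(
            {"plot_id": ["a", "b"], "agb_kg_per_m2": [2.0, 3.0]}
        )
        out = attach_agb(self.table(["a", "b"]), agb)
        assert len(out.plot_ids) == 2
        assert out.agb.loc["b"] == 3.0

    def test_missing_id_dropped_with_warning(self, caplog):
        agb = pd.DataFrame({"plot_id": ["a"], "agb_kg_per_m2": [2.0]})
        with caplog.at_level("WARNING"):
            out = attach_agb(self.table(["a", "b"]), agb)
        assert list(out.bands.index) == ["a"]
        assert "b" in caplog.text

    def test_duplicate_id_rejected(self):
        agb = pd.DataFrame(
            {"plot_id": ["a", "a"], "agb_kg_per_m2": [2.0, 2.5]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            attach_agb(self.table(["a"]), agb)

    def test_csv_roundtrip(self, tmp_path):
        t = self.table(["a", "b"])
        t.agb = pd.Series([1.0, 2.0], index=t.bands.index)
        path = tmp_path / "t.csv"
        t.to_csv(path)
        back = SpectralTable.from_csv(path)
        assert np.allclose(back.bands.to_numpy(), t.bands.to_numpy())
        assert np.allclose(back.agb.to_numpy(), [1.0, 2.0])
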