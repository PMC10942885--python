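"""Multiband raster container, file I/O, and zonal statistics.

Rasters are stored as multiband float32 TIFF files (one page per band)
with band names, wavelength centers, and the affine geotransform carried
in a JSON ``ImageDescription`` tag.  Plot polygons travel as GeoJSON.

Zonal extraction uses the common center-in-polygon rule: a pixel belongs
to a polygon when its center lies inside it.  Centers that fall exactly
on a polygon boundary are resolved deterministically by nudging the test
point toward the upper-left map direction (-x, +y), so a center on a
shared vertical edge belongs to the left polygon and one on a shared
horizontal edge to the upper polygon.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import shape as shapely_shape

from .bands import CENTER_NM

logger = logging.getLogger(__name__)

_META_KEY = "agbsat"


@dataclass
class SceneRaster:
    """Georeferenced band x row x col grid of reflectance (or stretched counts).

    ``transform`` is a GDAL-style 6-tuple ``(x0, dx, 0, y0, 0, dy)`` with
    ``dy < 0`` (row index increases southwards); the pixel center of
    ``(row, col)`` is ``(x0 + (col + 0.5) dx, y0 + (row + 0.5) dy)``.
    """

    values: np.ndarray  # (n_bands, n_rows, n_cols)
    band_names: tuple[str, ...]
    transform: tuple[float, float, float, float, float, float]
    wavelengths_nm: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("values must be (bands, rows, cols)")
        if self.values.shape[0] != len(self.band_names):
            raise ValueError("band_names length must match band axis")
        if len(set(self.band_names)) != len(self.band_names):
            raise ValueError("band names must be unique")
        if not self.wavelengths_nm:
            self.wavelengths_nm = tuple(
                CENTER_NM.get(b, float("nan")) for b in self.band_names
            )

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def band(self, name: str) -> np.ndarray:
        return self.values[self.band_names.index(name)]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map-coordinate x (per column) and y (per row) of pixel centers."""
        x0, dx, _, y0, _, dy = self.transform
        nrows, ncols = self.shape
        xs = x0 + (np.arange(ncols) + 0.5) * dx
        ys = y0 + (np.arange(nrows) + 0.5) * dy
        return xs, ys


def write_scene(raster: SceneRaster, path: str | Path) -> Path:
    """Write a multiband float32 TIFF with JSON band/geo metadata."""
    path = Path(path)
    meta = {
        _META_KEY: {
            "band_names": list(raster.band_names),
            "wavelengths_nm": list(raster.wavelengths_nm),
            "transform": list(raster.transform),
        }
    }
    tifffile.imwrite(
        path,
        raster.values,
        photometric="minisblack",
        description=json.dumps(meta),
    )
    return path


def read_scene(path: str | Path, expect_bands: int | None = 8) -> SceneRaster:
    """Read a multiband TIFF written by :func:`write_scene` (or any TIFF).

    Files lacking the package's metadata tag are accepted with generic
    band names.  A band count differing from ``expect_bands`` triggers a
    warning, not a failure, so generic rasters remain usable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        values = tf.asarray()
        desc = tf.pages[0].description or ""
    if values.ndim == 2:
        values = values[None]
    meta = None
    try:
        meta = json.loads(desc).get(_META_KEY)
    except (json.JSONDecodeError, AttributeError):
        meta = None
    if meta is not None:
        band_names = tuple(meta["band_names"])
        transform = tuple(meta["transform"])
        wavelengths = tuple(meta.get("wavelengths_nm", ()))
    else:
        band_names = tuple(f"band{i + 1}" for i in range(values.shape[0]))
        transform = (0.0, 1.0, 0.0, float(values.shape[1]), 0.0, -1.0)
        wavelengths = ()
        logger.warning("%s: no band metadata found; using generic names", path)
    if expect_bands is not None and values.shape[0] != expect_bands:
        warnings.warn(
            f"{path}: expected {expect_bands} bands, found {values.shape[0]}; "
            "proceeding with the file's own layout",
            stacklevel=2,
        )
    return SceneRaster(values, band_names, transform, wavelengths)


@dataclass
class SpectralTable:
    """Plots x bands table of zonal mean reflectance, with optional AGB.

    ``bands`` is indexed by plot id; ``agb`` (kg/m2) shares that index
    when present.
    """

    bands: pd.DataFrame
    agb: pd.Series | None = None

    @property
    def band_names(self) -> list[str]:
        return list(self.bands.columns)

    @property
    def plot_ids(self) -> list:
        return list(self.bands.index)

    def copy(self) -> "SpectralTable":
        return SpectralTable(
            self.bands.copy(), None if self.agb is None else self.agb.copy()
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.bands.copy()
        if self.agb is not None:
            df["agb_kg_per_m2"] = self.agb
        return df

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index_label="plot_id")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralTable":
        df = pd.read_csv(path, index_col="plot_id")
        agb = None
        if "agb_kg_per_m2" in df.columns:
            agb = df.pop("agb_kg_per_m2")
        return cls(df, agb)


def _as_polygon_items(polygons) -> list[tuple[object, shapely.Geometry]]:
    """Normalize polygon input: GeoJSON path/dict or iterable of (id, geom)."""
    if isinstance(polygons, (str, Path)):
        with open(polygons) as fh:
            polygons = json.load(fh)
    if isinstance(polygons, dict) and polygons.get("type") == "FeatureCollection":
        items = []
        for i, feat in enumerate(polygons["features"]):
            pid = (feat.get("properties") or {}).get("plot_id", i)
            items.append((pid, shapely_shape(feat["geometry"])))
        return items
    return [(pid, geom) for pid, geom in polygons]


def _pixel_mask(
    raster: SceneRaster, geom: shapely.Geometry
) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of pixels whose centers fall in ``geom``.

    Boundary centers are resolved by re-testing the point nudged by a
    small offset toward (-x, +y); the nudge is far below pixel scale so
    strictly interior/exterior points are unaffected.
    """
    xs, ys = raster.pixel_centers()
    dx = abs(raster.transform[1])
    minx, miny, maxx, maxy = geom.bounds
    jj = np.nonzero((xs >= minx - dx) & (xs <= maxx + dx))[0]
    ii = np.nonzero((ys >= miny - dx) & (ys <= maxy + dx))[0]
    if len(jj) == 0 or len(ii) == 0:
        return np.empty(0, int), np.empty(0, int)
    gx, gy = np.meshgrid(xs[jj], ys[ii])
    inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel())
    on_edge = shapely.intersects(
        geom, shapely.points(gx.ravel(), gy.ravel())
    ) & ~inside
    if on_edge.any():
        eps = 1e-9 * dx
        inside[on_edge] = shapely.contains_xy(
            geom, gx.ravel()[on_edge] - eps, gy.ravel()[on_edge] + eps
        )
    sel = inside.reshape(gx.shape)
    r, c = np.nonzero(sel)
    return ii[r], jj[c]


def zonal_means(raster: SceneRaster, polygons) -> SpectralTable:
    """Per-plot, per-band arithmetic mean of pixels under each polygon.

    Plots covering zero pixel centers are dropped with a logged warning.
    """
    items = _as_polygon_items(polygons)
    rows = {}
    for pid, geom in items:
        rr, cc = _pixel_mask(raster, geom)
        if len(rr) == 0:
            logger.warning("plot %r covers no pixel centers; dropped", pid)
            continue
        rows[pid] = raster.values[:, rr, cc].mean(axis=1)
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(raster.band_names)
    ).astype(float)
    df.index.name = "plot_id"
    return SpectralTable(df)


def attach_agb(table: SpectralTable, agb_source) -> SpectralTable:
    """Inner-join plot AGB (kg/m2) onto the table by plot id.

    ``agb_source`` is a CSV path or DataFrame with ``plot_id`` and
    ``agb_kg_per_m2`` columns.  Duplicate plot ids are an error; ids
    missing on either side are reported and dropped.
    """
    if isinstance(agb_source, (str, Path)):
        agb_df = pd.read_csv(agb_source)
    else:
        agb_df = pd.DataFrame(agb_source)
    if "plot_id" not in agb_df.columns or "agb_kg_per_m2" not in agb_df.columns:
        raise ValueError("AGB table needs plot_id and agb_kg_per_m2 columns")
    if agb_df["plot_id"].duplicated().any():
        dups = agb_df.loc[agb_df["plot_id"].duplicated(), "plot_id"].tolist()
        raise ValueError(f"duplicate plot_id in AGB table: {dups}")
    agb = agb_df.set_index("plot_id")["agb_kg_per_m2"].astype(float)
    common = table.bands.index.intersection(agb.index)
    missing = table.bands.index.difference(agb.index)
    if len(missing):
        logger.warning("no AGB for plots %s; dropped", list(missing))
    return SpectralTable(table.bands.loc[common].copy(), agb.loc[common])
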