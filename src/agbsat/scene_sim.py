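"""Synthetic grassland fertilization-trial scenes with biomass saturation.

This module generates the three inputs the estimation pipeline consumes
(multiband reflectance raster, plot polygons, plot AGB table) for a
nitrogen-fertilization trial: rectangular plots laid out in replicate
blocks, two ammonium fertilizer series at three rates each plus a
control, a high-density stratum whose aboveground biomass (AGB) follows
a truncated normal calibrated to stated field moments, and a saturating
canopy reflectance model in which the red band loses sensitivity at
high biomass long before the near-infrared bands do.

Canopy reflectance follows a Beer-Lambert soil/canopy mixture::

    rho_b(AGB) = rho_inf_b + (rho_soil_b - rho_inf_b) * exp(-k_b * c * AGB)

with per-band extinction ``k_b`` (large in the red, small in the NIR so
red saturates first) and leaf area index proportional to AGB via ``c``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy import optimize, stats
from shapely.geometry import box, mapping

from .bands import SENSOR_BAND_NAMES
from .raster import SceneRaster, SpectralTable, _pixel_mask, write_scene

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Treatment:
    """A fertilizer treatment: product id, application rate, N stratum."""

    fertilizer: str
    rate_g_per_m2: float
    high_nitrogen: bool


#: Ammonium nitrate (AN) and ammonium sulfate (AS) series at three rates
#: each, plus an unfertilized control.  The two upper rates of each
#: series form the high-nitrogen stratum.
DEFAULT_TREATMENTS: tuple[Treatment, ...] = (
    Treatment("control", 0.0, False),
    Treatment("AN", 21.0, False),
    Treatment("AN", 42.1, True),
    Treatment("AN", 63.2, True),
    Treatment("AS", 33.6, False),
    Treatment("AS", 67.2, True),
    Treatment("AS", 100.8, True),
)


@dataclass(frozen=True)
class TrialDesign:
    """Geometry and treatment structure of the fertilization trial."""

    n_plots: int = 96
    plot_width_m: float = 3.0
    plot_length_m: float = 9.0
    n_blocks: int = 3
    treatments: tuple[Treatment, ...] = DEFAULT_TREATMENTS
    n_high_density: int = 47
    gap_m: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    pixel_size_m: float = 2.0
    #: Render pixels at pixel_size_m / supersample so that the 3 m x 9 m
    #: plots cover enough pixel centers for stable zonal means.
    supersample: int = 4
    #: "treatment": flag the plots assigned to high-nitrogen treatments
    #: (the rule that yields the configured count); "threshold": flag
    #: plots with AGB >= high_density_threshold instead.
    selector: str = "treatment"
    high_density_threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.n_high_density > self.n_plots:
            raise ValueError("n_high_density cannot exceed n_plots")
        for name in ("plot_width_m", "plot_length_m", "pixel_size_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gap_m < 0 or self.n_blocks < 1 or self.supersample < 1:
            raise ValueError("invalid layout parameters")
        if self.selector not in ("treatment", "threshold"):
            raise ValueError("selector must be 'treatment' or 'threshold'")
        if not any(t.high_nitrogen for t in self.treatments) and (
            self.n_high_density > 0
        ):
            raise ValueError("no high-nitrogen treatment to absorb the stratum")

    @property
    def plot_area_m2(self) -> float:
        return self.plot_width_m * self.plot_length_m


@dataclass(frozen=True)
class BiomassDistribution:
    """Truncated-normal AGB model for the two fertilization strata.

    ``mean``/``sd`` are the target moments of the *truncated* high-density
    distribution on (``lower``, ``upper``); the parent normal is solved by
    moment matching so that samples reproduce the stated moments rather
    than the naively shifted ones truncation would otherwise induce.
    """

    mean: float = 3.37
    sd: float = 0.7075
    lower: float = 1.5
    upper: float = 4.5
    low_density_mean: float = 1.5
    low_density_sd: float = 0.6
    low_density_bounds: tuple[float, float] = (0.2, 3.0)

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("lower must be below upper")
        if self.sd <= 0 or self.low_density_sd <= 0:
            raise ValueError("sd must be positive")
        if not (self.lower < self.mean < self.upper):
            raise ValueError("mean must lie inside the truncation bounds")
        lo, hi = self.low_density_bounds
        if not (lo < self.low_density_mean < hi):
            raise ValueError("low-density mean must lie inside its bounds")


@lru_cache(maxsize=32)
def _parent_normal(
    mean: float, sd: float, lower: float, upper: float
) -> tuple[float, float]:
    """Parent (mu, sigma) whose [lower, upper] truncation has the given moments."""

    def resid(p):
        mu, log_sigma = p
        sigma = float(np.exp(log_sigma))
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol, info, ier, msg = optimize.fsolve(
        resid, [mean, np.log(sd)], full_output=True
    )
    if ier != 1:
        raise ValueError(
            f"cannot calibrate truncated normal to mean={mean}, sd={sd} "
            f"on [{lower}, {upper}]: {msg}"
        )
    return float(sol[0]), float(np.exp(sol[1]))


def _sample_truncated(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    lower: float,
    upper: float,
) -> np.ndarray:
    """Seeded rejection sampling from the calibrated truncated normal."""
    mu, sigma = _parent_normal(mean, sd, lower, upper)
    out: list[float] = []
    while len(out) < n:
        draw = rng.normal(mu, sigma, size=max(4 * (n - len(out)), 16))
        out.extend(draw[(draw >= lower) & (draw <= upper)].tolist())
    return np.asarray(out[:n])


@dataclass(frozen=True)
class CanopyModelParams:
    """Beer-Lambert soil/canopy mixture parameters per sensor band.

    Arrays follow the sensor band order.  ``lai_per_agb`` converts AGB
    (kg/m2) to leaf area index; ``pixel_noise_sd`` is additive Gaussian
    reflectance noise per pixel; ``plot_noise_cv`` is a multiplicative
    per-plot, per-band deviation (coefficient of variation) modelling
    plot-scale canopy heterogeneity that zonal averaging cannot remove.
    """

    soil_reflectance: tuple[float, ...] = (
        0.12, 0.14, 0.24, 0.21, 0.22, 0.25, 0.28, 0.30,
    )
    asymptotic_reflectance: tuple[float, ...] = (
        0.03, 0.04, 0.05, 0.07, 0.015, 0.35, 0.50, 0.48,
    )
    extinction: tuple[float, ...] = (
        0.90, 1.00, 0.18, 0.50, 2.00, 0.25, 0.15, 0.17,
    )
    lai_per_agb: float = 1.5
    pixel_noise_sd: float = 0.01
    plot_noise_cv: float = 0.05

    def __post_init__(self) -> None:
        soil = np.asarray(self.soil_reflectance)
        inf = np.asarray(self.asymptotic_reflectance)
        k = np.asarray(self.extinction)
        n = len(SENSOR_BAND_NAMES)
        if not (len(soil) == len(inf) == len(k) == n):
            raise ValueError(f"expected {n} per-band parameters")
        if ((soil < 0) | (soil > 1) | (inf < 0) | (inf > 1)).any():
            raise ValueError("reflectances must lie in [0, 1]")
        if (k <= 0).any() or self.lai_per_agb <= 0:
            raise ValueError("extinction and lai_per_agb must be positive")
        if self.pixel_noise_sd < 0 or self.plot_noise_cv < 0:
            raise ValueError("noise parameters must be non-negative")
        i_red = SENSOR_BAND_NAMES.index("red")
        for nir in ("nir1", "nir2"):
            if not k[i_red] > k[SENSOR_BAND_NAMES.index(nir)]:
                raise ValueError(
                    "red extinction must exceed NIR extinction "
                    "(red saturates first)"
                )


@dataclass
class PlotRecord:
    """One trial plot: treatment, biomass, stratum flag, and footprint."""

    plot_id: str
    treatment: Treatment
    block: int
    agb_kg_per_m2: float
    agb_kg_per_plot: float
    high_density: bool
    geometry: shapely.Geometry


def canopy_reflectance(params: CanopyModelParams, agb: float) -> np.ndarray:
    """Noise-free per-band reflectance of a canopy with the given AGB."""
    if agb < 0:
        raise ValueError("agb must be non-negative")
    soil = np.asarray(params.soil_reflectance)
    inf = np.asarray(params.asymptotic_reflectance)
    k = np.asarray(params.extinction)
    rho = inf + (soil - inf) * np.exp(-k * params.lai_per_agb * agb)
    return np.clip(rho, 0.0, 1.0)


def _treatment_counts(design: TrialDesign) -> list[tuple[Treatment, int]]:
    """Plot counts per treatment: the high-nitrogen treatments absorb
    exactly ``n_high_density`` plots, the rest go to the low stratum."""
    high = [t for t in design.treatments if t.high_nitrogen]
    low = [t for t in design.treatments if not t.high_nitrogen]
    n_low = design.n_plots - design.n_high_density
    if n_low > 0 and not low:
        raise ValueError("no low-nitrogen treatment to absorb remaining plots")
    counts: list[tuple[Treatment, int]] = []
    for group, total in ((high, design.n_high_density), (low, n_low)):
        if not group:
            continue
        base, extra = divmod(total, len(group))
        for i, t in enumerate(group):
            counts.append((t, base + (1 if i < extra else 0)))
    return counts


def _plot_geometry(design: TrialDesign, idx: int) -> tuple[shapely.Geometry, int]:
    """Axis-aligned plot rectangle and block id for plot ``idx``.

    Blocks are stacked rows; within a block plots sit side by side with
    ``gap_m`` spacing, width along x and length along y.
    """
    per_block = -(-design.n_plots // design.n_blocks)  # ceil
    block, col = divmod(idx, per_block)
    x0, y0 = design.origin
    px = x0 + col * (design.plot_width_m + design.gap_m)
    py = y0 + block * (design.plot_length_m + design.gap_m)
    geom = box(px, py, px + design.plot_width_m, py + design.plot_length_m)
    return geom, block


def sample_trial(
    design: TrialDesign, dist: BiomassDistribution, seed: int
) -> list[PlotRecord]:
    """Draw one randomized trial: treatments, AGB, geometry per plot."""
    rng = np.random.default_rng(seed)
    labels: list[Treatment] = []
    for t, count in _treatment_counts(design):
        labels.extend([t] * count)
    labels = list(np.asarray(labels, dtype=object)[rng.permutation(len(labels))])

    n_high = sum(1 for t in labels if t.high_nitrogen)
    agb_high = _sample_truncated(
        rng, n_high, dist.mean, dist.sd, dist.lower, dist.upper
    )
    lo, hi = dist.low_density_bounds
    agb_low = _sample_truncated(
        rng,
        len(labels) - n_high,
        dist.low_density_mean,
        dist.low_density_sd,
        lo,
        hi,
    )
    records: list[PlotRecord] = []
    ih = il = 0
    for idx, t in enumerate(labels):
        if t.high_nitrogen:
            agb = float(agb_high[ih])
            ih += 1
        else:
            agb = float(agb_low[il])
            il += 1
        geom, block = _plot_geometry(design, idx)
        if design.selector == "treatment":
            flag = t.high_nitrogen
        else:
            flag = agb >= design.high_density_threshold
        records.append(
            PlotRecord(
                plot_id=f"p{idx + 1:03d}",
                treatment=t,
                block=block,
                agb_kg_per_m2=agb,
                agb_kg_per_plot=agb * design.plot_area_m2,
                high_density=flag,
                geometry=geom,
            )
        )
    return records


@dataclass
class SimulatedScene:
    """A rendered trial: raster, plot polygons (GeoJSON dict), truth table."""

    raster: SceneRaster
    features: dict
    truth: pd.DataFrame


def render_scene(
    plots: list[PlotRecord],
    params: CanopyModelParams,
    design: TrialDesign,
    seed: int,
) -> SimulatedScene:
    """Rasterize the trial at the design's (supersampled) pixel size.

    Every pixel whose center falls inside a plot receives the plot's
    realized reflectance (closed-form canopy reflectance times the
    plot-level deviation) plus per-pixel Gaussian noise; background
    pixels receive soil reflectance plus the same per-pixel noise.  All
    values are clipped to [0, 1].
    """
    tree = shapely.STRtree([p.geometry for p in plots])
    for i, p in enumerate(plots):
        for j in tree.query(p.geometry, predicate="intersects"):
            if j != i and p.geometry.intersection(plots[j].geometry).area > 0:
                raise ValueError(
                    f"overlapping plot polygons: {p.plot_id} and "
                    f"{plots[j].plot_id}"
                )

    rng = np.random.default_rng(seed)
    px = design.pixel_size_m / design.supersample
    bounds = shapely.total_bounds(shapely.GeometryCollection(
        [p.geometry for p in plots]
    ))
    margin = 2 * design.pixel_size_m
    minx, miny = bounds[0] - margin, bounds[1] - margin
    maxx, maxy = bounds[2] + margin, bounds[3] + margin
    ncols = int(np.ceil((maxx - minx) / px))
    nrows = int(np.ceil((maxy - miny) / px))
    transform = (minx, px, 0.0, maxy, 0.0, -px)

    soil = np.asarray(params.soil_reflectance, dtype=np.float64)
    nb = len(SENSOR_BAND_NAMES)
    values = np.broadcast_to(
        soil[:, None, None], (nb, nrows, ncols)
    ).copy()

    raster = SceneRaster(
        np.zeros((nb, nrows, ncols), np.float32), SENSOR_BAND_NAMES, transform
    )
    for p in plots:
        rho = canopy_reflectance(params, p.agb_kg_per_m2)
        if params.plot_noise_cv > 0:
            rho = rho * (1.0 + rng.normal(0.0, params.plot_noise_cv, nb))
            rho = np.clip(rho, 0.0, 1.0)
        rr, cc = _pixel_mask(raster, p.geometry)
        if len(rr) == 0:
            raise ValueError(
                f"plot {p.plot_id} covers no pixel centers at {px} m pixels"
            )
        values[:, rr, cc] = rho[:, None]
    if params.pixel_noise_sd > 0:
        values = values + rng.normal(0.0, params.pixel_noise_sd, values.shape)
    values = np.clip(values, 0.0, 1.0)
    raster = SceneRaster(
        values.astype(np.float32), SENSOR_BAND_NAMES, transform
    )

    features = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(p.geometry),
                "properties": {
                    "plot_id": p.plot_id,
                    "fertilizer": p.treatment.fertilizer,
                    "rate_g_per_m2": p.treatment.rate_g_per_m2,
                    "block": p.block,
                    "high_density": bool(p.high_density),
                },
            }
            for p in plots
        ],
    }
    truth = pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in plots],
            "agb_kg_per_m2": [p.agb_kg_per_m2 for p in plots],
            "agb_kg_per_plot": [p.agb_kg_per_plot for p in plots],
            "high_density": [bool(p.high_density) for p in plots],
        }
    )
    return SimulatedScene(raster, features, truth)


def simulate(
    design: TrialDesign | None = None,
    dist: BiomassDistribution | None = None,
    params: CanopyModelParams | None = None,
    seed: int = 0,
) -> SimulatedScene:
    """Sample a trial and render it in one call (convenience wrapper)."""
    design = design or TrialDesign()
    dist = dist or BiomassDistribution()
    params = params or CanopyModelParams()
    plots = sample_trial(design, dist, seed)
    # Independent stream for rendering noise so plot sampling and pixel
    # noise stay decoupled under a shared seed.
    return render_scene(plots, params, design, seed=seed + 1)


def gradient_trial(
    n_plots: int = 200,
    agb_range: tuple[float, float] = (0.5, 4.5),
    design: TrialDesign | None = None,
    params: CanopyModelParams | None = None,
    seed: int = 0,
) -> SimulatedScene:
    """A diagnostic scene with AGB spread uniformly over ``agb_range``.

    Used to probe index saturation across the whole biomass gradient
    rather than the fertilization strata.
    """
    base = design or TrialDesign()
    design = replace(
        base,
        n_plots=n_plots,
        n_high_density=0,
        n_blocks=max(base.n_blocks, int(np.ceil(n_plots / 32))),
    )
    params = params or CanopyModelParams()
    rng = np.random.default_rng(seed)
    lo, hi = agb_range
    agb = rng.uniform(lo, hi, n_plots)
    low_treatment = next(t for t in design.treatments if not t.high_nitrogen)
    plots = []
    for idx in range(n_plots):
        geom, block = _plot_geometry(design, idx)
        plots.append(
            PlotRecord(
                plot_id=f"p{idx + 1:03d}",
                treatment=low_treatment,
                block=block,
                agb_kg_per_m2=float(agb[idx]),
                agb_kg_per_plot=float(agb[idx]) * design.plot_area_m2,
                high_density=False,
                geometry=geom,
            )
        )
    return render_scene(plots, params, design, seed=seed + 1)


def expected_table(
    plots: list[PlotRecord], params: CanopyModelParams
) -> SpectralTable:
    """Closed-form (noise-free) band table for a list of plots."""
    rows = {
        p.plot_id: canopy_reflectance(params, p.agb_kg_per_m2) for p in plots
    }
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(SENSOR_BAND_NAMES)
    )
    df.index.name = "plot_id"
    agb = pd.Series(
        {p.plot_id: p.agb_kg_per_m2 for p in plots}, name="agb_kg_per_m2"
    )
    return SpectralTable(df, agb.loc[df.index])


def write_outputs(scene: SimulatedScene, outdir: str | Path) -> dict[str, Path]:
    """Write raster (.tif), polygons (.geojson), and truth table (.csv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "raster": write_scene(scene.raster, outdir / "scene.tif"),
        "polygons": outdir / "plots.geojson",
        "truth": outdir / "truth.csv",
    }
    with open(paths["polygons"], "w") as fh:
        json.dump(scene.features, fh)
    scene.truth.to_csv(paths["truth"], index=False)
    return paths
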