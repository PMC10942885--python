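"""Experiment orchestration: the enhancement-variant x variable-group grid.

For each enhancement variant (original image; linear stretch + SVD;
histogram equalization + SVD) the pipeline runs

    stretch raster -> zonal means -> attach AGB -> nir3 -> SVD denoise
    -> index evaluation -> per-group forest evaluation

and reports cross-validated R2 / RMSE per variable group (all variables,
bands only, all indices, standard NDVI alone, and the top-3 optimal
model), together with averaged variable importances and per-plot
out-of-fold predictions.  Every run writes a log with the seed, a config
hash, and software versions so outputs are reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enhance import StretchSpec, enhance_raster, enhance_table
from .indices import band_features, evaluate, full_catalog, make_nir3
from .raster import attach_agb, read_scene, zonal_means
from .regression import (
    EvaluationResult,
    ModelConfig,
    evaluate_group,
    evaluate_optimal,
)
from .scene_sim import (
    BiomassDistribution,
    CanopyModelParams,
    TrialDesign,
    simulate,
)
from .svd import denoise_table, diagnostics_frame

logger = logging.getLogger(__name__)

VARIANTS: tuple[str, ...] = ("original", "linear_svd", "histeq_svd")
GROUPS: tuple[str, ...] = (
    "all_variables",
    "bands_only",
    "all_indices",
    "standard_ndvi",
    "optimal_top3",
)

_VARIANT_STRETCH = {
    "original": "none",
    "linear_svd": "linear_minmax",
    "histeq_svd": "histogram_equalization",
}


@dataclass
class RunConfig:
    """Everything a full grid run needs.

    Exactly one input mode: either ``simulate_inputs`` is True (the
    built-in trial simulator provides raster, polygons, and AGB) or the
    three input paths are given.
    """

    simulate_inputs: bool = True
    raster_path: str | None = None
    polygons_path: str | None = None
    agb_path: str | None = None
    design: TrialDesign = field(default_factory=TrialDesign)
    dist: BiomassDistribution = field(default_factory=BiomassDistribution)
    canopy: CanopyModelParams = field(default_factory=CanopyModelParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    variants: tuple[str, ...] = VARIANTS
    groups: tuple[str, ...] = GROUPS
    stretch_stage: str = "raster"  # "raster" | "table"
    svd_threshold: float = 0.5
    svd_sv_floor: float = 0.01
    svd_center: bool = False
    high_density_only: bool = True
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        paths = (self.raster_path, self.polygons_path, self.agb_path)
        if self.simulate_inputs and any(p is not None for p in paths):
            raise ValueError("choose simulator inputs or file inputs, not both")
        if not self.simulate_inputs and any(p is None for p in paths):
            raise ValueError("file mode needs raster, polygons, and AGB paths")
        if self.stretch_stage not in ("raster", "table"):
            raise ValueError("stretch_stage must be 'raster' or 'table'")
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown variants: {sorted(unknown)}")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the scientific configuration.

    The output directory is excluded: where results land does not change
    what was computed.
    """
    payload = dataclasses.asdict(config)
    payload.pop("outdir", None)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _acquire_inputs(config: RunConfig):
    """Raster, polygon features, AGB frame (with high-density flags)."""
    if config.simulate_inputs:
        scene = simulate(
            config.design, config.dist, config.canopy, seed=config.seed
        )
        return scene.raster, scene.features, scene.truth
    for p in (config.raster_path, config.polygons_path, config.agb_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    raster = read_scene(config.raster_path)
    with open(config.polygons_path) as fh:
        features = json.load(fh)
    agb = pd.read_csv(config.agb_path)
    return raster, features, agb


def prepare_variant_table(config: RunConfig, variant: str, raster, features, agb):
    """Run one variant's table-level pipeline up to the denoised bands."""
    spec = StretchSpec(method=_VARIANT_STRETCH[variant])
    if config.stretch_stage == "raster" and spec.method != "none":
        raster = enhance_raster(raster, spec)
    table = zonal_means(raster, features)
    if config.stretch_stage == "table" and spec.method != "none":
        table = enhance_table(table, spec)
    table = attach_agb(table, agb)
    if config.high_density_only and "high_density" in agb.columns:
        keep = set(agb.loc[agb["high_density"].astype(bool), "plot_id"])
        idx = [i for i in table.bands.index if i in keep]
        table = type(table)(table.bands.loc[idx], table.agb.loc[idx])
    table = make_nir3(table)
    svd_info = None
    if variant != "original":
        table, res, retained = denoise_table(
            table,
            threshold=config.svd_threshold,
            sv_floor=config.svd_sv_floor,
            center=config.svd_center,
        )
        svd_info = diagnostics_frame(res, retained)
    return table, svd_info


def _group_features(group: str, bands: pd.DataFrame, idx: pd.DataFrame):
    if group == "all_variables":
        return pd.concat([bands, idx], axis=1)
    if group == "bands_only":
        return bands
    if group == "all_indices":
        return idx
    if group == "standard_ndvi":
        return idx[["NDVI 1"]]
    raise ValueError(f"unknown group {group!r}")


def run_experiment(config: RunConfig) -> dict:
    """Execute the full variant x group grid; optionally write outputs.

    Returns a dict with per-cell :class:`EvaluationResult` objects, the
    results table, and (when ``outdir`` is set) the output paths.
    """
    raster, features, agb = _acquire_inputs(config)
    results: dict[tuple[str, str], EvaluationResult] = {}
    svd_diags: dict[str, pd.DataFrame] = {}
    for variant in config.variants:
        table, svd_info = prepare_variant_table(
            config, variant, raster, features, agb
        )
        if svd_info is not None:
            svd_diags[variant] = svd_info
        feats = evaluate(table, full_catalog())
        bands = band_features(table)
        y = table.agb.to_numpy()
        for group in config.groups:
            cfg = config.model
            if group == "optimal_top3":
                res = evaluate_optimal(
                    _group_features("all_variables", bands, feats.values),
                    y,
                    cfg,
                    group=group,
                    variant=variant,
                )
            else:
                res = evaluate_group(
                    _group_features(group, bands, feats.values),
                    y,
                    cfg,
                    group=group,
                    variant=variant,
                )
            res.predictions = (
                None
                if res.predictions is None
                else res.predictions.set_axis(table.bands.index)
            )
            results[(variant, group)] = res
            logger.info(
                "%s / %s: R2=%.3f RMSE=%.3f", variant, group, res.r2, res.rmse
            )

    grid = _results_grid(results, config)
    out = {"results": results, "grid": grid, "config_hash": config_hash(config)}
    if config.outdir is not None:
        out["paths"] = _write_outputs(config, grid, results, svd_diags)
    return out


def _results_grid(results, config: RunConfig) -> pd.DataFrame:
    rows = []
    for variant in config.variants:
        for metric in ("r2", "rmse"):
            row = {"variant": variant, "metric": metric}
            for group in config.groups:
                row[group] = round(getattr(results[(variant, group)], metric), 6)
            rows.append(row)
    return pd.DataFrame(rows)


def _write_outputs(config, grid, results, svd_diags) -> dict[str, Path]:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    paths: dict[str, Path] = {}

    paths["results"] = outdir / "results.csv"
    with open(paths["results"], "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        grid.to_csv(fh, index=False)

    imp_rows = []
    for (variant, group), res in results.items():
        if group != "all_variables":
            continue
        s = res.importance.sort_values(ascending=False)
        for rank, (name, val) in enumerate(s.items(), start=1):
            imp_rows.append(
                {
                    "variant": variant,
                    "rank": rank,
                    "variable": name,
                    "pct_inc_mse": round(float(val), 6),
                }
            )
    if imp_rows:
        paths["importance"] = outdir / "importance.csv"
        with open(paths["importance"], "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            pd.DataFrame(imp_rows).to_csv(fh, index=False)

    pred_rows = []
    for (variant, group), res in results.items():
        if group != "optimal_top3" or res.predictions is None:
            continue
        for pid, val in res.predictions.items():
            pred_rows.append(
                {
                    "variant": variant,
                    "plot_id": pid,
                    "predicted": round(float(val), 6),
                }
            )
    if pred_rows:
        paths["predictions"] = outdir / "predictions.csv"
        with open(paths["predictions"], "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            pd.DataFrame(pred_rows).to_csv(fh, index=False)

    for variant, diag in svd_diags.items():
        p = outdir / f"svd_{variant}.csv"
        diag.to_csv(p, index=False)
        paths[f"svd_{variant}"] = p

    import sklearn

    paths["runlog"] = outdir / "runlog.json"
    with open(paths["runlog"], "w") as fh:
        json.dump(
            {
                "config_hash": chash,
                "seed": config.seed,
                "versions": {
                    "agbsat": __version__,
                    "numpy": np.__version__,
                    "pandas": pd.__version__,
                    "scikit-learn": sklearn.__version__,
                },
                "config": dataclasses.asdict(config),
            },
            fh,
            indent=2,
            default=str,
        )
    return paths
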