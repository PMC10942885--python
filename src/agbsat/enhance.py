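"""Per-band contrast enhancement: min-max linear stretch and histogram
equalization onto a 0-255 output range.

Both operations are rank-preserving, so they leave Spearman correlations
between a band and biomass untouched; what they change is the *shape* of
the value distribution that downstream matrix factorization sees.
Outputs are continuous by default; 8-bit style quantization onto a fixed
number of levels is opt-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

from .raster import SceneRaster, SpectralTable

logger = logging.getLogger(__name__)

_METHODS = ("linear_minmax", "histogram_equalization", "none")


@dataclass(frozen=True)
class StretchSpec:
    method: str = "linear_minmax"
    out_min: float = 0.0
    out_max: float = 255.0
    levels: int = 256
    quantize: bool = False

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if not self.out_min < self.out_max:
            raise ValueError("out_min must be below out_max")
        if self.levels < 2:
            raise ValueError("levels must be at least 2")


def linear_stretch(values, spec: StretchSpec = StretchSpec()) -> np.ndarray:
    """Affine remap of [min, max] onto [out_min, out_max].

    A constant input is degenerate (zero dynamic range): all values map
    to ``out_min`` and a warning is logged.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    lo, hi = v.min(), v.max()
    if hi == lo:
        logger.warning("constant band: linear stretch maps all values to out_min")
        return np.full_like(v, spec.out_min)
    out = (v - lo) * (spec.out_max - spec.out_min) / (hi - lo) + spec.out_min
    if spec.quantize:
        out = _quantize(out, spec)
    return out


def histogram_equalize(values, spec: StretchSpec = StretchSpec()) -> np.ndarray:
    """Empirical-CDF remap: v' = out_min + (out_max - out_min) * F(v).

    F is the empirical CDF with mid-rank tie handling (average rank / n),
    so ties map to a common value and the mapping is monotone
    non-decreasing.  For n distinct values the sorted outputs are equally
    spaced over (out_min, out_max].
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    cdf = rankdata(v.ravel(), method="average") / v.size
    out = (spec.out_min + (spec.out_max - spec.out_min) * cdf).reshape(v.shape)
    if spec.quantize:
        out = _quantize(out, spec)
    return out


def _quantize(out: np.ndarray, spec: StretchSpec) -> np.ndarray:
    """Floor continuous outputs onto a grid of ``levels`` values."""
    span = spec.out_max - spec.out_min
    k = np.floor((out - spec.out_min) / span * spec.levels)
    k = np.clip(k, 0, spec.levels - 1)
    return spec.out_min + k * span / (spec.levels - 1)


def _apply(values: np.ndarray, spec: StretchSpec) -> np.ndarray:
    if spec.method == "none":
        return np.asarray(values, dtype=float)
    if spec.method == "linear_minmax":
        return linear_stretch(values, spec)
    return histogram_equalize(values, spec)


def enhance_table(table: SpectralTable, spec: StretchSpec) -> SpectralTable:
    """Apply the stretch column-wise (per band) across plots; AGB untouched."""
    out = table.copy()
    if spec.method == "none":
        return out
    for col in out.bands.columns:
        out.bands[col] = _apply(out.bands[col].to_numpy(), spec)
    return out


def enhance_raster(raster: SceneRaster, spec: StretchSpec) -> SceneRaster:
    """Apply the stretch to each full band of a raster (the image-level
    analogue of :func:`enhance_table`; this is the default pipeline stage)."""
    if spec.method == "none":
        return raster
    out = np.stack([_apply(b, spec) for b in raster.values])
    return SceneRaster(
        out.astype(np.float32),
        raster.band_names,
        raster.transform,
        raster.wavelengths_nm,
    )
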