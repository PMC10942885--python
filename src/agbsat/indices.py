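"""Vegetation index catalog: the modified normalized-difference family
over all ordered band pairs, plus the standard index families.

The modified family generalizes NDVI to any ordered band pair::

    index(i, j) = (R_i - R_j) / (R_i + R_j)

Over the 9-band set (8 sensor bands plus the derived ``nir3``) there are
72 ordered pairs; the three pairs (nir1, red), (nir2, red), (nir3, red)
are the classical NDVI 1-3 and are catalogued with the standard indices
instead, leaving 69 modified indices.  Ids m1..m69 are assigned
consecutively in row-major band order (coastal, blue, green, yellow,
red, rededge, nir1, nir2, nir3), skipping the three reassigned pairs:
m20 is green/red, m35 red/green, m51 nir1/green, m53 nir1/rededge.

Standard families (three NIR variants each, 15 total): NDVI, simple
ratio SR, enhanced vegetation index EVI, soil-adjusted vegetation index
SAVI, and green difference vegetation index GDVI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import ALL_BAND_NAMES, BandSet, DEFAULT_BANDSET
from .raster import SpectralTable

logger = logging.getLogger(__name__)

#: Ordered pairs reassigned to the standard catalog as NDVI 1-3.
NDVI_PAIRS: tuple[tuple[str, str], ...] = (
    ("nir1", "red"),
    ("nir2", "red"),
    ("nir3", "red"),
)

# Canonical published constants for the parameterized families.
EVI_G, EVI_C1, EVI_C2, EVI_L = 2.5, 6.0, 7.5, 1.0
SAVI_L, SAVI_SCALE = 0.5, 1.5


@dataclass(frozen=True)
class IndexSpec:
    """One index: id, family, ordered band arguments, fixed constants."""

    id: str
    family: str
    bands: tuple[str, ...]
    constants: dict = field(default_factory=dict, compare=False)


def make_nir3(table: SpectralTable) -> SpectralTable:
    """Add the derived nir3 band = arithmetic mean of nir1 and nir2."""
    for parent in ("nir1", "nir2"):
        if parent not in table.bands.columns:
            raise ValueError(f"cannot build nir3: missing band {parent!r}")
    out = table.copy()
    out.bands["nir3"] = (out.bands["nir1"] + out.bands["nir2"]) / 2.0
    return out


def modified_ndvi(Ri, Rj):
    """Normalized difference of two band values; NaN where Ri + Rj == 0."""
    Ri = np.asarray(Ri, dtype=float)
    Rj = np.asarray(Rj, dtype=float)
    denom = Ri + Rj
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (Ri - Rj) / np.where(denom == 0, 1, denom),
                       np.nan)
    return out if out.ndim else float(out)


def enumerate_modified(bands: BandSet = DEFAULT_BANDSET) -> list[IndexSpec]:
    """All ordered band pairs except the NDVI 1-3 pairs, ids m1, m2, ...

    Enumeration is row-major over the band order; the reassigned pairs
    are skipped entirely so ids run consecutively.
    """
    skip = {p for p in NDVI_PAIRS if p[0] in bands and p[1] in bands}
    specs: list[IndexSpec] = []
    k = 0
    for bi in bands.names:
        for bj in bands.names:
            if bi == bj or (bi, bj) in skip:
                continue
            k += 1
            specs.append(IndexSpec(f"m{k}", "modified_ndvi", (bi, bj)))
    if tuple(bands.names) != ALL_BAND_NAMES:
        logger.info(
            "non-default band set: %d modified indices enumerated", len(specs)
        )
    return specs


def standard_catalog(bands: BandSet = DEFAULT_BANDSET) -> list[IndexSpec]:
    """The 15 standard indices: NDVI/SR/EVI/SAVI/GDVI x NIR 1-3."""
    specs: list[IndexSpec] = []
    for k, nir in enumerate(("nir1", "nir2", "nir3"), start=1):
        if nir not in bands:
            continue
        specs.append(IndexSpec(f"NDVI {k}", "ndvi", (nir, "red")))
        specs.append(IndexSpec(f"SR {k}", "sr", (nir, "red")))
        specs.append(
            IndexSpec(
                f"EVI {k}",
                "evi",
                (nir, "red", "blue"),
                {"G": EVI_G, "C1": EVI_C1, "C2": EVI_C2, "L": EVI_L},
            )
        )
        specs.append(
            IndexSpec(
                f"SAVI {k}",
                "savi",
                (nir, "red"),
                {"L": SAVI_L, "scale": SAVI_SCALE},
            )
        )
        specs.append(IndexSpec(f"GDVI {k}", "gdvi", (nir, "green")))
    return specs


def full_catalog(bands: BandSet = DEFAULT_BANDSET) -> list[IndexSpec]:
    """Modified family plus standard families (84 on the default set)."""
    return enumerate_modified(bands) + standard_catalog(bands)


def _evaluate_one(spec: IndexSpec, get) -> np.ndarray:
    if spec.family in ("modified_ndvi", "ndvi"):
        return modified_ndvi(get(spec.bands[0]), get(spec.bands[1]))
    if spec.family == "sr":
        nir, red = get(spec.bands[0]), get(spec.bands[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(red != 0, nir / np.where(red == 0, 1, red), np.nan)
    if spec.family == "evi":
        nir, red, blue = (get(b) for b in spec.bands)
        c = spec.constants
        denom = nir + c["C1"] * red - c["C2"] * blue + c["L"]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                denom != 0,
                c["G"] * (nir - red) / np.where(denom == 0, 1, denom),
                np.nan,
            )
    if spec.family == "savi":
        nir, red = get(spec.bands[0]), get(spec.bands[1])
        c = spec.constants
        denom = nir + red + c["L"]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                denom != 0,
                c["scale"] * (nir - red) / np.where(denom == 0, 1, denom),
                np.nan,
            )
    if spec.family == "gdvi":
        return get(spec.bands[0]) - get(spec.bands[1])
    raise ValueError(f"unknown index family {spec.family!r}")


@dataclass
class FeatureMatrix:
    """Plots x features with per-column provenance (the source spec)."""

    values: pd.DataFrame
    provenance: dict[str, IndexSpec]

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


def evaluate(table: SpectralTable, specs: list[IndexSpec]) -> FeatureMatrix:
    """Evaluate index specs against a band table, one column per spec.

    Band values are clipped at zero before evaluation so normalized
    differences stay within [-1, 1] even on enhanced (stretched) inputs
    whose range is no longer physical reflectance.  Undefined cells
    (zero denominators) propagate as NaN and are logged per plot.
    """
    missing = sorted(
        {b for s in specs for b in s.bands} - set(table.bands.columns)
    )
    if missing:
        raise ValueError(f"specs reference absent bands: {missing}")
    clipped = table.bands.clip(lower=0.0)

    def get(band: str) -> np.ndarray:
        return clipped[band].to_numpy()

    cols = {s.id: _evaluate_one(s, get) for s in specs}
    df = pd.DataFrame(cols, index=table.bands.index)
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        logger.warning("undefined index cells for plots %s", list(bad))
    return FeatureMatrix(df, {s.id: s for s in specs})


def band_features(table: SpectralTable) -> pd.DataFrame:
    """The raw band columns as a feature block (bands-only group)."""
    return table.bands.copy()
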