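"""Worldview-3-style band layout used throughout the package.

The eight VNIR sensor bands, in sensor order, plus the derived ``nir3``
band (mean of the two near-infrared bands) that the index catalog adds.
Wavelength centers are nominal band-center values in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Sensor bands in acquisition order: (name, center nm, (lo nm, hi nm)).
SENSOR_BANDS: tuple[tuple[str, float, tuple[float, float]], ...] = (
    ("coastal", 425.0, (400.0, 450.0)),
    ("blue", 480.0, (450.0, 510.0)),
    ("green", 545.0, (510.0, 580.0)),
    ("yellow", 605.0, (585.0, 625.0)),
    ("red", 660.0, (630.0, 690.0)),
    ("rededge", 725.0, (705.0, 745.0)),
    ("nir1", 833.0, (770.0, 895.0)),
    ("nir2", 950.0, (860.0, 1040.0)),
)

SENSOR_BAND_NAMES: tuple[str, ...] = tuple(b[0] for b in SENSOR_BANDS)
CENTER_NM: dict[str, float] = {b[0]: b[1] for b in SENSOR_BANDS}
CENTER_NM["nir3"] = (CENTER_NM["nir1"] + CENTER_NM["nir2"]) / 2.0

#: Band order used for index enumeration: the 8 sensor bands plus nir3.
ALL_BAND_NAMES: tuple[str, ...] = SENSOR_BAND_NAMES + ("nir3",)

N_SENSOR_BANDS = len(SENSOR_BAND_NAMES)


@dataclass(frozen=True)
class BandSet:
    """An ordered, named set of spectral bands.

    The default configuration carries the 8 sensor bands plus the derived
    ``nir3`` band; ``nir3`` may only be present when both of its parent
    near-infrared bands are.
    """

    names: tuple[str, ...] = ALL_BAND_NAMES

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("band names must be unique")
        if "nir3" in self.names and not (
            "nir1" in self.names and "nir2" in self.names
        ):
            raise ValueError("nir3 requires both nir1 and nir2")

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


DEFAULT_BANDSET = BandSet()
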