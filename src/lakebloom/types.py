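"""Shared domain types for the bloom-mapping pipeline.

Reflectance scenes, lake polygons and terrestrial covariate rasters are the
three inputs every downstream stage consumes.  All spatial objects live in a
single projected, meter-based CRS; geographic (degree) coordinates are
rejected on construction because buffer distances and pixel areas are
meaningless in degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry.base import BaseGeometry

from .grid import GridTransform

logger = logging.getLogger(__name__)

BAND_ROLES = ("red", "nir", "swir", "green")

#: Sentinel-2A band centers (nm) for B4 / B8a / B11 / B3.
S2A_WAVELENGTHS = {"red": 664.6, "nir": 864.8, "swir": 1613.7, "green": 559.8}
#: Sentinel-2B band centers (nm).
S2B_WAVELENGTHS = {"red": 664.9, "nir": 864.0, "swir": 1610.4, "green": 559.0}

COVARIATE_NAMES = (
    "erosion",
    "phosphorus",
    "nitrogen",
    "temperature",
    "elevation",
    "slope",
    "flow_accumulation",
)

COVARIATE_UNITS = {
    "erosion": "t ha-1 yr-1",
    "phosphorus": "mg kg-1",
    "nitrogen": "g kg-1",
    "temperature": "degC",
    "elevation": "m",
    "slope": "deg",
    "flow_accumulation": "cells",
}


class ConfigurationError(ValueError):
    """Invalid configuration (band map, wavelengths, thresholds, spectra)."""


class RegistrationError(ValueError):
    """Input grids are not co-registered (shape/transform mismatch)."""


class PlacementError(RuntimeError):
    """Synthetic lake placement failed within the retry budget."""


@dataclass(frozen=True)
class BandSpec:
    """One spectral band: its role in the index, position in the file, center wavelength (nm)."""

    role: str
    band_index: int
    center_wavelength: float

    def __post_init__(self) -> None:
        if self.role not in BAND_ROLES:
            raise ConfigurationError(f"unknown band role {self.role!r}")
        if self.band_index < 0:
            raise ConfigurationError("band_index must be >= 0")
        if self.center_wavelength <= 0:
            raise ConfigurationError("center_wavelength must be positive (nm)")


@dataclass
class Scene:
    """One co-registered multiband reflectance raster for one month.

    ``reflectance`` has shape (bands, rows, cols); ``nodata_mask`` is True
    where any band is missing at a pixel.
    """

    date_tag: str
    reflectance: np.ndarray
    transform: GridTransform
    nodata_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.reflectance.ndim != 3:
            raise ValueError("reflectance must be (bands, rows, cols)")
        if self.nodata_mask.shape != self.reflectance.shape[1:]:
            raise ValueError("nodata_mask shape mismatch")
        self.transform.pixel_size  # raises if non-square

    @property
    def shape(self) -> tuple[int, int]:
        return self.reflectance.shape[1:]

    @property
    def year(self) -> str:
        return self.date_tag[:4]


@dataclass
class SceneStack:
    """Dated sequence of co-registered scenes sharing one band layout."""

    scenes: list[Scene]
    bands: list[BandSpec]
    crs_id: str = "unknown"

    def __post_init__(self) -> None:
        if not self.scenes:
            raise ValueError("SceneStack needs at least one scene")
        roles = [b.role for b in self.bands]
        if len(set(roles)) != len(roles):
            raise ConfigurationError("duplicate band role in stack")
        wl = {b.role: b.center_wavelength for b in self.bands}
        if {"red", "nir", "swir"} <= set(wl):
            if not (wl["red"] < wl["nir"] < wl["swir"]):
                raise ConfigurationError(
                    "wavelengths must be strictly ordered red < nir < swir"
                )
        tags = [s.date_tag for s in self.scenes]
        if len(set(tags)) != len(tags):
            raise ValueError("duplicate scene date_tag")
        self.scenes.sort(key=lambda s: s.date_tag)
        ref = self.scenes[0]
        for s in self.scenes[1:]:
            if s.shape != ref.shape or not s.transform.almost_equals(ref.transform):
                raise RegistrationError(
                    f"scene {s.date_tag} is not co-registered with {ref.date_tag}"
                )

    @property
    def transform(self) -> GridTransform:
        return self.scenes[0].transform

    @property
    def shape(self) -> tuple[int, int]:
        return self.scenes[0].shape

    def band(self, role: str) -> BandSpec:
        for b in self.bands:
            if b.role == role:
                return b
        raise ConfigurationError(f"stack has no {role!r} band")


@dataclass
class Lake:
    lake_id: str
    geometry: BaseGeometry
    surface_area_km2: float
    mean_depth_m: float | None = None

    def __post_init__(self) -> None:
        if self.geometry.is_empty or not self.geometry.is_valid:
            raise ValueError(f"lake {self.lake_id}: invalid or empty geometry")
        if self.surface_area_km2 <= 0:
            raise ValueError(f"lake {self.lake_id}: surface_area must be positive")


@dataclass
class LakeSet:
    lakes: list[Lake]
    region_tag: str = ""

    def __post_init__(self) -> None:
        ids = [lk.lake_id for lk in self.lakes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate lake_id(s): {dupes}")

    def __iter__(self):
        return iter(self.lakes)

    def __len__(self) -> int:
        return len(self.lakes)

    def get(self, lake_id: str) -> Lake:
        for lk in self.lakes:
            if lk.lake_id == lake_id:
                return lk
        raise KeyError(lake_id)


@dataclass
class CovariateRaster:
    """Single-band terrestrial covariate grid.

    Erosion is aggregated by summation inside buffer zones (a relative proxy
    for sediment delivery); every other covariate by its mean.
    """

    name: str
    values: np.ndarray
    transform: GridTransform
    units: str = ""
    aggregation: str = ""

    def __post_init__(self) -> None:
        if self.name not in COVARIATE_NAMES:
            raise ConfigurationError(f"unknown covariate {self.name!r}")
        if not self.aggregation:
            self.aggregation = "sum" if self.name == "erosion" else "mean"
        if (self.aggregation == "sum") != (self.name == "erosion"):
            raise ConfigurationError(
                "aggregation must be 'sum' for erosion and 'mean' otherwise"
            )
        if not self.units:
            self.units = COVARIATE_UNITS.get(self.name, "")
        if self.values.ndim != 2:
            raise ValueError("covariate grid must be 2-D")


@dataclass
class CategoricalRaster:
    """Integer-coded land-use/land-cover grid; negative codes mean nodata."""

    values: np.ndarray
    transform: GridTransform
    class_names: dict[int, str] = field(default_factory=dict)


def looks_geographic(geometry: BaseGeometry) -> bool:
    """Heuristic: bounds that fit in lon/lat ranges are treated as degrees."""
    minx, miny, maxx, maxy = geometry.bounds
    return -180.0 <= minx <= maxx <= 180.0 and -90.0 <= miny <= maxy <= 90.0
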