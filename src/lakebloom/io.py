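"""Readers and writers for the pipeline's file formats.

Rasters are GeoTIFF-tagged TIFFs handled through :mod:`tifffile`: the
georeference travels in the standard ``ModelPixelScale`` / ``ModelTiepoint``
tags, nodata in ``GDAL_NODATA``, and free-form metadata (date tag, band
roles, wavelengths, CRS id) as JSON in the image description.  Vectors are
GeoJSON handled through :mod:`shapely`; tables are CSV.

Inputs must already be in a projected, meter-based CRS — coordinates that
look like degrees are rejected rather than silently misinterpreted.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape
from shapely.validation import make_valid

from .grid import GridTransform, regrid_nearest
from .types import (
    BandSpec,
    ConfigurationError,
    CovariateRaster,
    Lake,
    LakeSet,
    RegistrationError,
    Scene,
    SceneStack,
    looks_geographic,
)

logger = logging.getLogger(__name__)

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


# ---------------------------------------------------------------------------
# raster I/O


def write_geotiff(
    path: str | Path,
    values: np.ndarray,
    transform: GridTransform,
    metadata: dict | None = None,
) -> Path:
    """Write a single- or multi-band float raster with geo tags; NaN is nodata."""
    path = Path(path)
    arr = np.asarray(values, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (abs(transform.a), abs(transform.e), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.c, transform.f, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, "nan"),
    ]
    tifffile.imwrite(
        path,
        arr,
        photometric="minisblack",
        description=json.dumps(metadata or {}, sort_keys=True),
        extratags=extratags,
    )
    return path


def read_geotiff(path: str | Path) -> tuple[np.ndarray, GridTransform, dict]:
    """Read a raster written by :func:`write_geotiff` (or any axis-aligned GeoTIFF)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray().astype(np.float64)
        page = tif.pages[0]
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ConfigurationError(f"{path}: missing GeoTIFF georeference tags")
        sx, sy, _ = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        ox, oy = tie[3], tie[4]
        meta: dict = {}
        desc = tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                if not isinstance(meta, dict):
                    meta = {}
            except (TypeError, json.JSONDecodeError):
                meta = {}
    transform = GridTransform(sx, 0.0, ox, 0.0, -sy, oy)
    if arr.ndim == 2:
        arr = arr[None]
    return arr, transform, meta


def write_scene(path: str | Path, scene: Scene, bands: list[BandSpec], crs_id: str = "unknown") -> Path:
    vals = scene.reflectance.astype(np.float32).copy()
    vals[:, scene.nodata_mask] = np.nan
    meta = {
        "date_tag": scene.date_tag,
        "crs_id": crs_id,
        "bands": [
            {"role": b.role, "band_index": b.band_index, "center_wavelength": b.center_wavelength}
            for b in bands
        ],
    }
    return write_geotiff(path, vals, scene.transform, meta)


def read_scene_stack(
    paths: list,
    band_map: dict[str, int] | None = None,
    wavelengths: dict[str, float] | None = None,
    crs_id: str = "unknown",
) -> SceneStack:
    """Assemble a validated scene stack from monthly raster files.

    Each entry in ``paths`` is either one multiband file, or (for sensors
    that deliver bands at different native resolutions) a mapping
    ``role -> single-band file``; in the latter case bands whose pixel size
    differs from the reference grid are nearest-neighbour resampled onto it.
    ``band_map``/``wavelengths`` may be omitted when the files carry their
    band layout in embedded metadata.  Scenes are sorted by date tag, so the
    input listing order does not matter.
    """
    if not paths:
        raise ValueError("no scene paths given")
    scenes: list[Scene] = []
    bands: list[BandSpec] | None = None
    ref_transform: GridTransform | None = None
    ref_shape: tuple[int, int] | None = None

    for entry in paths:
        if isinstance(entry, dict):
            scene, file_bands = _read_scene_per_band(entry, wavelengths, ref_transform, ref_shape)
        else:
            scene, file_bands = _read_scene_multiband(Path(entry), band_map, wavelengths)
        if ref_transform is None:
            ref_transform, ref_shape = scene.transform, scene.shape
            bands = file_bands
        else:
            if scene.shape != ref_shape or not scene.transform.almost_equals(ref_transform):
                raise RegistrationError(
                    f"scene {scene.date_tag}: grid does not match the first scene "
                    "(all monthly files must share shape, pixel size and origin)"
                )
        scenes.append(scene)
    assert bands is not None
    return SceneStack(scenes=scenes, bands=bands, crs_id=crs_id)


def _bands_from_meta(meta: dict) -> list[BandSpec] | None:
    if "bands" not in meta:
        return None
    return [
        BandSpec(b["role"], int(b["band_index"]), float(b["center_wavelength"]))
        for b in meta["bands"]
    ]


def _read_scene_multiband(
    path: Path, band_map: dict[str, int] | None, wavelengths: dict[str, float] | None
) -> tuple[Scene, list[BandSpec]]:
    arr, transform, meta = read_geotiff(path)
    bands = _bands_from_meta(meta)
    if bands is None:
        if band_map is None or wavelengths is None:
            raise ConfigurationError(
                f"{path}: no embedded band metadata; band_map and wavelengths are required"
            )
        missing = {"red", "nir", "swir"} - set(band_map)
        if missing:
            raise ConfigurationError(f"band_map missing role(s): {sorted(missing)}")
        bands = [BandSpec(role, idx, wavelengths[role]) for role, idx in sorted(band_map.items())]
    for b in bands:
        if b.band_index >= arr.shape[0]:
            raise ConfigurationError(
                f"{path}: band_index {b.band_index} out of range for {arr.shape[0]}-band file"
            )
    date_tag = str(meta.get("date_tag", path.stem))
    nodata = ~np.all(np.isfinite(arr), axis=0)
    return Scene(date_tag, arr, transform, nodata), bands


def _read_scene_per_band(
    entry: dict,
    wavelengths: dict[str, float] | None,
    ref_transform: GridTransform | None,
    ref_shape: tuple[int, int] | None,
) -> tuple[Scene, list[BandSpec]]:
    roles = sorted(entry)
    if not {"red", "nir", "swir"} <= set(roles):
        raise ConfigurationError(f"per-band scene missing role(s): need red/nir/swir, got {roles}")
    grids, transform, shape_, date_tag = {}, ref_transform, ref_shape, None
    raw = {}
    for role in roles:
        arr, tr, meta = read_geotiff(entry[role])
        raw[role] = (arr[0], tr)
        date_tag = date_tag or meta.get("date_tag")
        if transform is None or (tr.pixel_size < transform.pixel_size):
            transform, shape_ = tr, arr[0].shape
    assert transform is not None and shape_ is not None
    for role, (band, tr) in raw.items():
        if band.shape == shape_ and tr.almost_equals(transform):
            grids[role] = band
        else:
            logger.info("resampling %s band (%.0f m) onto %.0f m grid", role, tr.pixel_size, transform.pixel_size)
            grids[role] = regrid_nearest(band, tr, transform, shape_)
    if wavelengths is None:
        raise ConfigurationError("per-band scenes require explicit wavelengths")
    bands = [BandSpec(role, i, wavelengths[role]) for i, role in enumerate(roles)]
    stack = np.stack([grids[r] for r in roles])
    nodata = ~np.all(np.isfinite(stack), axis=0)
    tag = str(date_tag) if date_tag else Path(entry[roles[0]]).stem
    return Scene(tag, stack, transform, nodata), bands


def write_covariate(path: str | Path, raster: CovariateRaster, crs_id: str = "unknown") -> Path:
    meta = {"covariate": raster.name, "units": raster.units, "aggregation": raster.aggregation, "crs_id": crs_id}
    return write_geotiff(path, raster.values, raster.transform, meta)


def read_covariate(path: str | Path, name: str | None = None) -> CovariateRaster:
    arr, transform, meta = read_geotiff(path)
    name = name or meta.get("covariate")
    if name is None:
        raise ConfigurationError(f"{path}: covariate name not given and not embedded")
    return CovariateRaster(name=name, values=arr[0], transform=transform, units=meta.get("units", ""))


# ---------------------------------------------------------------------------
# vector I/O


def read_lakes(
    path: str | Path,
    id_field: str = "lake_id",
    depth_field: str = "mean_depth_m",
    area_field: str | None = "surface_area_km2",
    region_tag: str = "",
) -> LakeSet:
    """Read lake polygons from GeoJSON.

    Invalid geometries are repaired with ``make_valid`` when the result is
    still polygonal, otherwise dropped with a log entry.  Areas are
    recomputed from geometry (m^2 -> km^2) when ``area_field`` is absent.
    """
    path = Path(path)
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    lakes: list[Lake] = []
    for feat in feats:
        props = feat.get("properties") or {}
        lake_id = str(props.get(id_field, ""))
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            logger.warning("lake %s: non-polygon geometry %s rejected", lake_id, geom.geom_type)
            continue
        if not geom.is_valid:
            geom = make_valid(geom)
            if geom.geom_type not in ("Polygon", "MultiPolygon") or geom.is_empty:
                logger.warning("lake %s: unrepairable geometry dropped", lake_id)
                continue
            logger.info("lake %s: geometry repaired", lake_id)
        if looks_geographic(geom):
            raise ConfigurationError(
                f"lake {lake_id}: coordinates look geographic (degrees); "
                "reproject inputs to a meter-based CRS first"
            )
        area = props.get(area_field) if area_field else None
        if area is None:
            area = geom.area / 1e6
        depth = props.get(depth_field)
        lakes.append(
            Lake(
                lake_id=lake_id,
                geometry=geom,
                surface_area_km2=float(area),
                mean_depth_m=None if depth is None else float(depth),
            )
        )
    return LakeSet(lakes=lakes, region_tag=region_tag or str(gj.get("name", "")))


def write_lakes(lakeset: LakeSet, path: str | Path) -> Path:
    path = Path(path)
    feats = []
    for lk in lakeset:
        props = {"lake_id": lk.lake_id, "surface_area_km2": lk.surface_area_km2}
        if lk.mean_depth_m is not None:
            props["mean_depth_m"] = lk.mean_depth_m
        feats.append({"type": "Feature", "properties": props, "geometry": mapping(lk.geometry)})
    gj = {"type": "FeatureCollection", "name": lakeset.region_tag, "features": feats}
    with open(path, "w") as fh:
        json.dump(gj, fh)
    return path


# ---------------------------------------------------------------------------
# tables


def write_table(rows, path: str | Path) -> Path:
    """Write rows (DataFrame or list of dicts) as deterministic CSV.

    Row order is preserved, column order follows the first row's schema,
    nulls become empty cells, floats use repr-shortest formatting.
    """
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        df = pd.DataFrame(rows, columns=list(rows[0].keys()) if rows else None)
    df.to_csv(path, index=False, na_rep="", lineterminator="\n")
    return path
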