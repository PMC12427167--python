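"""Bloom occurrence compositing and per-lake bloom summaries.

Per pixel, bloom occurrence (BO) is the percentage of scenes in which the
pixel was classified as bloom, out of the scenes with valid data at that
pixel.  Per lake, maximum bloom extent (MBE) is the area of lake pixels
that bloomed in at least one scene (pixels with BO = 0 are removed before
summing), and the mean BO is taken over those ever-bloomed pixels.

Lake pixels are selected by center containment: a pixel belongs to the
lake iff its center falls inside the polygon.  This is unbiased for area;
the all-touched alternative systematically inflates small lakes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely

from .fai import BloomMask
from .grid import GridTransform
from .types import Lake

logger = logging.getLogger(__name__)

__all__ = [
    "BoRaster",
    "LakeBloomSummary",
    "bloom_occurrence",
    "lake_mask",
    "max_bloom_extent",
    "classify_lake",
    "summarize_lakes",
]

SIZE_SMALL_MAX_KM2 = 1.0    # small < 1 km2 <= medium <= 100 km2 < large
SIZE_MEDIUM_MAX_KM2 = 100.0
DEPTH_SHALLOW_MAX_M = 3.0   # shallow < 3 m <= deep


@dataclass
class BoRaster:
    """Bloom-occurrence percentage grid with the per-pixel scene count."""

    values: np.ndarray       # % in [0, 100]; NaN where no scene had valid data
    n_scenes_used: np.ndarray
    transform: GridTransform


@dataclass
class LakeBloomSummary:
    lake_id: str
    mbe_km2: float
    mean_bo_pct: float
    n_bloom_pixels: int
    size_class: str
    depth_class: str
    year_tag: str = "all"
    n_scenes: int = 0


def bloom_occurrence(masks: list[BloomMask]) -> BoRaster:
    """Composite per-scene bloom masks into a BO percentage grid.

    The denominator is the number of scenes with valid data at each pixel,
    which reduces to the total scene count when nothing is missing.
    """
    if not masks:
        raise ValueError("bloom_occurrence needs at least one mask")
    shape = masks[0].values.shape
    for m in masks:
        if m.values.shape != shape:
            raise ValueError("masks are not co-registered")
    n_bloom = np.zeros(shape, dtype=np.int64)
    n_valid = np.zeros(shape, dtype=np.int64)
    for m in masks:
        n_valid += m.valid
        n_bloom += m.values & m.valid
    with np.errstate(invalid="ignore", divide="ignore"):
        bo = 100.0 * n_bloom / n_valid
    bo[n_valid == 0] = np.nan
    return BoRaster(values=bo, n_scenes_used=n_valid, transform=None)  # type: ignore[arg-type]


def lake_mask(lake: Lake, transform: GridTransform, shape: tuple[int, int]) -> np.ndarray:
    """Boolean grid of pixels whose centers fall inside the lake polygon."""
    rows, cols = shape
    minx, miny, maxx, maxy = lake.geometry.bounds
    # window of candidate pixels, clipped to the grid
    r0, c0 = transform.rowcol(minx, maxy)
    r1, c1 = transform.rowcol(maxx, miny)
    r_lo = max(int(np.floor(min(r0, r1))) - 1, 0)
    r_hi = min(int(np.ceil(max(r0, r1))) + 1, rows)
    c_lo = max(int(np.floor(min(c0, c1))) - 1, 0)
    c_hi = min(int(np.ceil(max(c0, c1))) + 1, cols)
    out = np.zeros(shape, dtype=bool)
    if r_lo >= r_hi or c_lo >= c_hi:
        logger.warning("lake %s does not overlap the grid", lake.lake_id)
        return out
    xs = transform.c + transform.a * (np.arange(c_lo, c_hi) + 0.5)
    ys = transform.f + transform.e * (np.arange(r_lo, r_hi) + 0.5)
    xg, yg = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(lake.geometry, xg.ravel(), yg.ravel()).reshape(xg.shape)
    if not inside.any():
        logger.warning("lake %s covers no pixel centers", lake.lake_id)
    out[r_lo:r_hi, c_lo:c_hi] = inside
    return out


def classify_lake(lake: Lake) -> tuple[str, str]:
    """Size class by surface area (km^2) and depth class by mean depth (m)."""
    a = lake.surface_area_km2
    if a < SIZE_SMALL_MAX_KM2:
        size = "small"
    elif a <= SIZE_MEDIUM_MAX_KM2:
        size = "medium"
    else:
        size = "large"
    if lake.mean_depth_m is None:
        depth = "unknown"
    elif lake.mean_depth_m < DEPTH_SHALLOW_MAX_M:
        depth = "shallow"
    else:
        depth = "deep"
    return size, depth


def max_bloom_extent(
    bo: BoRaster,
    lake: Lake,
    transform: GridTransform,
    year_tag: str = "all",
    n_scenes: int = 0,
) -> LakeBloomSummary:
    """Per-lake MBE (km^2) and mean BO over ever-bloomed pixels."""
    lm = lake_mask(lake, transform, bo.values.shape)
    vals = bo.values[lm]
    vals = vals[np.isfinite(vals)]
    bloomed = vals[vals > 0]
    n_bloom = int(bloomed.size)
    mbe_km2 = n_bloom * transform.pixel_area / 1e6
    mean_bo = float(bloomed.mean()) if n_bloom else 0.0
    size_class, depth_class = classify_lake(lake)
    return LakeBloomSummary(
        lake_id=lake.lake_id,
        mbe_km2=mbe_km2,
        mean_bo_pct=mean_bo,
        n_bloom_pixels=n_bloom,
        size_class=size_class,
        depth_class=depth_class,
        year_tag=year_tag,
        n_scenes=n_scenes,
    )


def summarize_lakes(
    masks: list[BloomMask],
    lakes,
    transform: GridTransform,
    per_year: bool = True,
) -> list[LakeBloomSummary]:
    """BO/MBE summaries for every lake, pooled and (optionally) per year.

    Scene year is the leading ``YYYY`` of the mask date tag.  The pooled
    rows carry ``year_tag='all'``.
    """
    groups: dict[str, list[BloomMask]] = {"all": list(masks)}
    if per_year:
        years = sorted({m.date_tag[:4] for m in masks})
        if len(years) > 1:
            for y in years:
                groups[y] = [m for m in masks if m.date_tag[:4] == y]
    out: list[LakeBloomSummary] = []
    for year_tag in sorted(groups):
        grp = groups[year_tag]
        bo = bloom_occurrence(grp)
        bo.transform = transform
        for lake in lakes:
            out.append(max_bloom_extent(bo, lake, transform, year_tag=year_tag, n_scenes=len(grp)))
    return out
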