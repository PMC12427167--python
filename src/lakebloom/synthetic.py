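"""Synthetic region generator: scenes, lakes and covariates with known truth.

Every input the pipeline consumes can be generated at desk scale with a
known ground truth: monthly multiband reflectance stacks in which bloom
pixels raise NIR above the red-SWIR baseline, non-overlapping lake
polygons spanning the small and medium size classes and both depth
classes, and smooth covariate random fields with a planted statistical
link — by default, the buffer-summed soil erosion drives each lake's
maximum bloom extent.

The planted link operates at the lake level: a standardized response index

    z_i = sum_c w_c * standardize(buffer summary of c for lake i) + eps_i

(eps ~ Normal(0, response_noise_sd)) is mapped affinely onto a bloom
fraction, so the standardized true MBE reproduces z exactly (up to pixel
quantization).  The generator emits both the rasters and the realized
per-lake summaries it used, so tests can verify the construction
independently of the zonal-extraction code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, box

from .bloom import lake_mask
from .fai import DEFAULT_THRESHOLD
from .grid import GridTransform
from .types import (
    BandSpec,
    ConfigurationError,
    CovariateRaster,
    Lake,
    LakeSet,
    PlacementError,
    S2A_WAVELENGTHS,
    Scene,
    SceneStack,
    COVARIATE_NAMES,
)
from .zonal import BufferRing, build_buffers, summarize_covariates, summary_column

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "GroundTruth", "generate_lakes", "generate_scenes",
           "generate_covariates", "generate_region", "RegionBundle"]

#: reflectance spectra per class (role -> mean reflectance).  Water sits
#: below the FAI threshold, bloom well above it, and land carries a strong
#: vegetation-like signal so tests can confirm lake masking excludes it.
WATER_SPECTRUM = {"red": 0.02, "nir": 0.01, "swir": 0.005, "green": 0.03}
BLOOM_SPECTRUM = {"red": 0.03, "nir": 0.10, "swir": 0.01, "green": 0.06}
LAND_SPECTRUM = {"red": 0.04, "nir": 0.35, "swir": 0.18, "green": 0.08}

ROLE_ORDER = ("green", "red", "nir", "swir")

#: plausible marginal scales per covariate: (transform of a standard-normal
#: smooth field z).  Erosion is lognormal-ish and strictly positive.
_FIELD_SCALES = {
    "erosion": lambda z: np.exp(0.8 * z) * 2.0,          # t ha-1 yr-1
    "phosphorus": lambda z: 25.0 + 8.0 * z,              # mg kg-1
    "nitrogen": lambda z: 2.0 + 0.6 * z,                 # g kg-1
    "temperature": lambda z: 9.0 + 2.5 * z,              # degC
    "elevation": lambda z: 300.0 + 120.0 * z,            # m
    "slope": lambda z: np.abs(3.0 + 2.0 * z),            # deg
    "flow_accumulation": lambda z: np.exp(1.2 * z) * 50.0,  # cells
}


@dataclass
class SimConfig:
    seed: int = 0
    n_lakes: int = 6
    grid_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 20.0
    n_months: int = 8                       # March-October of one season
    start_year: int = 2021
    bloom_link: dict[str, float] = field(default_factory=lambda: {"erosion": 0.5})
    response_noise_sd: float = 0.1
    noise_sd: float = 0.005                 # reflectance noise
    water_spectrum: dict[str, float] = field(default_factory=lambda: dict(WATER_SPECTRUM))
    bloom_spectrum: dict[str, float] = field(default_factory=lambda: dict(BLOOM_SPECTRUM))
    land_spectrum: dict[str, float] = field(default_factory=lambda: dict(LAND_SPECTRUM))
    threshold_truth: float = DEFAULT_THRESHOLD
    #: per-month bloom size as a fraction of the maximum patch (low, high);
    #: (1.0, 1.0) makes every month show the full extent
    monthly_fill: tuple[float, float] = (0.3, 1.0)
    link_distance_m: float = 100.0
    buffer_distances: tuple[float, ...] = (100.0, 200.0, 500.0, 1000.0)
    field_smooth_px: float = 10.0
    medium_fraction: float = 0.34           # share of lakes drawn in the medium class
    region_tag: str = "synthetic"

    @property
    def transform(self) -> GridTransform:
        return GridTransform.from_origin(0.0, self.grid_shape[0] * self.pixel_size, self.pixel_size)

    def wavelengths(self) -> dict[str, float]:
        return dict(S2A_WAVELENGTHS)


@dataclass
class GroundTruth:
    """Exact truth emitted alongside the fixtures."""

    bloom_pixels: dict[str, list[np.ndarray]] = field(default_factory=dict)  # lake -> per-month (k,2) row/col
    max_bloom_pixels: dict[str, np.ndarray] = field(default_factory=dict)
    mbe_km2: dict[str, float] = field(default_factory=dict)
    bloom_fraction: dict[str, float] = field(default_factory=dict)
    lake_pixel_count: dict[str, int] = field(default_factory=dict)
    driver_weights: dict[str, float] = field(default_factory=dict)
    realized_summaries: dict[str, dict[str, float]] = field(default_factory=dict)  # lake -> column -> value
    response_index: dict[str, float] = field(default_factory=dict)
    fai_margin: tuple[float, float] | None = None  # (bloom FAI - thr, thr - water FAI), noiseless

    def bo_pct(self, lake_id: str) -> dict[tuple[int, int], float]:
        """True BO (%) per ever-bloomed pixel of one lake."""
        sets = self.bloom_pixels[lake_id]
        counts: dict[tuple[int, int], int] = {}
        for monthly in sets:
            for r, c in monthly:
                counts[(int(r), int(c))] = counts.get((int(r), int(c)), 0) + 1
        n = len(sets)
        return {k: 100.0 * v / n for k, v in counts.items()}


@dataclass
class RegionBundle:
    config: SimConfig
    lakes: LakeSet
    stack: SceneStack | None
    covariates: list[CovariateRaster]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# lakes


def generate_lakes(config: SimConfig, rng: np.random.Generator | None = None) -> LakeSet:
    """Place non-overlapping lake polygons (rectangles and ellipses).

    Areas span the small (< 1 km^2) and medium (1-100 km^2) classes and
    depths straddle the 3 m shallow/deep boundary.  Placement is rejection
    sampling with a bounded retry budget.
    """
    rng = rng or np.random.default_rng(config.seed)
    rows, cols = config.grid_shape
    px = config.pixel_size
    width_m, height_m = cols * px, rows * px
    lakes: list[Lake] = []
    geoms = []
    margin = 2 * px
    grid_km2 = width_m * height_m / 1e6
    # cap the medium-class draw so one lake always fits inside the grid
    medium_hi = min(3.0, 0.15 * grid_km2)
    max_tries = 200 * max(config.n_lakes, 1)
    tries = 0
    for i in range(config.n_lakes):
        medium = medium_hi > 1.0 and rng.random() < config.medium_fraction
        while True:
            tries += 1
            if tries > max_tries:
                raise PlacementError(
                    f"could not place {config.n_lakes} lakes on a {rows}x{cols} grid; "
                    "enlarge the grid or reduce n_lakes"
                )
            if medium:
                area_km2 = rng.uniform(1.0, medium_hi)
            else:
                area_km2 = rng.uniform(0.2, 0.9)
            area_m2 = area_km2 * 1e6
            aspect = rng.uniform(0.6, 1.6)
            rectangular = rng.random() < 0.5
            if rectangular:
                hx = math.sqrt(area_m2 * aspect) / 2
                hy = area_m2 / (4 * hx)
            else:
                hx = math.sqrt(area_m2 * aspect / math.pi)
                hy = area_m2 / (math.pi * hx)
            if margin + hx > width_m - margin - hx or margin + hy > height_m - margin - hy:
                continue  # shape cannot fit; counts toward the retry budget
            cx = rng.uniform(margin + hx, width_m - margin - hx)
            cy = rng.uniform(margin + hy, height_m - margin - hy)
            if rectangular:
                geom = box(cx - hx, cy - hy, cx + hx, cy + hy)
            else:
                geom = shapely_scale(Point(cx, cy).buffer(1.0, quad_segs=16), hx, hy)
            if w_fits(geom, width_m, height_m, margin) and not any(
                geom.distance(g) < 2 * px for g in geoms
            ):
                break
        depth = float(rng.uniform(0.5, 2.9) if rng.random() < 0.5 else rng.uniform(3.0, 15.0))
        lakes.append(
            Lake(
                lake_id=f"lake_{i:04d}",
                geometry=geom,
                surface_area_km2=geom.area / 1e6,
                mean_depth_m=depth,
            )
        )
        geoms.append(geom)
    return LakeSet(lakes=lakes, region_tag=config.region_tag)


def shapely_scale(geom, rx: float, ry: float):
    from shapely import affinity

    return affinity.scale(geom, xfact=rx, yfact=ry)


def w_fits(geom, width_m: float, height_m: float, margin: float) -> bool:
    minx, miny, maxx, maxy = geom.bounds
    return minx >= margin and miny >= margin and maxx <= width_m - margin and maxy <= height_m - margin


# ---------------------------------------------------------------------------
# covariates with the planted driver link


def _smooth_field(shape, sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal(shape)
    z = gaussian_filter(z, sigma=sigma_px, mode="reflect")
    sd = z.std()
    return z / sd if sd > 0 else z


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_covariates(
    config: SimConfig,
    lakes: LakeSet,
    rng: np.random.Generator | None = None,
) -> tuple[list[CovariateRaster], GroundTruth]:
    """Covariate random fields plus the planted lake-level response.

    The response index combines the standardized buffer summaries (at
    ``link_distance_m``) with the configured weights plus Gaussian noise,
    and is mapped affinely onto per-lake bloom fractions so that the
    standardized true MBE equals the standardized index.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    if not any(config.bloom_link.values()) and config.response_noise_sd == 0:
        raise ConfigurationError("all-zero driver weights with zero noise: degenerate response")
    unknown = set(config.bloom_link) - set(COVARIATE_NAMES)
    if unknown:
        raise ConfigurationError(f"bloom_link names unknown covariate(s): {sorted(unknown)}")

    transform = config.transform
    rasters = [
        CovariateRaster(
            name=name,
            values=_FIELD_SCALES[name](_smooth_field(config.grid_shape, config.field_smooth_px, rng)),
            transform=transform,
        )
        for name in COVARIATE_NAMES
    ]

    truth = GroundTruth(driver_weights=dict(config.bloom_link))
    lake_ids = [lk.lake_id for lk in lakes]
    rings = [
        r for r in build_buffers(lakes, [config.link_distance_m])
    ]
    summaries: dict[str, dict[str, float]] = {lid: {} for lid in lake_ids}
    for ring in rings:
        for rast in rasters:
            summaries[ring.lake_id][summary_column(rast.name)] = summarize_covariates(ring, rast)
    truth.realized_summaries = summaries

    n = len(lake_ids)
    index = np.zeros(n)
    for name, weight in config.bloom_link.items():
        if weight == 0:
            continue
        col = summary_column(name)
        vals = np.array([summaries[lid][col] for lid in lake_ids])
        index += weight * _standardize(vals)
    index += rng.normal(0.0, config.response_noise_sd, size=n)
    truth.response_index = dict(zip(lake_ids, index.tolist()))

    # affine map index -> bloom fraction, scaled by the smallest lake so the
    # fraction stays inside (0, 1) for every lake without (rarely) clipping
    pixel_area_km2 = transform.pixel_area / 1e6
    counts = {}
    for lk in lakes:
        lm = lake_mask(lk, transform, config.grid_shape)
        counts[lk.lake_id] = int(lm.sum())
    truth.lake_pixel_count = counts
    areas_px_km2 = {lid: counts[lid] * pixel_area_km2 for lid in lake_ids}
    a_min = min(areas_px_km2.values()) if lake_ids else 0.0
    z = _standardize(index) if n > 1 else index
    for lid, zi in zip(lake_ids, z):
        target = 0.5 * a_min + 0.12 * a_min * zi
        target = float(np.clip(target, pixel_area_km2, 0.98 * areas_px_km2[lid]))
        n_px = max(1, round(target / pixel_area_km2))
        truth.mbe_km2[lid] = n_px * pixel_area_km2
        truth.bloom_fraction[lid] = n_px / counts[lid]
    return rasters, truth


# ---------------------------------------------------------------------------
# scenes


def _spectrum_fai(spec: dict[str, float], wavelengths: dict[str, float]) -> float:
    frac = (wavelengths["nir"] - wavelengths["red"]) / (wavelengths["swir"] - wavelengths["red"])
    return spec["nir"] - (spec["red"] + (spec["swir"] - spec["red"]) * frac)


def _contiguous_patch(lake_pixels: np.ndarray, n_target: int, rng: np.random.Generator) -> np.ndarray:
    """Grow a 4-connected patch of ``n_target`` pixels inside the lake."""
    pix = {(int(r), int(c)) for r, c in lake_pixels}
    start = tuple(lake_pixels[rng.integers(len(lake_pixels))])
    start = (int(start[0]), int(start[1]))
    order = [start]
    chosen = {start}
    frontier = [start]
    while len(order) < n_target:
        new_frontier = []
        for r, c in frontier:
            for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if nb in pix and nb not in chosen:
                    chosen.add(nb)
                    order.append(nb)
                    new_frontier.append(nb)
                    if len(order) >= n_target:
                        break
            if len(order) >= n_target:
                break
        if not new_frontier:
            # disconnected remainder: jump to an unused pixel
            rest = list(pix - chosen)
            if not rest:
                break
            nxt = rest[rng.integers(len(rest))]
            chosen.add(nxt)
            order.append(nxt)
            new_frontier = [nxt]
        frontier = new_frontier
    return np.array(order[:n_target], dtype=int)


def generate_scenes(
    config: SimConfig,
    lakes: LakeSet,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[SceneStack, GroundTruth]:
    """Monthly reflectance stacks realizing the planted bloom fractions.

    Each lake gets one contiguous maximum-bloom patch; monthly bloom sets
    are nested prefixes of it (one month shows the full patch, so the
    ever-bloomed extent equals the planted MBE exactly).  Reflectance is
    the class spectrum plus clipped Gaussian noise.  The noiseless FAI
    separation of the spectra across the threshold is verified before any
    scene is emitted.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    wl = config.wavelengths()
    fai_bloom = _spectrum_fai(config.bloom_spectrum, wl)
    fai_water = _spectrum_fai(config.water_spectrum, wl)
    margin = (fai_bloom - config.threshold_truth, config.threshold_truth - fai_water)
    if margin[0] <= 0 or margin[1] <= 0:
        raise ConfigurationError(
            f"spectra do not separate across threshold {config.threshold_truth}: "
            f"bloom FAI {fai_bloom:.4f}, water FAI {fai_water:.4f}"
        )
    truth.fai_margin = margin

    transform = config.transform
    shape = config.grid_shape
    water_lookup = np.zeros(shape, dtype=bool)
    lake_pixels: dict[str, np.ndarray] = {}
    for lk in lakes:
        lm = lake_mask(lk, transform, shape)
        water_lookup |= lm
        lake_pixels[lk.lake_id] = np.argwhere(lm)
        truth.lake_pixel_count.setdefault(lk.lake_id, int(lm.sum()))

    # maximum-bloom patch per lake
    for lk in lakes:
        pix = lake_pixels[lk.lake_id]
        if len(pix) == 0:
            truth.max_bloom_pixels[lk.lake_id] = np.empty((0, 2), dtype=int)
            truth.mbe_km2.setdefault(lk.lake_id, 0.0)
            truth.bloom_fraction.setdefault(lk.lake_id, 0.0)
            continue
        frac = truth.bloom_fraction.get(lk.lake_id)
        if frac is None:
            frac = float(rng.uniform(0.2, 0.9))
            truth.bloom_fraction[lk.lake_id] = frac
        n_target = max(1, round(frac * len(pix)))
        patch = _contiguous_patch(pix, n_target, rng)
        truth.max_bloom_pixels[lk.lake_id] = patch
        truth.mbe_km2[lk.lake_id] = len(patch) * transform.pixel_area / 1e6

    # nested monthly prefixes; one month (chosen at random) is the full patch
    months = []
    for m in range(config.n_months):
        year = config.start_year + (m // 8 if config.n_months > 8 else 0)
        month = 3 + (m % 8)
        months.append(f"{year}-{month:02d}")
    full_month = {lk.lake_id: int(rng.integers(config.n_months)) for lk in lakes}
    monthly_sets: dict[str, list[np.ndarray]] = {lk.lake_id: [] for lk in lakes}
    for lk in lakes:
        patch = truth.max_bloom_pixels[lk.lake_id]
        for m in range(config.n_months):
            if len(patch) == 0:
                monthly_sets[lk.lake_id].append(np.empty((0, 2), dtype=int))
                continue
            if m == full_month[lk.lake_id]:
                k = len(patch)
            else:
                k = max(1, round(float(rng.uniform(*config.monthly_fill)) * len(patch)))
            monthly_sets[lk.lake_id].append(patch[:k])
    truth.bloom_pixels = monthly_sets

    bands = [BandSpec(role, i, wl[role]) for i, role in enumerate(ROLE_ORDER)]
    scenes = []
    for m, tag in enumerate(months):
        refl = np.empty((len(ROLE_ORDER), *shape))
        for bi, role in enumerate(ROLE_ORDER):
            layer = np.full(shape, config.land_spectrum[role])
            layer[water_lookup] = config.water_spectrum[role]
            refl[bi] = layer
        for lk in lakes:
            sel = monthly_sets[lk.lake_id][m]
            if len(sel):
                for bi, role in enumerate(ROLE_ORDER):
                    refl[bi][sel[:, 0], sel[:, 1]] = config.bloom_spectrum[role]
        if config.noise_sd > 0:
            refl += rng.normal(0.0, config.noise_sd, size=refl.shape)
            np.clip(refl, -0.1, 1.5, out=refl)
        scenes.append(Scene(tag, refl, transform, np.zeros(shape, dtype=bool)))
    stack = SceneStack(scenes=scenes, bands=bands, crs_id="synthetic-metric")
    return stack, truth


def planted_driver_rows(
    seed: int,
    n_lakes: int = 300,
    grid_shape: tuple[int, int] = (1400, 1400),
    bloom_link: dict[str, float] | None = None,
    response_noise_sd: float = 0.1,
):
    """Covariate table for one replicate of the planted-driver study.

    Defaults reproduce the recovery benchmark: 300 lakes, the buffer-summed
    erosion driving standardized MBE with weight 0.5 against Normal(0, 0.1)
    noise, six independent nuisance covariates.  Returns one row per lake
    with the seven summaries (at the link distance) and the true MBE; no
    reflectance scenes are rendered — the link is planted at lake level.
    """
    import pandas as pd

    cfg = SimConfig(
        seed=seed,
        n_lakes=n_lakes,
        grid_shape=grid_shape,
        bloom_link=bloom_link if bloom_link is not None else {"erosion": 0.5},
        response_noise_sd=response_noise_sd,
        medium_fraction=0.15,
        field_smooth_px=8.0,
    )
    rng = np.random.default_rng(cfg.seed)
    lakes = generate_lakes(cfg, rng)
    _, truth = generate_covariates(cfg, lakes, rng)
    rows = pd.DataFrame(
        [
            {"lake_id": lk.lake_id, **truth.realized_summaries[lk.lake_id],
             "mbe_km2": truth.mbe_km2[lk.lake_id]}
            for lk in lakes
        ]
    )
    return rows


def generate_region(config: SimConfig, with_scenes: bool = True) -> RegionBundle:
    """Lakes + covariates (+ scenes) for one synthetic region, one seed."""
    rng = np.random.default_rng(config.seed)
    lakes = generate_lakes(config, rng)
    covariates, truth = generate_covariates(config, lakes, rng)
    stack = None
    if with_scenes:
        stack, truth = generate_scenes(config, lakes, truth, rng)
    return RegionBundle(config=config, lakes=lakes, stack=stack, covariates=covariates, truth=truth)
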