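"""Floating Algae Index (FAI) and threshold-based bloom masking.

FAI measures how far the near-infrared reflectance of a pixel rises above a
linear baseline interpolated between the red and shortwave-infrared bands
(Hu's baseline-subtraction index):

    FAI = R_nir - [ R_red + (R_swir - R_red) * (l_nir - l_red) / (l_swir - l_red) ]

where ``l`` are the band center wavelengths in nm.  Open water sits on or
below its own baseline (FAI near or below zero); floating algae and
vegetation push NIR up and FAI positive.  A fixed threshold — 0.02 by
common convention, 0.05 as a conservative alternative — converts the index
into a binary bloom mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid import GridTransform
from .types import BandSpec, ConfigurationError, Scene

__all__ = ["FaiRaster", "BloomMask", "compute_fai", "apply_threshold", "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 0.02


@dataclass
class FaiRaster:
    """Per-pixel FAI grid (unitless); NaN marks missing cells."""

    values: np.ndarray
    date_tag: str
    transform: GridTransform


@dataclass
class BloomMask:
    """Binary bloom classification of one scene.

    ``values`` is True where the pixel is bloom; ``valid`` is False where
    FAI was missing (those pixels carry no information either way).
    """

    values: np.ndarray
    valid: np.ndarray
    threshold_used: float
    date_tag: str


def compute_fai(scene: Scene, bands: list[BandSpec]) -> FaiRaster:
    """Compute FAI for one scene in double precision.

    Pixels missing in any contributing band are NaN in the result.  The
    whole grid is computed — restriction to lake surfaces happens in the
    compositing stage, so the index raster stays reusable.
    """
    by_role = {b.role: b for b in bands}
    for role in ("red", "nir", "swir"):
        if role not in by_role:
            raise ConfigurationError(f"compute_fai requires a {role!r} band")
    l_red = by_role["red"].center_wavelength
    l_nir = by_role["nir"].center_wavelength
    l_swir = by_role["swir"].center_wavelength
    if math.isclose(l_swir, l_red):
        raise ConfigurationError("degenerate wavelengths: l_swir == l_red")

    refl = scene.reflectance.astype(np.float64)
    r_red = refl[by_role["red"].band_index]
    r_nir = refl[by_role["nir"].band_index]
    r_swir = refl[by_role["swir"].band_index]

    frac = (l_nir - l_red) / (l_swir - l_red)
    fai = r_nir - (r_red + (r_swir - r_red) * frac)
    fai = np.where(scene.nodata_mask, np.nan, fai)
    return FaiRaster(values=fai, date_tag=scene.date_tag, transform=scene.transform)


def apply_threshold(fai: FaiRaster, threshold: float = DEFAULT_THRESHOLD, inclusive: bool = True) -> BloomMask:
    """Classify bloom pixels as FAI >= threshold (inclusive by default).

    The inclusive convention keeps a pixel sitting exactly at the printed
    threshold detectable; set ``inclusive=False`` for strict comparison.
    """
    if not np.isfinite(threshold):
        raise ConfigurationError("threshold must be finite")
    valid = np.isfinite(fai.values)
    with np.errstate(invalid="ignore"):
        bloom = fai.values >= threshold if inclusive else fai.values > threshold
    bloom = bloom & valid
    return BloomMask(values=bloom, valid=valid, threshold_used=threshold, date_tag=fai.date_tag)
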