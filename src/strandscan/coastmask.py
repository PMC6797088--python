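"""Water masking, coastline extraction and metric coastal buffering.

The land-water split uses the Normalized Difference Water Index,
NDWI = (green - NIR) / (green + NIR), thresholded at a configurable
level (default 0). The coastline is the set of land pixels 4-adjacent
to water; the coastal buffer is every pixel whose center lies within a
metric distance of a coastline pixel center, optionally restricted to
the landward or seaward side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import MultispectralRaster


@dataclass
class WaterMask:
    mask: np.ndarray  # True = water
    ndwi_threshold: float


@dataclass
class CoastalBufferMask:
    mask: np.ndarray
    buffer_distance_m: float
    side: str  # both | landward | seaward


def compute_ndwi(ms: MultispectralRaster, green_band: int = 3, nir_band: int = 7) -> np.ndarray:
    """NDWI grid in [-1, 1]; 0/0 pixels and nodata become NaN.

    ``green_band``/``nir_band`` are 1-based sensor band numbers
    (defaults: the green and NIR1 bands).
    """
    if green_band == nir_band:
        raise ValueError("green and NIR bands must differ")
    g = ms.band(green_band).astype(np.float64)
    n = ms.band(nir_band).astype(np.float64)
    denom = g + n
    with np.errstate(divide="ignore", invalid="ignore"):
        ndwi = (g - n) / denom
    ndwi[denom == 0] = np.nan
    return ndwi


def extract_water_mask(ndwi: np.ndarray, threshold: float = 0.0) -> WaterMask:
    """Classify water as NDWI strictly above the threshold."""
    if not (-1.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (-1, 1)")
    if not np.isfinite(ndwi).any():
        raise ValueError("NDWI raster contains no valid pixels")
    mask = np.zeros(ndwi.shape, dtype=bool)
    finite = np.isfinite(ndwi)
    mask[finite] = ndwi[finite] > threshold
    return WaterMask(mask=mask, ndwi_threshold=threshold)


def coastline_pixels(water: np.ndarray) -> np.ndarray:
    """Boundary = land pixels with at least one water pixel 4-adjacent."""
    if water.all() or not water.any():
        return np.zeros(water.shape, dtype=bool)
    struct = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
    water_dilated = ndimage.binary_dilation(water, structure=struct)
    return water_dilated & ~water


def build_coastal_buffer(
    water_mask: WaterMask | np.ndarray,
    distance_m: float,
    pixel_size_m: float,
    side: str = "both",
) -> CoastalBufferMask:
    """Pixels within ``distance_m`` (center-to-center, Euclidean) of a
    coastline pixel, filtered to one side of the coast if requested.

    An all-water or all-land mask yields an empty buffer with a warning.
    """
    if distance_m < 0:
        raise ValueError("distance must be >= 0")
    if side not in ("both", "landward", "seaward"):
        raise ValueError("side must be 'both', 'landward' or 'seaward'")
    water = water_mask.mask if isinstance(water_mask, WaterMask) else np.asarray(water_mask, bool)

    boundary = coastline_pixels(water)
    if not boundary.any():
        warnings.warn("mask is all-water or all-land; coastal buffer is empty")
        return CoastalBufferMask(np.zeros(water.shape, bool), distance_m, side)

    # Distance (in pixels) from every pixel center to the nearest boundary
    # pixel center.
    dist_px = ndimage.distance_transform_edt(~boundary)
    buffer = dist_px * pixel_size_m <= distance_m + 1e-9
    if side == "landward":
        buffer &= ~water | boundary
    elif side == "seaward":
        buffer &= water | boundary
    return CoastalBufferMask(buffer, distance_m, side)


def coastline_geojson(water: np.ndarray, transform) -> dict:
    """Coastline pixel centers as a GeoJSON MultiPoint (simple export)."""
    boundary = coastline_pixels(water)
    rr, cc = np.nonzero(boundary)
    xs, ys = transform.pixel_center(rr, cc)
    return {
        "type": "Feature",
        "geometry": {
            "type": "MultiPoint",
            "coordinates": [[float(x), float(y)] for x, y in zip(xs, ys)],
        },
        "properties": {"role": "coastline_pixels"},
    }
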