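"""Georeferenced raster containers and GeoTIFF I/O.

Rasters live in a projected CRS with meter units, north-up, pixel-center
registration. Multiband arrays are stored ``(bands, rows, cols)`` float32;
nodata is NaN. GeoTIFF files carry the geotransform in the standard
ModelPixelScale / ModelTiepoint tags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine georeference: top-left corner + square pixel size."""

    origin_x: float
    origin_y: float
    pixel_size: float

    def pixel_center(self, row, col):
        """Easting/northing of pixel center(s); accepts scalars or arrays."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.origin_x + (col + 0.5) * self.pixel_size
        y = self.origin_y - (row + 0.5) * self.pixel_size
        return x, y

    def world_to_pixel(self, x, y):
        """Row/col indices of the pixel containing (x, y)."""
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.pixel_size)
        row = np.floor((self.origin_y - np.asarray(y, dtype=float)) / self.pixel_size)
        return row.astype(int), col.astype(int)

    def rescaled(self, pixel_size: float) -> "GeoTransform":
        return GeoTransform(self.origin_x, self.origin_y, pixel_size)


@dataclass(frozen=True)
class Band:
    index: int  # 1-based, as sensor band numbering
    name: str
    center_wavelength_nm: float


@dataclass(frozen=True)
class BandSet:
    """Ordered sensor bands plus the two native pixel sizes.

    The multispectral pixel size must be an integer multiple of the
    panchromatic pixel size (the sharpening ratio).
    """

    bands: tuple[Band, ...]
    ms_pixel_size: float = 2.0
    pan_pixel_size: float = 0.5

    def __post_init__(self):
        wl = [b.center_wavelength_nm for b in self.bands]
        if any(b >= a for b, a in zip(wl, wl[1:])):
            raise ValueError("band center wavelengths must be strictly increasing")
        ratio = self.ms_pixel_size / self.pan_pixel_size
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError("ms_pixel_size must be an integer multiple of pan_pixel_size")

    @property
    def ratio(self) -> int:
        return int(round(self.ms_pixel_size / self.pan_pixel_size))

    def __len__(self) -> int:
        return len(self.bands)

    def band_index(self, sensor_index: int) -> int:
        """0-based array index for a 1-based sensor band number."""
        for i, b in enumerate(self.bands):
            if b.index == sensor_index:
                return i
        raise KeyError(f"no band with sensor index {sensor_index}")


#: WorldView2-like layout: 8 bands, coastal blue through NIR2, with NIR1
#: centered near 850 nm; 2 m multispectral over 0.5 m panchromatic pixels.
WORLDVIEW2_BANDS = BandSet(
    bands=(
        Band(1, "coastal", 427.0),
        Band(2, "blue", 478.0),
        Band(3, "green", 546.0),
        Band(4, "yellow", 608.0),
        Band(5, "red", 659.0),
        Band(6, "red_edge", 724.0),
        Band(7, "nir1", 833.0),
        Band(8, "nir2", 949.0),
    ),
    ms_pixel_size=2.0,
    pan_pixel_size=0.5,
)


@dataclass
class MultispectralRaster:
    """(bands, rows, cols) radiance grid with band metadata."""

    values: np.ndarray
    transform: GeoTransform
    band_set: BandSet = field(default=WORLDVIEW2_BANDS)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("multispectral values must be (bands, rows, cols)")
        if self.values.shape[0] != len(self.band_set):
            raise ValueError(
                f"band count {self.values.shape[0]} does not match band set "
                f"({len(self.band_set)})"
            )

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def band(self, sensor_index: int) -> np.ndarray:
        return self.values[self.band_set.band_index(sensor_index)]

    def valid_mask(self) -> np.ndarray:
        return np.all(np.isfinite(self.values), axis=0)

    def copy_with(self, values: np.ndarray, transform: GeoTransform | None = None):
        return MultispectralRaster(values, transform or self.transform, self.band_set)


@dataclass
class PanRaster:
    """Single-band panchromatic grid."""

    values: np.ndarray
    transform: GeoTransform

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("pan values must be (rows, cols)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def _geo_extratags(transform: GeoTransform):
    ps = float(transform.pixel_size)
    return [
        (_MODEL_PIXEL_SCALE, "d", 3, (ps, ps, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(transform.origin_x), float(transform.origin_y), 0.0)),
    ]


def write_geotiff(path: str | Path, values: np.ndarray, transform: GeoTransform,
                  dtype=np.float32) -> None:
    """Write a (rows, cols) or (bands, rows, cols) array as a tagged GeoTIFF."""
    arr = np.asarray(values).astype(dtype)
    tifffile.imwrite(
        str(path), arr, photometric="minisblack", extratags=_geo_extratags(transform)
    )


def _read_array(path: str | Path) -> tuple[np.ndarray, GeoTransform]:
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        tags = tif.pages[0].tags
        try:
            scale = tags[_MODEL_PIXEL_SCALE].value
            tie = tags[_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise ValueError(f"{path}: missing geotransform tags") from exc
    transform = GeoTransform(origin_x=float(tie[3]), origin_y=float(tie[4]),
                             pixel_size=float(scale[0]))
    return arr, transform


def read_multispectral(path: str | Path, band_set: BandSet = WORLDVIEW2_BANDS) -> MultispectralRaster:
    arr, transform = _read_array(path)
    if arr.ndim == 2:
        arr = arr[None]
    return MultispectralRaster(arr, transform, band_set)


def read_pan(path: str | Path) -> PanRaster:
    arr, transform = _read_array(path)
    return PanRaster(np.squeeze(arr), transform)


def read_mask(path: str | Path) -> tuple[np.ndarray, GeoTransform]:
    arr, transform = _read_array(path)
    return np.squeeze(arr).astype(bool), transform


def block_mean(arr: np.ndarray, factor: int) -> np.ndarray:
    """Average non-overlapping factor x factor blocks (NaN-aware)."""
    if factor == 1:
        return arr.copy()
    h, w = arr.shape[-2:]
    if h % factor or w % factor:
        raise ValueError("array dimensions must be divisible by the block factor")
    new = arr.reshape(*arr.shape[:-2], h // factor, factor, w // factor, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        return np.nanmean(new, axis=(-3, -1))
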