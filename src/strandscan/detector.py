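"""Spectral signature extraction and Spectral Angle Mapper classification.

The Spectral Angle Mapper scores each pixel by the angle between its
spectrum and a reference (end-member) spectrum,

    theta = arccos( <x, t> / (||x|| ||t||) ),

which is invariant to overall illumination: only the shape of the
spectral profile matters. A pixel is a candidate when its smallest
angle to any *target* signature is within ``max_angle_rad`` and beats
its angle to every *exclusion* signature (exclusions let confounders
such as cloud be "highlighted and removed"). Each candidate carries a
0-100 likelihood, a linear remapping of the angle:

    likelihood = 100 * (1 - theta / max_angle_rad), clipped to [0, 100].

The reference score in the original tooling is not publicly defined;
the linear map is the simplest monotone choice and is configuration,
not canon.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .raster import MultispectralRaster

_STATS = ("mean", "min", "max", "sd")


@dataclass
class SpectralSignature:
    """Per-band statistics of a labelled pixel set used as a SAM end member."""

    label: str
    role: str  # target | exclusion
    mean: np.ndarray
    min: np.ndarray
    max: np.ndarray
    sd: np.ndarray
    n_pixels: int
    source_pixels: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.role not in ("target", "exclusion"):
            raise ValueError("role must be 'target' or 'exclusion'")
        self.mean = np.asarray(self.mean, float)
        self.min = np.asarray(self.min, float)
        self.max = np.asarray(self.max, float)
        self.sd = np.asarray(self.sd, float)
        if self.n_pixels < 1:
            raise ValueError("a signature needs at least one pixel")
        if np.any(self.min > self.mean + 1e-9) or np.any(self.mean > self.max + 1e-9):
            raise ValueError("per-band min <= mean <= max violated")
        if np.any(self.sd < 0):
            raise ValueError("per-band sd must be >= 0")


@dataclass(frozen=True)
class SamParams:
    """Classifier controls: angle threshold and likelihood strata."""

    max_angle_rad: float = 0.10
    likelihood_thresholds: tuple[float, ...] = (0.0, 40.0, 65.0)

    def __post_init__(self):
        if not (0 < self.max_angle_rad <= np.pi / 2):
            raise ValueError("max_angle_rad must lie in (0, pi/2]")
        t = self.likelihood_thresholds
        if any(x < 0 or x > 100 for x in t) or list(t) != sorted(t):
            raise ValueError("likelihood thresholds must be ascending in [0, 100]")


@dataclass
class CandidatePixel:
    row: int
    col: int
    easting: float
    northing: float
    label: str  # best-matching target signature
    angle_rad: float
    likelihood: float


def extract_signature(
    raster: MultispectralRaster,
    pixels: Iterable[tuple[int, int]],
    label: str,
    role: str = "target",
) -> SpectralSignature:
    """Per-band mean/min/max/sd over the given (row, col) pixels.

    Nodata pixels are dropped; if none remain, this is an error.
    """
    pixels = list(pixels)
    if not pixels:
        raise ValueError("no pixels given")
    rr = np.array([p[0] for p in pixels])
    cc = np.array([p[1] for p in pixels])
    spectra = raster.values[:, rr, cc].astype(np.float64)  # (bands, n)
    valid = np.all(np.isfinite(spectra), axis=0)
    if not valid.any():
        raise ValueError("all requested pixels are nodata")
    spectra = spectra[:, valid]
    kept = [p for p, v in zip(pixels, valid) if v]
    return SpectralSignature(
        label=label,
        role=role,
        mean=spectra.mean(axis=1),
        min=spectra.min(axis=1),
        max=spectra.max(axis=1),
        sd=spectra.std(axis=1, ddof=0),
        n_pixels=spectra.shape[1],
        source_pixels=kept,
    )


def spectral_angle(a, b) -> float:
    """Angle in radians between two spectra; 0 iff they are positive
    scalar multiples of one another."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("spectra must have the same length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm spectrum has no direction")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.arccos(cosang))


def angle_to_likelihood(angle_rad, max_angle_rad: float):
    """Linear 0-100 score: 100 at angle 0, 0 at or beyond the threshold."""
    if max_angle_rad <= 0:
        raise ValueError("max_angle_rad must be positive")
    angle = np.asarray(angle_rad, float)
    lik = 100.0 * (1.0 - angle / max_angle_rad)
    out = np.clip(lik, 0.0, 100.0)
    return float(out) if np.isscalar(angle_rad) else out


def sam_classify(
    raster: MultispectralRaster,
    signatures: Sequence[SpectralSignature],
    params: SamParams = SamParams(),
    mask: np.ndarray | None = None,
) -> list[CandidatePixel]:
    """Run SAM over a raster, restricted to ``mask`` if given.

    A pixel is a candidate iff it is valid, inside the mask, its minimum
    angle to any target signature mean is <= ``params.max_angle_rad``,
    and that angle is strictly smaller than its angle to every exclusion
    signature mean. Candidates are ordered by (row, col).
    """
    targets = [s for s in signatures if s.role == "target"]
    exclusions = [s for s in signatures if s.role == "exclusion"]
    if not targets:
        raise ValueError("at least one target signature is required")
    for s in signatures:
        if s.mean.shape != (raster.n_bands,):
            raise ValueError(
                f"signature {s.label!r} has {s.mean.shape[0]} bands, "
                f"raster has {raster.n_bands}"
            )

    h, w = raster.shape
    select = raster.valid_mask()
    if mask is not None:
        m = getattr(mask, "mask", mask)
        if m.shape != (h, w):
            raise ValueError("mask shape does not match raster")
        select = select & m.astype(bool)
    rr, cc = np.nonzero(select)
    if len(rr) == 0:
        return []

    spectra = raster.values[:, rr, cc].astype(np.float64).T  # (n, bands)
    norms = np.linalg.norm(spectra, axis=1)
    ok = norms > 0
    spectra, rr, cc, norms = spectra[ok], rr[ok], cc[ok], norms[ok]
    unit = spectra / norms[:, None]

    def angles_to(sigs):
        mat = np.stack([s.mean / np.linalg.norm(s.mean) for s in sigs])
        return np.arccos(np.clip(unit @ mat.T, -1.0, 1.0))  # (n, n_sigs)

    tang = angles_to(targets)
    best = tang.argmin(axis=1)
    best_angle = tang[np.arange(len(rr)), best]
    keep = best_angle <= params.max_angle_rad
    if exclusions:
        eang = angles_to(exclusions).min(axis=1)
        keep &= best_angle < eang

    out = []
    xs, ys = raster.transform.pixel_center(rr, cc)
    lik = angle_to_likelihood(best_angle, params.max_angle_rad)
    for i in np.nonzero(keep)[0]:
        out.append(
            CandidatePixel(
                row=int(rr[i]), col=int(cc[i]),
                easting=float(xs[i]), northing=float(ys[i]),
                label=targets[best[i]].label,
                angle_rad=float(best_angle[i]),
                likelihood=float(lik[i]),
            )
        )
    out.sort(key=lambda c: (c.row, c.col))
    return out


# ---------------------------------------------------------------------------
# Signature and candidate I/O
# ---------------------------------------------------------------------------

def write_signatures_csv(signatures: Sequence[SpectralSignature], path) -> None:
    n_bands = len(signatures[0].mean) if signatures else 0
    header = ["label", "role", "n_pixels"] + [
        f"band_{b + 1}_{s}" for b in range(n_bands) for s in _STATS
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for sig in signatures:
            row = [sig.label, sig.role, sig.n_pixels]
            for b in range(n_bands):
                row += [sig.mean[b], sig.min[b], sig.max[b], sig.sd[b]]
            writer.writerow(row)


def read_signatures_csv(path) -> list[SpectralSignature]:
    out = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            bands = sorted(
                {int(k.split("_")[1]) for k in rec if k.startswith("band_")}
            )
            stats = {s: [float(rec[f"band_{b}_{s}"]) for b in bands] for s in _STATS}
            out.append(
                SpectralSignature(
                    label=rec["label"], role=rec["role"],
                    mean=stats["mean"], min=stats["min"], max=stats["max"],
                    sd=stats["sd"], n_pixels=int(rec["n_pixels"]),
                )
            )
    return out


def write_signatures_json(signatures: Sequence[SpectralSignature], path) -> None:
    data = [
        {
            "label": s.label, "role": s.role, "n_pixels": s.n_pixels,
            "mean": s.mean.tolist(), "min": s.min.tolist(),
            "max": s.max.tolist(), "sd": s.sd.tolist(),
            "source_pixels": [[int(r), int(c)] for r, c in s.source_pixels],
        }
        for s in signatures
    ]
    Path(path).write_text(json.dumps(data, indent=1))


def read_signatures_json(path) -> list[SpectralSignature]:
    data = json.loads(Path(path).read_text())
    return [
        SpectralSignature(
            label=d["label"], role=d["role"], mean=d["mean"], min=d["min"],
            max=d["max"], sd=d["sd"], n_pixels=d["n_pixels"],
            source_pixels=[(r, c) for r, c in d.get("source_pixels", [])],
        )
        for d in data
    ]


def candidates_to_geojson(candidates: Sequence[CandidatePixel]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [c.easting, c.northing]},
                "properties": {
                    "row": c.row, "col": c.col, "label": c.label,
                    "angle_rad": c.angle_rad, "likelihood": c.likelihood,
                },
            }
            for c in candidates
        ],
    }


def candidates_from_geojson(data: dict) -> list[CandidatePixel]:
    out = []
    for feat in data["features"]:
        p = feat["properties"]
        x, y = feat["geometry"]["coordinates"]
        out.append(
            CandidatePixel(
                row=int(p["row"]), col=int(p["col"]), easting=float(x),
                northing=float(y), label=p["label"],
                angle_rad=float(p["angle_rad"]), likelihood=float(p["likelihood"]),
            )
        )
    return out


def write_candidates_csv(candidates: Sequence[CandidatePixel], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col", "easting", "northing", "label",
                         "angle_rad", "likelihood"])
        for c in candidates:
            writer.writerow([c.row, c.col, f"{c.easting:.6f}", f"{c.northing:.6f}",
                             c.label, f"{c.angle_rad:.8f}", f"{c.likelihood:.4f}"])
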