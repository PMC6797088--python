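"""Detection-performance evaluation against ground truth / survey points.

Produces the two report shapes used to judge a stranding survey from
imagery:

* a threshold-stratified pixel/whale report — at each likelihood
  threshold, how many flagged pixels fall on true whales (the rest are
  errors of commission) and how many truth whales attract at least one
  flagged pixel (the rest are errors of omission);
* a satellite-vs-ground count comparison with per-confidence-class
  counts and the percentage excess of the satellite count.

Point sets (e.g. satellite detections vs aerial-survey GPS fixes) are
compared with a nearest-neighbour "Near" analysis and summarised as the
share of detections within given radii.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .detector import CandidatePixel
from .objects import CandidateObject
from .scenegen import TruthSet


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal rounding with ties away from zero (reporting convention)."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class SurveyPoint:
    id: str
    easting: float
    northing: float
    source: str = "truth"  # aerial | boat | ground | truth


@dataclass
class SurveyPointSet:
    points: list[SurveyPoint]

    def __post_init__(self):
        ids = [p.id for p in self.points]
        if len(set(ids)) != len(ids):
            raise ValueError("survey point ids must be unique")
        for p in self.points:
            if not (np.isfinite(p.easting) and np.isfinite(p.northing)):
                raise ValueError(f"point {p.id} has non-finite coordinates")

    @classmethod
    def from_truth(cls, truth: TruthSet, label: str = "whale") -> "SurveyPointSet":
        return cls([
            SurveyPoint(id=str(o.id), easting=o.easting, northing=o.northing)
            for o in truth.by_label(label)
        ])

    def coords(self) -> np.ndarray:
        return np.array([[p.easting, p.northing] for p in self.points])


@dataclass
class NearMatch:
    a_id: str
    b_id: str
    distance_m: float


def nearest_match(a: SurveyPointSet, b: SurveyPointSet) -> list[NearMatch]:
    """For every point in ``a``, its nearest point in ``b`` (planar
    distance, one-to-many allowed)."""
    if not b.points:
        raise ValueError("reference point set is empty")
    if not a.points:
        return []
    tree = cKDTree(b.coords())
    dists, idx = tree.query(a.coords())
    return [
        NearMatch(a_id=pa.id, b_id=b.points[j].id, distance_m=float(d))
        for pa, d, j in zip(a.points, dists, idx)
    ]


def within_distance_summary(
    matches: Sequence[NearMatch], radii: Sequence[float]
) -> list[dict]:
    """Cumulative count and integer percentage of matches within each radius."""
    if not matches:
        raise ValueError("no matches to summarise")
    if list(radii) != sorted(radii):
        raise ValueError("radii must be ascending")
    n = len(matches)
    dists = np.array([m.distance_m for m in matches])
    out = []
    for r in radii:
        k = int((dists <= r).sum())
        out.append({
            "radius_m": float(r),
            "count": k,
            "n": n,
            "percent": int(round_half_up(100.0 * k / n)),
        })
    return out


# ---------------------------------------------------------------------------
# Threshold-stratified detection report
# ---------------------------------------------------------------------------

@dataclass
class ReportRow:
    """One likelihood stratum of the detection report."""

    threshold: float
    total_pixels: int
    whale_pixels: int
    commission_pixels: int
    whales_identified: int
    n_whales: int
    omission_whales: int
    pct_whale_pixels: float
    pct_commission: float
    pct_whales_identified: float
    pct_omission: float


def report_row_from_counts(
    threshold: float,
    total_pixels: int,
    whale_pixels: int,
    whales_identified: int,
    n_whales: int,
) -> ReportRow:
    """Build one report stratum from raw counts (percentages to one
    decimal, half-up). Usable directly on published count tables."""
    if whale_pixels > total_pixels:
        raise ValueError("whale pixels cannot exceed total pixels")
    if whales_identified > n_whales:
        raise ValueError("whales identified cannot exceed whale count")
    commission = total_pixels - whale_pixels
    omission = n_whales - whales_identified

    def pct(k, n):
        return round_half_up(100.0 * k / n, 1) if n > 0 else 0.0

    return ReportRow(
        threshold=threshold,
        total_pixels=total_pixels,
        whale_pixels=whale_pixels,
        commission_pixels=commission,
        whales_identified=whales_identified,
        n_whales=n_whales,
        omission_whales=omission,
        pct_whale_pixels=pct(whale_pixels, total_pixels),
        pct_commission=pct(commission, total_pixels),
        pct_whales_identified=pct(whales_identified, n_whales),
        pct_omission=pct(omission, n_whales),
    )


@dataclass
class DetectionReport:
    rows: list[ReportRow]

    def row(self, threshold: float) -> ReportRow:
        for r in self.rows:
            if r.threshold == threshold:
                return r
        raise KeyError(f"no stratum at threshold {threshold}")

    def to_dict(self) -> dict:
        return {"rows": [vars(r) for r in self.rows]}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _whale_association(candidates, truth: TruthSet, tolerance_px: int):
    """Map each candidate to the truth whale whose footprint it hits
    (within a Chebyshev pixel tolerance), or None."""
    whales = truth.whales
    owner = -np.ones(truth.shape, dtype=int)
    for w in whales:
        for r, c in w.footprint:
            owner[r, c] = w.id
    h, wid = truth.shape
    assoc = []
    for cand in candidates:
        hit = None
        for dr in range(-tolerance_px, tolerance_px + 1):
            for dc in range(-tolerance_px, tolerance_px + 1):
                r, c = cand.row + dr, cand.col + dc
                if 0 <= r < h and 0 <= c < wid and owner[r, c] >= 0:
                    hit = int(owner[r, c])
                    break
            if hit is not None:
                break
        assoc.append(hit)
    return assoc


def detection_report(
    candidates: Sequence[CandidatePixel],
    truth: TruthSet,
    thresholds: Sequence[float] = (0.0, 40.0, 65.0),
    tolerance_px: int = 1,
) -> DetectionReport:
    """Threshold-stratified pixel and whale-level accounting.

    A candidate is a whale pixel iff it lies on, or within
    ``tolerance_px`` pixels of, a truth whale footprint (georeferencing
    jitter allowance). A whale is identified at a stratum iff at least
    one candidate with likelihood >= threshold associates to it — a
    whale claimed by several separate pixel groups still counts once.
    """
    whales = truth.whales
    if not whales:
        raise ValueError("truth set contains no whales")
    n_whales = len(whales)
    assoc = _whale_association(candidates, truth, tolerance_px)
    liks = np.array([c.likelihood for c in candidates], dtype=float)

    rows = []
    for t in thresholds:
        in_stratum = liks >= t if len(liks) else np.zeros(0, bool)
        total = int(in_stratum.sum())
        hit_ids = {a for a, keep in zip(assoc, in_stratum) if keep and a is not None}
        whale_px = sum(1 for a, keep in zip(assoc, in_stratum) if keep and a is not None)
        rows.append(
            report_row_from_counts(
                threshold=float(t),
                total_pixels=total,
                whale_pixels=whale_px,
                whales_identified=len(hit_ids),
                n_whales=n_whales,
            )
        )
    return DetectionReport(rows=rows)


# ---------------------------------------------------------------------------
# Satellite-vs-ground count comparison
# ---------------------------------------------------------------------------

@dataclass
class CountComparison:
    ground_count: int
    satellite_count: int
    class_counts: dict[int, int]
    excess: int
    excess_pct: int | None  # None when ground_count == 0
    discrepancy: str | None = None

    def to_dict(self) -> dict:
        return {
            "ground_count": self.ground_count,
            "satellite_count": self.satellite_count,
            "class_counts": {str(k): v for k, v in self.class_counts.items()},
            "excess": self.excess,
            "excess_pct": self.excess_pct,
            "discrepancy": self.discrepancy,
        }


def count_comparison(
    satellite: Sequence[CandidateObject] | Mapping[int, int] | int,
    ground_count: int,
    satellite_count: int | None = None,
) -> CountComparison:
    """Compare a satellite object count against a ground/aerial count.

    ``satellite`` may be classified objects, a {class: count} mapping,
    or a plain total. Per-class counts are validated against the total;
    a mismatch is surfaced in ``discrepancy`` rather than resolved.
    """
    if ground_count < 0:
        raise ValueError("ground_count must be >= 0")
    if isinstance(satellite, int):
        class_counts: dict[int, int] = {}
        total = satellite
    elif isinstance(satellite, Mapping):
        class_counts = {int(k): int(v) for k, v in satellite.items()}
        total = satellite_count if satellite_count is not None else sum(class_counts.values())
    else:
        class_counts = {}
        for obj in satellite:
            cls = obj.confidence_class or 3
            class_counts[cls] = class_counts.get(cls, 0) + 1
        total = len(satellite)

    discrepancy = None
    if class_counts and sum(class_counts.values()) != total:
        discrepancy = (
            f"per-class counts sum to {sum(class_counts.values())} "
            f"but satellite total is {total}"
        )
    excess = total - ground_count
    excess_pct = (
        int(round_half_up(100.0 * excess / ground_count)) if ground_count > 0 else None
    )
    return CountComparison(
        ground_count=ground_count,
        satellite_count=total,
        class_counts=class_counts,
        excess=excess,
        excess_pct=excess_pct,
        discrepancy=discrepancy,
    )


def matches_to_csv(matches: Sequence[NearMatch], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["a_id", "b_id", "distance_m"])
        for m in matches:
            writer.writerow([m.a_id, m.b_id, f"{m.distance_m:.3f}"])
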