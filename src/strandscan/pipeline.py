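"""End-to-end orchestration: simulate -> preprocess -> coast -> detect
-> objects -> evaluate, as one seeded, reproducible run.

A run is driven by a :class:`RunConfig` (loadable from YAML). Every
stage output is written as a plain file under the output directory, and
a manifest records the configuration hash, the seed and every
paper-gap default actually used (SAM angle threshold, NDWI threshold,
buffer side, likelihood mapping), so identical config + seed gives an
identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .coastmask import build_coastal_buffer, compute_ndwi, extract_water_mask
from .detector import (
    SamParams,
    SpectralSignature,
    extract_signature,
    sam_classify,
    candidates_to_geojson,
    write_candidates_csv,
    write_signatures_csv,
    write_signatures_json,
)
from .evaluate import (
    DetectionReport,
    count_comparison,
    detection_report,
    report_row_from_counts,
)
from .objects import (
    ConfidenceRules,
    classify_objects,
    group_pixels,
    objects_to_geojson,
    write_objects_csv,
)
from .preprocess import pansharpen_gram_schmidt
from .raster import write_geotiff
from .scenegen import SceneConfig, TruthSet, generate_scene, write_truth

logger = logging.getLogger("strandscan")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class SignatureConfig:
    """How end-member signatures are drawn from known whales: pixels from
    the centers of a few clearly identified carcasses."""

    n_whales: int = 3
    pixels_per_signature: int = 8
    per_decay_state: bool = False


@dataclass(frozen=True)
class CoastConfig:
    ndwi_threshold: float = 0.0
    green_band: int = 3
    nir_band: int = 7
    buffer_distance_m: float = 5.0
    side: str = "both"


@dataclass(frozen=True)
class EvaluateConfig:
    thresholds: tuple[float, ...] = (0.0, 40.0, 65.0)
    tolerance_px: int = 1


@dataclass(frozen=True)
class RunConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    sam: SamParams = field(default_factory=SamParams)
    coast: CoastConfig = field(default_factory=CoastConfig)
    signatures: SignatureConfig = field(default_factory=SignatureConfig)
    rules: ConfidenceRules = field(default_factory=ConfidenceRules)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)
    connectivity: int = 8
    use_pansharpened: bool = False  # SAM runs on the MS grid by default
    out_dir: str | None = None
    seed: int | None = None  # overrides scene.seed when set

    def resolved_scene(self) -> SceneConfig:
        if self.seed is not None:
            return dataclasses.replace(self.scene, seed=self.seed)
        return self.scene

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(klass, section):
            return klass(**{k: _coerce(v) for k, v in (section or {}).items()})

        def _coerce(v):
            return tuple(v) if isinstance(v, list) else v

        return cls(
            scene=build(SceneConfig, data.get("scene")),
            sam=build(SamParams, data.get("sam")),
            coast=build(CoastConfig, data.get("coast")),
            signatures=build(SignatureConfig, data.get("signatures")),
            rules=build(ConfidenceRules, data.get("rules")),
            evaluate=build(EvaluateConfig, data.get("evaluate")),
            connectivity=data.get("connectivity", 8),
            use_pansharpened=data.get("use_pansharpened", False),
            out_dir=data.get("out_dir"),
            seed=data.get("seed"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        d = {
            "scene": clean(self.resolved_scene()),
            "sam": clean(self.sam),
            "coast": clean(self.coast),
            "signatures": clean(self.signatures),
            "rules": clean(self.rules),
            "evaluate": clean(self.evaluate),
            "connectivity": self.connectivity,
            "use_pansharpened": self.use_pansharpened,
        }
        d["scene"].pop("band_set", None)  # band metadata is not YAML-serialisable
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def signatures_from_truth(
    ms,
    truth: TruthSet,
    config: SignatureConfig = SignatureConfig(),
) -> list[SpectralSignature]:
    """Target end members from the centers of known whales.

    Picks the largest-footprint whales (optionally the largest per decay
    state, covering carcass heterogeneity) and takes the pixels closest
    to each footprint centroid.
    """
    whales = sorted(truth.whales, key=lambda o: -len(o.footprint))
    if not whales:
        return []
    if config.per_decay_state:
        chosen, seen = [], set()
        for w in whales:
            if w.decay_state not in seen:
                chosen.append(w)
                seen.add(w.decay_state)
    else:
        chosen = whales[: config.n_whales]

    sigs = []
    for w in chosen:
        fp = np.array(w.footprint, dtype=float)
        center = fp.mean(axis=0)
        order = np.argsort(((fp - center) ** 2).sum(axis=1))
        pixels = [tuple(map(int, fp[i])) for i in order[: config.pixels_per_signature]]
        sigs.append(
            extract_signature(ms, pixels, label=f"whale_{w.id}", role="target")
        )
    return sigs


@dataclass
class PipelineResult:
    config: RunConfig
    ms: object
    pan: object
    truth: TruthSet
    water: object
    buffer: object
    signatures: list[SpectralSignature]
    candidates: list
    objects: list
    report: DetectionReport
    counts: object
    manifest: dict


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute all stages; write outputs if an output directory is set."""
    out = Path(out_dir) if out_dir else (Path(config.out_dir) if config.out_dir else None)
    scene_cfg = config.resolved_scene()

    ms, pan, truth = _stage("simulate")(generate_scene)(scene_cfg)
    logger.info("simulate: %dx%d scene, %d truth objects (%d whales)",
                *ms.shape, len(truth.objects), len(truth.whales))

    detect_raster = ms
    sharpened = None
    if config.use_pansharpened:
        sharpened = _stage("pansharpen")(pansharpen_gram_schmidt)(ms, pan)
        detect_raster = sharpened

    @_stage("coast")
    def coast():
        ndwi = compute_ndwi(ms, config.coast.green_band, config.coast.nir_band)
        water = extract_water_mask(ndwi, config.coast.ndwi_threshold)
        buf = build_coastal_buffer(
            water, config.coast.buffer_distance_m,
            ms.transform.pixel_size, config.coast.side,
        )
        return water, buf

    water, buffer_mask = coast()

    # The buffer is built on the MS grid; replicate it if detecting on the
    # sharpened grid.
    det_mask = buffer_mask.mask
    if config.use_pansharpened:
        k = ms.band_set.ratio
        det_mask = np.repeat(np.repeat(det_mask, k, axis=0), k, axis=1)

    @_stage("detect")
    def detect():
        sigs = signatures_from_truth(ms, truth, config.signatures)
        if not sigs:
            return [], []
        cands = sam_classify(detect_raster, sigs, config.sam, det_mask)
        return sigs, cands

    signatures, candidates = detect()
    logger.info("detect: %d signatures, %d candidate pixels (theta_max=%.3f rad, "
                "likelihood map: linear)", len(signatures), len(candidates),
                config.sam.max_angle_rad)

    @_stage("objects")
    def build_objects():
        px = detect_raster.transform.pixel_size
        objs = group_pixels(candidates, config.connectivity, pixel_size_m=px)
        classify_objects(objs, config.rules)
        return objs

    objs = build_objects()

    @_stage("evaluate")
    def build_report():
        if truth.whales and not config.use_pansharpened:
            report = detection_report(
                candidates, truth, config.evaluate.thresholds,
                config.evaluate.tolerance_px,
            )
        elif truth.whales:
            # map pan-grid candidates back to MS pixels for association
            k = ms.band_set.ratio
            ms_cands = [
                dataclasses.replace(c, row=c.row // k, col=c.col // k)
                for c in candidates
            ]
            report = detection_report(
                ms_cands, truth, config.evaluate.thresholds,
                config.evaluate.tolerance_px,
            )
        else:
            report = DetectionReport(rows=[
                report_row_from_counts(float(t), len(candidates) if t == 0 else 0,
                                       0, 0, 0)
                for t in config.evaluate.thresholds
            ])
        counts = count_comparison(objs, ground_count=len(truth.whales))
        return report, counts

    report, counts = build_report()

    manifest = {
        "tool": "strandscan",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": scene_cfg.seed,
        "defaults_used": {
            "sam_max_angle_rad": config.sam.max_angle_rad,
            "likelihood_mapping": "linear: 100*(1 - angle/max_angle)",
            "ndwi_threshold": config.coast.ndwi_threshold,
            "buffer_side": config.coast.side,
            "buffer_distance_m": config.coast.buffer_distance_m,
        },
        "n_truth_objects": len(truth.objects),
        "n_truth_whales": len(truth.whales),
        "n_candidates": len(candidates),
        "n_objects": len(objs),
        "counts": counts.to_dict(),
        "report": report.to_dict(),
    }

    if out is not None:
        _stage("write")(_write_outputs)(
            out, ms, pan, sharpened, truth, water, buffer_mask,
            signatures, candidates, objs, report, counts, manifest,
        )

    return PipelineResult(
        config=config, ms=ms, pan=pan, truth=truth, water=water,
        buffer=buffer_mask, signatures=signatures, candidates=candidates,
        objects=objs, report=report, counts=counts, manifest=manifest,
    )


def _write_outputs(out, ms, pan, sharpened, truth, water, buffer_mask,
                   signatures, candidates, objs, report, counts, manifest):
    out.mkdir(parents=True, exist_ok=True)
    write_geotiff(out / "ms.tif", ms.values, ms.transform)
    write_geotiff(out / "pan.tif", pan.values, pan.transform)
    if sharpened is not None:
        write_geotiff(out / "pansharpened.tif", sharpened.values, sharpened.transform)
    write_truth(truth, out / "truth")
    write_geotiff(out / "water_mask.tif", water.mask.astype(np.uint8),
                  ms.transform, dtype=np.uint8)
    write_geotiff(out / "coastal_buffer.tif", buffer_mask.mask.astype(np.uint8),
                  ms.transform, dtype=np.uint8)
    if signatures:
        write_signatures_csv(signatures, out / "signatures.csv")
        write_signatures_json(signatures, out / "signatures.json")
    (out / "candidates.geojson").write_text(
        json.dumps(candidates_to_geojson(candidates))
    )
    write_candidates_csv(candidates, out / "candidates.csv")
    (out / "objects.geojson").write_text(
        json.dumps(objects_to_geojson(objs, ms.transform))
    )
    write_objects_csv(objs, out / "objects.csv")
    report.to_json(out / "report.json")
    (out / "counts.json").write_text(json.dumps(counts.to_dict(), indent=1))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
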