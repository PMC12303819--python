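"""YAML-driven orchestration: segment -> consensus -> evaluate -> catalog.

A run is described by a single YAML document; executing it produces all
artifacts plus a JSON manifest recording the configuration hash, package
versions, seed and per-stage timings, so a rerun with the same config and
seed is byte-identical (plots aside).  External segmenters are reached
only through registered adapters (callables mapping an image to a label
mask) or through pre-computed mask files — the consensus core never
imports segmenter code.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import yaml

from . import __version__
from .consensus import ConsensusConfig, build_uber_mask
from .evaluation import evaluate_masks
from .diagnostics import intensity_catalog
from .io import read_image, read_mask, write_catalog, write_image, write_mask
from .preprocess import PreprocessConfig, equalize_local, normalize_percentile
from .types import MethodMaskSet, validate_mask
from .watershed import WatershedConfig, segment_watershed

logger = logging.getLogger("ubermask")

SegmenterAdapter = Callable[[np.ndarray, dict[str, Any]], np.ndarray]

_ADAPTERS: dict[str, SegmenterAdapter] = {}


def register_adapter(name: str, fn: SegmenterAdapter) -> None:
    """Register an external segmenter under a unique name.

    The callable receives the preprocessed image and a parameter dict and
    must return an integer label mask of the same shape.
    """
    if name in _ADAPTERS:
        raise ValueError(f"adapter {name!r} is already registered")
    if not callable(fn):
        raise TypeError("adapter must be callable")
    _ADAPTERS[name] = fn


def get_adapter(name: str) -> SegmenterAdapter:
    try:
        return _ADAPTERS[name]
    except KeyError:
        raise KeyError(
            f"no adapter registered under {name!r}; known: {sorted(_ADAPTERS)}"
        ) from None


def registered_adapters() -> list[str]:
    return sorted(_ADAPTERS)


def _filtered(cls, block: dict[str, Any]):
    names = set(cls.__dataclass_fields__)
    unknown = set(block) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**block)


@dataclass
class RunConfig:
    """Parsed run description (see module docstring for the YAML layout)."""

    image: str | None = None
    channel: int | None = None
    methods: list[dict[str, Any]] = field(default_factory=list)
    preprocess: dict[str, Any] = field(default_factory=dict)
    consensus: dict[str, Any] = field(default_factory=dict)
    evaluate: dict[str, Any] = field(default_factory=dict)
    catalog: dict[str, Any] = field(default_factory=dict)
    output_dir: str = "ubermask_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        cfg = _filtered(cls, raw)
        if not cfg.methods:
            raise ValueError("run config must list at least one method")
        names = [m.get("name") for m in cfg.methods]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate method names in config: {names}")
        return cfg


def _produce_mask(
    method: dict[str, Any], image: np.ndarray | None, seed: int
) -> np.ndarray:
    name = method.get("name", "?")
    kind = method.get("kind", "mask_file")
    params = dict(method.get("params", {}))
    if kind == "mask_file":
        path = method.get("path")
        if not path or not Path(path).exists():
            raise FileNotFoundError(
                f"method {name!r}: mask file {path!r} does not exist"
            )
        return read_mask(path)
    if image is None:
        raise ValueError(f"method {name!r} of kind {kind!r} requires an input image")
    if kind == "builtin_watershed":
        return segment_watershed(image, _filtered(WatershedConfig, params))
    if kind == "adapter":
        fn = get_adapter(method.get("adapter", name))
        mask = validate_mask(fn(image, params))
        if mask.shape != image.shape:
            raise ValueError(
                f"adapter for method {name!r} returned shape {mask.shape}, "
                f"expected {image.shape}"
            )
        return mask
    raise ValueError(f"method {name!r}: unknown kind {kind!r}")


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the configured stages and write all artifacts.

    Returns the manifest (also written to ``manifest.json`` in the output
    directory).  Any stage failure raises with a stage-attributed message.
    """
    logging.basicConfig(level=cfg.log_level)
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    manifest: dict[str, Any] = {
        "config_sha256": hashlib.sha256(cfg_blob).hexdigest(),
        "ubermask_version": __version__,
        "seed": cfg.seed,
        "stages": {},
        "outputs": {},
    }

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["stages"][name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                logger.info("stage %s: done", name)

        return _Timer()

    image = None
    if cfg.image is not None:
        with stage("preprocess"):
            image = read_image(cfg.image, channel=cfg.channel)
            pp = _filtered(PreprocessConfig, cfg.preprocess)
            image = equalize_local(normalize_percentile(image, pp), pp)
            write_image(image, out_dir / "preprocessed.tif")
            manifest["outputs"]["preprocessed"] = str(out_dir / "preprocessed.tif")

    masks: dict[str, np.ndarray] = {}
    with stage("segment"):
        for method in cfg.methods:
            name = method["name"]
            masks[name] = _produce_mask(method, image, cfg.seed)
            path = out_dir / f"mask_{name}.tif"
            write_mask(masks[name], path)
            manifest["outputs"][f"mask_{name}"] = str(path)

    with stage("consensus"):
        maskset = MethodMaskSet(masks)
        ccfg = _filtered(ConsensusConfig, cfg.consensus)
        uber, provenance = build_uber_mask(maskset, ccfg)
        write_mask(uber, out_dir / "uber_mask.tif")
        write_catalog(provenance, out_dir / "provenance.parquet")
        manifest["outputs"]["uber_mask"] = str(out_dir / "uber_mask.tif")
        manifest["outputs"]["provenance"] = str(out_dir / "provenance.parquet")

    if cfg.evaluate.get("gt_mask"):
        with stage("evaluate"):
            gt = read_mask(cfg.evaluate["gt_mask"])
            report = {}
            for name, mask in {**masks, "uber_mask": uber}.items():
                ss, match = evaluate_masks(
                    gt,
                    mask,
                    threshold=cfg.evaluate.get("iou_threshold", 0.1),
                    cutoff_px=cfg.evaluate.get("cutoff_px", 80.0),
                    expand_px=cfg.evaluate.get("expand", 0),
                )
                report[name] = {
                    "recall": ss.recall,
                    "precision": ss.precision,
                    "f1": ss.f1,
                    "jaccard": ss.jaccard,
                    "tp": match.tp,
                    "fp": match.fp,
                    "fn": match.fn,
                    "split_errors": match.split_errors,
                    "merge_errors": match.merge_errors,
                }
            with open(out_dir / "scores.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
            manifest["outputs"]["scores"] = str(out_dir / "scores.json")
            manifest["scores"] = report

    if cfg.catalog.get("channels"):
        with stage("catalog"):
            channels = {
                name: read_image(path)
                for name, path in cfg.catalog["channels"].items()
            }
            cat = intensity_catalog(
                uber,
                channels,
                bright_percentile=cfg.catalog.get("bright_percentile", 68.0),
                method="uber_mask",
            )
            write_catalog(cat, out_dir / "catalog.parquet")
            manifest["outputs"]["catalog"] = str(out_dir / "catalog.parquet")

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
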