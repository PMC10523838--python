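"""YAML run configuration.

A run config has nested blocks ``simulate`` / ``preprocess`` /
``backbone`` / ``detector`` / ``evaluate`` plus a global ``seed``,
``output_root`` and ``log_level``.  Unknown keys are rejected (typos must
not silently fall back to defaults), and every run writes its resolved
config next to its outputs so any artifact is reproducible from config +
seed alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .backbone import BackboneConfig
from .preprocess import PreprocessConfig
from .simulate import GeneratorConfig

__all__ = ["RunConfig", "load_run_config", "write_resolved_config"]

_TOP_KEYS = {"simulate", "preprocess", "backbone", "detector", "evaluate",
             "seed", "output_root", "log_level"}

_DETECTOR_KEYS = {
    "fuse_dim", "prob_threshold", "min_area", "score_threshold", "epochs",
    "batch_size", "lr", "lr_final_fraction", "weight_decay", "pos_weight",
    "augment_flips", "augment_salt_pepper", "seed",
}
_EVALUATE_KEYS = {"iou_threshold", "thresholds", "pixel_size_um"}


def _check_keys(block: dict, allowed: set[str], name: str) -> dict:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in '{name}' block: {sorted(unknown)}; "
                         f"allowed: {sorted(allowed)}")
    return dict(block)


def _dataclass_keys(cls) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)}


@dataclasses.dataclass
class RunConfig:
    simulate: dict = dataclasses.field(default_factory=dict)
    preprocess: dict = dataclasses.field(default_factory=dict)
    backbone: dict = dataclasses.field(default_factory=dict)
    detector: dict = dataclasses.field(default_factory=dict)
    evaluate: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    output_root: str = "."
    log_level: str = "INFO"

    def generator_config(self, seed: int | None = None) -> GeneratorConfig:
        block = dict(self.simulate)
        block.setdefault("seed", self.seed)
        if seed is not None:
            block["seed"] = seed
        for key in ("image_size", "cells_per_image", "condition_mix"):
            if key in block:
                block[key] = tuple(block[key])
        return GeneratorConfig(**block)

    def preprocess_config(self) -> PreprocessConfig:
        block = dict(self.preprocess)
        if "clahe_tile_grid" in block:
            block["clahe_tile_grid"] = tuple(block["clahe_tile_grid"])
        return PreprocessConfig(**block)

    def backbone_config(self) -> BackboneConfig:
        block = dict(self.backbone)
        for key in ("depths", "num_heads"):
            if key in block:
                block[key] = tuple(block[key])
        return BackboneConfig(**block)

    def estimator_params(self, seed: int | None = None) -> dict:
        params = dict(self.backbone)
        params.update(self.detector)
        params.setdefault("seed", self.seed)
        if seed is not None:
            params["seed"] = seed
        for key in ("depths", "num_heads"):
            if key in params:
                params[key] = tuple(params[key])
        return params

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_run_config(path) -> RunConfig:
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ValueError(f"could not read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    raw = _check_keys(raw, _TOP_KEYS, "top level")
    cfg = RunConfig(
        simulate=_check_keys(raw.get("simulate", {}) or {},
                             _dataclass_keys(GeneratorConfig), "simulate"),
        preprocess=_check_keys(raw.get("preprocess", {}) or {},
                               _dataclass_keys(PreprocessConfig), "preprocess"),
        backbone=_check_keys(raw.get("backbone", {}) or {},
                             _dataclass_keys(BackboneConfig), "backbone"),
        detector=_check_keys(raw.get("detector", {}) or {}, _DETECTOR_KEYS, "detector"),
        evaluate=_check_keys(raw.get("evaluate", {}) or {}, _EVALUATE_KEYS, "evaluate"),
        seed=int(raw.get("seed", 0)),
        output_root=str(raw.get("output_root", ".")),
        log_level=str(raw.get("log_level", "INFO")),
    )
    return cfg


def write_resolved_config(cfg_dict: dict, out_dir) -> Path:
    """Drop the fully resolved configuration beside a run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "resolved_config.json"
    path.write_text(json.dumps(cfg_dict, indent=2, sort_keys=True, default=str))
    return path
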