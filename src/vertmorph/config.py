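"""Run configuration: one human-readable YAML file drives the whole pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .phantom import FastingEffect, GrowthRates, PhantomParams, StudyDesign
from .pipeline import SegmentationConfig
from .segment import ShellParams

__all__ = ["RunConfig", "load_config", "save_config"]


def _build(cls, data: Mapping[str, Any], path: str):
    """Construct a (possibly nested) dataclass from a mapping.

    Unknown keys are rejected with the offending dotted path named, so a
    typo in a config file fails loudly instead of silently using defaults.
    """
    if not isinstance(data, Mapping):
        raise ValueError(f"{path or cls.__name__}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) at {path or 'top level'}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        nested = _NESTED.get((cls, name))
        if nested is not None and isinstance(value, Mapping):
            value = _build(nested, value, f"{path}.{name}" if path else name)
        elif isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[name] = value
    return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible end-to-end run needs."""

    seed: int = 0
    phantom: PhantomParams = field(default_factory=PhantomParams)
    design: StudyDesign = field(default_factory=StudyDesign)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    vertebrae: tuple[str, ...] = ("L2", "L3", "L4")
    out_dir: str = "study_out"
    log_level: str = "INFO"

    def resolved(self, seed: int | None = None, out_dir: str | None = None) -> "RunConfig":
        """Apply CLI overrides and push the run seed into the phantom."""
        cfg = self
        if seed is not None:
            cfg = replace(cfg, seed=int(seed))
        if out_dir is not None:
            cfg = replace(cfg, out_dir=str(out_dir))
        return replace(cfg, phantom=replace(cfg.phantom, seed=cfg.seed))

    def validate(self) -> None:
        self.phantom.validate()
        self.design.validate()


_NESTED = {
    (RunConfig, "phantom"): PhantomParams,
    (RunConfig, "design"): StudyDesign,
    (RunConfig, "segmentation"): SegmentationConfig,
    (SegmentationConfig, "shell"): ShellParams,
    (PhantomParams, "growth_rates"): GrowthRates,
    (PhantomParams, "fasting_effect"): FastingEffect,
}


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def load_config(path) -> RunConfig:
    """Read a RunConfig from YAML; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _build(RunConfig, data, "")


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))
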