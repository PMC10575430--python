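"""Schema-validated run configuration for the CLI umbrella.

One YAML file can carry nested sections for every stage; unknown keys are
rejected so typos fail loudly instead of silently using defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .contactflow import ProcessConfig
from .cunet import CuNetConfig
from .errors import InvalidSpecError
from .motionfocus import MixtureConfig

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Global seed/output plus per-stage configuration blocks."""

    seed: int = 0
    output_dir: str = "out"
    focus: MixtureConfig = field(default_factory=MixtureConfig)
    cunet: CuNetConfig = field(default_factory=CuNetConfig)
    process: ProcessConfig = field(default_factory=ProcessConfig)
    scene: dict = field(default_factory=dict)  # SceneSpec overrides
    tip: dict = field(default_factory=dict)  # locate_tip_scanline kwargs
    fuse: dict = field(default_factory=dict)  # fuse_boxes kwargs


def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise InvalidSpecError(f"unknown config keys in {where}: {sorted(unknown)}")
    coerced = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(coerced[f.name])
    return cls(**coerced)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from YAML; ``None`` yields pure defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise InvalidSpecError(f"{path}: config must be a mapping")
    known = {"seed", "output_dir", "focus", "cunet", "process", "scene", "tip", "fuse"}
    unknown = set(raw) - known
    if unknown:
        raise InvalidSpecError(f"unknown top-level config keys: {sorted(unknown)}")
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "out")),
        focus=_build(MixtureConfig, raw.get("focus", {}), "focus"),
        cunet=_build(CuNetConfig, raw.get("cunet", {}), "cunet"),
        process=_build(ProcessConfig, raw.get("process", {}), "process"),
        scene=dict(raw.get("scene", {})),
        tip=dict(raw.get("tip", {})),
        fuse=dict(raw.get("fuse", {})),
    )
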