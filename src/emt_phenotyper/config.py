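"""Run configuration: a shallow YAML file, schema-validated with defaults.

Unknown keys are rejected by name at every level so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .errors import ConfigError

_TOP_KEYS = {
    "seed", "out_dir", "log_level", "simulate", "conditions", "control_condition",
    "segmentation", "wound", "thresholds", "scene", "inputs",
}
_SEGMENTATION_KEYS = {"min_area_px", "smoothing_sigma"}
_WOUND_KEYS = {"texture_window_px", "area_threshold_px2"}
_THRESHOLD_KEYS = {
    "cn_epithelial_band", "ar_epithelial_band", "me_mesenchymal_min",
    "ar_mesenchymal_max", "me_epithelial_max",
}
_SCENE_KEYS = {"n_cells", "image_size_px", "noise_sd"}
_INPUT_KEYS = {"shapes_manifest", "wound_manifest", "marker_table", "ct_table"}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "emt_run"
    log_level: str = "INFO"
    simulate: bool = True
    control_condition: str | None = None
    conditions: list[str] | None = None
    segmentation: dict = field(default_factory=dict)
    wound: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    scene: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {where}: {', '.join(sorted(map(str, unknown)))}"
        )


def validate_config(path: str | Path) -> RunConfig:
    """Parse, default and validate a YAML run configuration."""
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    for block, allowed in (
        ("segmentation", _SEGMENTATION_KEYS),
        ("wound", _WOUND_KEYS),
        ("thresholds", _THRESHOLD_KEYS),
        ("scene", _SCENE_KEYS),
        ("inputs", _INPUT_KEYS),
    ):
        sub = raw.get(block, {})
        if not isinstance(sub, dict):
            raise ConfigError(f"{block} must be a mapping")
        _check_keys(sub, allowed, block)

    defaults = {f.name: getattr(RunConfig(), f.name) for f in dc_fields(RunConfig)}
    cfg = RunConfig(**(defaults | raw))

    if not isinstance(cfg.seed, int):
        raise ConfigError("seed must be an integer")
    if cfg.log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
        raise ConfigError(f"invalid log_level {cfg.log_level!r}")
    for key, p in cfg.inputs.items():
        if p is not None and not Path(p).exists():
            raise ConfigError(f"inputs.{key} path does not exist: {p}")
    if not cfg.simulate and not cfg.inputs:
        raise ConfigError("simulate is false but no inputs are configured")
    return cfg
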