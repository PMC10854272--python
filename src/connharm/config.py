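"""Pipeline configuration: a single YAML file with CLI overrides.

Example::

    seed: 0
    output_dir: results/run0
    methods: [reference, shift_site1, shift_site2, combat]
    combat_eb: true
    log_level: INFO
    synthetic:
      n_nodes: 84
      n_per_site: 84
      site_effect:
        multiplicative_factor: 0.33
      age_effect:
        between_slope: -0.0065

Keys under ``synthetic`` mirror the SyntheticConfig fields; omitted keys keep
the packaged defaults. The seed given at top level (or ``--seed``) overrides
``synthetic.seed`` so one flag controls every random draw.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from connharm.pipeline import METHODS
from connharm.synthetic import AgeEffect, SiteEffect, SyntheticConfig


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a pipeline config."""


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: Path = Path("connharm_out")
    methods: tuple[str, ...] = METHODS
    combat_eb: bool = True
    log_level: str = "INFO"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ConfigError(f"unknown methods {sorted(unknown)}; expected subset of {METHODS}")
        self.output_dir = Path(self.output_dir)
        self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)


def _build_dataclass(cls, data: dict, where: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")
    kwargs = {}
    for key, value in data.items():
        ftype = fields[key].type
        if key == "site_effect":
            value = _build_dataclass(SiteEffect, value or {}, f"{where}.site_effect")
        elif key == "age_effect":
            value = _build_dataclass(AgeEffect, value or {}, f"{where}.age_effect")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(
    path: str | Path | None = None,
    seed: int | None = None,
    output_dir: str | Path | None = None,
    methods: tuple[str, ...] | None = None,
) -> PipelineConfig:
    """Load a YAML pipeline config (or defaults) and apply CLI overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    synth = data.pop("synthetic", {}) or {}
    cfg = _build_dataclass(PipelineConfig, data, "config")
    cfg.synthetic = _build_dataclass(SyntheticConfig, synth, "config.synthetic")
    if seed is not None:
        cfg.seed = int(seed)
    if output_dir is not None:
        cfg.output_dir = Path(output_dir)
    if methods:
        cfg = dataclasses.replace(cfg, methods=tuple(methods))
    cfg.synthetic = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
    return cfg
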