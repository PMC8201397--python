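"""Pipeline configuration: YAML schema, validation, config hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import DEFAULT_CANDIDATES

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serializable to/from YAML.

    ``synthetic`` holds keyword arguments for
    :class:`uavfield.synthetic.SyntheticConfig` and is only consulted by the
    ``simulate`` step; real-data runs instead point ``raster_dir`` at a
    directory of per-index GeoTIFFs plus layout/points/samples files.
    """

    output_dir: str = "run"
    seed: int = 0
    cell_size_m: float = 0.25
    quadrat_size_m: float = 1.0
    response: str = "ear_dry_weight_g"
    candidates: list[str] = field(default_factory=lambda: list(DEFAULT_CANDIDATES))
    exclusions: list[str] = field(default_factory=list)
    sample_exclude_ids: list[str] = field(default_factory=list)
    max_candidates: int = 20
    p_adjust: str = "none"
    marginal_grid_points: int = 5
    synthetic: dict = field(default_factory=dict)
    raster_dir: str | None = None

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ConfigError("cell_size_m must be positive")
        if self.quadrat_size_m <= 0:
            raise ConfigError("quadrat_size_m must be positive")
        if self.p_adjust not in ("none", "holm"):
            raise ConfigError("p_adjust must be 'none' or 'holm'")
        unknown = set(self.exclusions) - set(self.candidates)
        if unknown:
            raise ConfigError(f"exclusions not among candidates: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable digest of the configuration (identifies a run's settings)."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
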