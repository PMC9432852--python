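"""Run configuration: one TOML file drives a whole pipeline run.

Defaults mirror the package-wide modelling choices (candidate grid, CBI
windowing, checkerboard factors, ExDet reference space, Jenks subsampling).
Unknown keys are rejected rather than ignored so that typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # paths
    occurrence_dir: str = "occurrences"
    raster_dir: str = "rasters"
    output_dir: str = "runs"
    hosts: list[str] = field(default_factory=list)
    parasite: str = "parasite"
    # pca
    variance_target: float = 0.95
    # maxent candidate grid
    classes: list[str] = field(default_factory=lambda: ["L", "Q", "H", "LQ", "LH", "QH", "LQH"])
    rms: list[float] = field(default_factory=lambda: [0.5, 1.0, 2.0, 4.0])
    background_n: int = 10_000
    k_h: int = 20
    # evaluation
    a1: int = 2
    a2: int = 2
    cbi_windows: int = 101
    cbi_window_frac: float = 0.1
    or_percentile: float = 10.0
    min_presences: int = 10
    # exdet
    exdet_reference: str = "parasite"  # 'parasite' (host-suitability space) or 'host' (PC space)
    radius_sd: float = 1.0
    # habitat / reserve
    jenks_k: int = 4
    jenks_subsample: int = 10_000
    reserve_rule: str = "intersection"
    i_threshold: float = 0.9
    # synthetic world (used by the `simulate` subcommand)
    world_rows: int = 120
    world_cols: int = 100
    world_scenarios: list[str] = field(default_factory=list)  # empty = all
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exdet_reference not in ("parasite", "host"):
            raise ConfigError("exdet_reference must be 'parasite' or 'host'")
        if self.reserve_rule not in ("intersection", "union"):
            raise ConfigError("reserve_rule must be 'intersection' or 'union'")
        if not 0 < self.variance_target <= 1:
            raise ConfigError("variance_target must be in (0, 1]")
        if self.jenks_k != 4:
            raise ConfigError("habitat classification uses exactly 4 levels")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        doc = tomllib.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self) | {"hash": self.config_hash()}, indent=2))
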