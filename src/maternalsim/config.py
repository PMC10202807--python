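"""Run configuration: YAML schema, validation, manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

MODES = ("synth", "simulate", "calibrate", "ppc", "project")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    mode: str
    out_dir: str = "out"
    world_dir: str | None = None      # simulate/project: a synth output dir
    archive_path: str | None = None   # ppc: archive.json from calibrate
    n_countries: int = 3
    years: tuple[int, int] = (1986, 2020)
    project_until: int = 2035
    report_from: int = 1990
    n_agents: int = 800
    iterations: int = 10
    noise_sd: float = 0.0
    cut_year: int = 2015
    anneal_steps: int = 400
    ppc_iterations: int = 40
    archive_k: int = 100
    seeds: dict = field(default_factory=lambda: {"world": 11, "anneal": 0, "first_order": 1})
    trace: bool = False

    def __post_init__(self):
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not all(isinstance(v, int) for v in self.seeds.values()):
            raise ConfigError("seeds must be integers")
        self.years = tuple(self.years)
        if len(self.years) != 2 or self.years[0] >= self.years[1]:
            raise ConfigError("years must be [start, end] with start < end")
        if not (self.years[0] < self.report_from <= self.years[1]):
            raise ConfigError("report_from must fall inside (start, end]: the "
                              "years before it are burn-in")
        if self.mode in ("simulate", "project") and self.world_dir is not None:
            if not Path(self.world_dir).exists():
                raise ConfigError(f"world_dir {self.world_dir!r} does not exist")
        if self.mode == "ppc" and self.archive_path is not None:
            if not Path(self.archive_path).exists():
                raise ConfigError(f"archive_path {self.archive_path!r} does not exist")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["years"] = list(self.years)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration; unknown keys rejected."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} not found")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "mode" not in raw:
        raise ConfigError("config is missing required key 'mode'")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def write_manifest(out_dir: Path, config: RunConfig, outputs: list[str],
                   status: str = "complete") -> Path:
    """run_manifest.json: config + seeds + a digest, enough to reproduce."""
    payload = {"config": config.to_dict(), "outputs": sorted(outputs), "status": status}
    digest = hashlib.sha256(
        json.dumps(payload["config"], sort_keys=True).encode()).hexdigest()
    payload["config_digest"] = digest
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path
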