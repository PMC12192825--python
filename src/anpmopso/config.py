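"""Run configuration: YAML parsing, validation, seeding, manifests.

One global seed fans out to per-component seeds through a counter-based
derivation (``numpy.random.SeedSequence`` over (base, component-CRC)), so
toggling one module never shifts another module's random stream.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import platform
import time
import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .objectives import ObjectivesConfig
from .optimizer import SwarmConfig


class ConfigError(ValueError):
    pass


def derive_seed(base_seed: int, component: str) -> int:
    """Deterministic per-component child seed (< 2**31)."""
    ss = np.random.SeedSequence([int(base_seed), zlib.crc32(component.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class WnpeeConfig:
    k_list: list[int] = field(default_factory=lambda: [5, 10, 15])
    dim: int | None = None
    r: float = 2.0
    max_iter: int = 30
    tol: float = 1e-8


@dataclass
class InitConfig:
    scramble: bool = False
    skip_zero: bool = False


@dataclass
class BenchmarkConfig:
    problem: str = "MMF1"
    runs: int = 15


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "anpmopso_out"
    normalize: bool = True
    wnpee: WnpeeConfig = field(default_factory=WnpeeConfig)
    init: InitConfig = field(default_factory=InitConfig)
    objectives: ObjectivesConfig = field(default_factory=ObjectivesConfig)
    swarm: SwarmConfig = field(default_factory=SwarmConfig)
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)

    def validate(self) -> None:
        try:
            self.swarm.validate()
        except Exception as exc:
            raise ConfigError(str(exc)) from exc
        if self.wnpee.r <= 1:
            raise ConfigError("wnpee.r must be > 1")
        if self.objectives.np_k < 1:
            raise ConfigError("objectives.np_k must be >= 1")
        if self.benchmark.runs < 1:
            raise ConfigError("benchmark.runs must be >= 1")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_SECTION_TYPES = {
    "wnpee": WnpeeConfig,
    "init": InitConfig,
    "objectives": ObjectivesConfig,
    "swarm": SwarmConfig,
    "benchmark": BenchmarkConfig,
}


def _apply(obj, values: dict, prefix: str) -> None:
    known = {f.name for f in fields(obj)}
    for key, val in values.items():
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown key {prefix}{key!r}{suggestion}")
        setattr(obj, key, val)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides.

    Unknown keys are rejected with a close-match suggestion; numeric fields
    are validated against module contracts before any compute.
    """
    cfg = RunConfig()
    data: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
    if overrides:
        data = _merge(data, overrides)

    top_known = {f.name for f in fields(RunConfig)}
    for key, val in data.items():
        if key not in top_known:
            hint = difflib.get_close_matches(key, top_known, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown key {key!r}{suggestion}")
        if key in _SECTION_TYPES:
            if not isinstance(val, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            _apply(getattr(cfg, key), val, prefix=f"{key}.")
        else:
            setattr(cfg, key, val)
    cfg.validate()
    return cfg


def _merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def write_manifest(output_dir: str | Path, config: RunConfig,
                   extra: dict | None = None,
                   started: float | None = None) -> Path:
    """MANIFEST.json: config hash, seed, versions, wall time, extras."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "wall_time_s": (time.time() - started) if started else None,
    }
    if extra:
        manifest.update(extra)
    path = output_dir / "MANIFEST.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return path
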