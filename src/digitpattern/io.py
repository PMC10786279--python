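"""Shared infrastructure: config parsing, result tables, manifests, RNG.

All configuration files are flat YAML key/value mappings validated against
the dataclass they configure (unknown keys and missing required keys are
errors that name the offending keys). Spatial/temporal results are written
as long-format CSV (time, position, component, value) so every output stays
inspectable with standard tools. Every CLI run writes one manifest
recording the configuration hash, seeds and file lists.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import ModelParameters
from .simulate import GrowthConfig, SimulationRecord


class ConfigError(ValueError):
    """Raised for unknown/missing keys or type mismatches in config files."""


_CONFIG_TYPES = {
    "params": ModelParameters,
    "growth": GrowthConfig,
}


def _coerce(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        raise ConfigError(f"unknown key(s) for {cls.__name__}: {unknown}")
    required = {
        name for name, f in fields.items()
        if f.default is dataclasses.MISSING
        and f.default_factory is dataclasses.MISSING  # type: ignore[misc]
    }
    missing = sorted(required - set(data))
    if missing:
        raise ConfigError(f"missing key(s) for {cls.__name__}: {missing}")
    clean = {}
    for key, value in data.items():
        expected = fields[key].type
        if isinstance(value, bool) or isinstance(value, (list, dict)):
            raise ConfigError(f"key {key!r}: expected a scalar, got {value!r}")
        if isinstance(value, str):
            if "str" not in str(expected):
                raise ConfigError(
                    f"key {key!r}: expected a number, got string {value!r}"
                )
            clean[key] = value
        else:
            clean[key] = float(value) if not isinstance(value, int) else value
    try:
        return cls(**clean)
    except (TypeError, ValueError) as err:
        raise ConfigError(str(err)) from err


def load_config(path, kind: str):
    """Load and validate a configuration file for one config kind.

    ``kind`` is "params" or "growth". Defaults are materialized by the
    dataclass; errors name the offending keys.
    """
    if kind not in _CONFIG_TYPES:
        raise ConfigError(f"unknown config kind {kind!r}")
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path} does not hold a key/value mapping")
    return _coerce(_CONFIG_TYPES[kind], data)


def dump_config(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(obj), fh, sort_keys=False)


def config_hash(obj) -> str:
    payload = json.dumps(dataclasses.asdict(obj), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# -- seeded RNG management --------------------------------------------------

def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-module RNG derived from one run seed.

    Every source of randomness in a run flows through substreams of the
    single run seed, so runs are reproducible end to end.
    """
    child = np.random.SeedSequence([seed, int.from_bytes(
        hashlib.sha256(label.encode()).digest()[:4], "big"
    )])
    return np.random.default_rng(child)


def substream_seed(seed: int, label: str) -> int:
    """A derived integer seed (< 2**31) for APIs that take plain seeds."""
    return int(substream(seed, label).integers(0, 2**31 - 1))


# -- result tables ----------------------------------------------------------

def record_to_frame(record: SimulationRecord) -> pd.DataFrame:
    """Long-format snapshot table: time, position, component, value."""
    from .model import COMPONENTS

    chunks = []
    for state in record.states:
        for comp in COMPONENTS:
            chunks.append(pd.DataFrame({
                "time": state.t,
                "position": state.x,
                "component": comp,
                "value": getattr(state, comp),
            }))
    return pd.concat(chunks, ignore_index=True)


def band_events_frame(record: SimulationRecord) -> pd.DataFrame:
    return pd.DataFrame(
        [{"time": ev.time, "position": ev.position} for ev in record.band_events],
        columns=["time", "position"],
    )


def write_manifest(
    out_dir, seed, configs: dict, inputs: list, outputs: list
) -> Path:
    """Write the run manifest next to the outputs; returns its path."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config_hashes": {k: config_hash(v) for k, v in configs.items()},
        "configs": {k: dataclasses.asdict(v) for k, v in configs.items()},
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
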