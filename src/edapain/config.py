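"""YAML configuration handling and run-sidecar logging.

A config file is a nested mapping with one section per pipeline stage
(``simulate:``, ``preprocess:``, ``vfcdm:``, ``cvxeda:``, ``indices:``,
``stream:``, ``ml:``).  Unknown keys raise early so typos do not silently
fall back to defaults.  Every CLI run writes a JSON sidecar next to its
outputs recording the resolved configuration and seed, so any output file
can be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import yaml

from .records import SimulationConfig, ValidationError
from .realtime import StreamConfig

_SECTIONS = {"simulate", "preprocess", "vfcdm", "cvxeda", "indices", "stream", "ml"}


def load_config(path: str | Path | None) -> dict:
    """Load and minimally validate a YAML config; ``None`` gives defaults."""
    if path is None:
        return {}
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ValidationError(f"unknown config section(s): {sorted(unknown)}")
    return raw


def simulation_config(cfg: dict, seed: int | None = None) -> SimulationConfig:
    section = dict(cfg.get("simulate", {}))
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(section) - known
    if unknown:
        raise ValidationError(f"unknown simulate key(s): {sorted(unknown)}")
    for key in ("isi_range", "spontaneous_amp_range"):
        if key in section:
            section[key] = tuple(section[key])
    if seed is not None:
        section["seed"] = seed
    return SimulationConfig(**section)


def stream_config(cfg: dict) -> StreamConfig:
    section = dict(cfg.get("stream", {}))
    known = {f.name for f in dataclasses.fields(StreamConfig)}
    unknown = set(section) - known
    if unknown:
        raise ValidationError(f"unknown stream key(s): {sorted(unknown)}")
    if "indices" in section:
        section["indices"] = tuple(section["indices"])
    return StreamConfig(**section)


def write_sidecar(out_dir: str | Path, command: str, config: dict, seed: int | None) -> Path:
    """Write the reproducibility sidecar (config + seed + timestamp)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "command": command,
        "seed": seed,
        "config": config,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / f"{command}_run.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
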