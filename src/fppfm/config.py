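"""Run configuration: YAML files with flat dotted keys, CLI overrides,
and run manifests recording seed, options and versions."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import yaml


def load_config(path=None) -> dict:
    """Load a YAML config of flat dotted keys (e.g. ``cov.per_stage: true``)."""
    if path is None:
        return {}
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    return {str(k): v for k, v in raw.items()}


def merged(config: dict, overrides: dict) -> dict:
    """CLI overrides (not-None values) win over file values."""
    out = dict(config)
    for k, v in overrides.items():
        if v is not None:
            out[k] = v
    return out


def setup_logging(level: str = "INFO"):
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


class Manifest:
    """Collects the effective config, seed and wall time of one run."""

    def __init__(self, subcommand: str, config: dict, seed):
        self.t0 = time.time()
        self.payload = {
            "subcommand": subcommand,
            "config": config,
            "seed": seed,
        }

    def write(self, out_dir, outputs=None):
        from fppfm import __version__

        self.payload["fppfm_version"] = __version__
        self.payload["wall_time_s"] = round(time.time() - self.t0, 3)
        self.payload["outputs"] = outputs or []
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(self.payload, indent=2, default=str) + "\n")
        return path
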