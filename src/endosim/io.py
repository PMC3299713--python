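"""Configuration loading/validation and run manifests.

Configuration files are YAML (JSON is a YAML subset) with top-level sections
``params``, ``settings``, ``ensemble``, plus ``mechanism``, ``scale`` and
``out_dir``.  Unknown keys anywhere are rejected with the offending key
named, and every field is validated by the owning dataclass before any
computation starts.  The effective (defaults-applied) configuration can be
persisted and round-trips to an equal RunConfig.

Every CLI run writes a ``manifest.json`` beside its outputs recording the
command, seed, configuration hash, package version and wall-clock time, so
any output file can be traced to its exact inputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .mechanisms import Phenotype, get_mechanism
from .params import ConfigurationError, ModelParams, SimulationSettings

__all__ = ["RunConfig", "load_config", "save_config", "write_manifest", "config_hash"]

#: Scale presets applied to fields the user left unset.
SCALE_PRESETS = {
    "desk": {"n_initial": 1000, "n_runs": 100, "n_samples": 500},
    "paper": {"n_initial": 9000, "n_runs": 4000, "n_samples": 10000},
}


@dataclass
class RunConfig:
    """Validated run configuration (parameters, settings, fitting options)."""

    params: ModelParams = field(default_factory=ModelParams)
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    mechanism: str = "ME+/CX-/EU"
    n_samples: int = 500
    threshold: float = 0.025
    bounds: dict = field(default_factory=dict)
    scale: str = "desk"
    out_dir: str = "endosim-out"

    def to_dict(self) -> dict:
        nprog1 = {Phenotype(k).name: v for k, v in self.params.nprog_stage1.items()}
        nprog2 = {Phenotype(k).name: v for k, v in self.params.nprog_stage2.items()}
        p = {n: v for n, v in self.params.flat_items() if not n.startswith("nprog")}
        p["nprog_stage1"] = nprog1
        p["nprog_stage2"] = nprog2
        return {
            "params": p,
            "settings": {
                "n_initial": self.settings.n_initial,
                "n_runs": self.settings.n_runs,
                "horizon": self.settings.horizon,
                "observation_interval": self.settings.observation_interval,
                "seed": self.settings.seed,
            },
            "mechanism": self.mechanism,
            "ensemble": {
                "n_samples": self.n_samples,
                "threshold": self.threshold,
                "bounds": {k: list(v) for k, v in self.bounds.items()},
            },
            "scale": self.scale,
            "out_dir": self.out_dir,
        }


def _reject_unknown(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in {where}: {sorted(unknown)} (allowed: {sorted(allowed)})"
        )


def _build_params(section: dict) -> ModelParams:
    allowed = set(ModelParams._SCALARS) | {"nprog_stage1", "nprog_stage2"}
    _reject_unknown(section, allowed, "params")
    kwargs = dict(section)
    for key in ("nprog_stage1", "nprog_stage2"):
        if key in kwargs:
            try:
                kwargs[key] = {Phenotype[k]: float(v) for k, v in kwargs[key].items()}
            except KeyError as exc:
                raise ConfigurationError(f"unknown lineage in {key}: {exc}") from None
    return ModelParams(**kwargs)


def parse_config(raw: dict) -> RunConfig:
    """Build a validated RunConfig from a parsed mapping, applying scale
    presets to unset size fields."""
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration root must be a mapping")
    _reject_unknown(
        raw, {"params", "settings", "mechanism", "ensemble", "scale", "out_dir"}, "config"
    )
    scale = raw.get("scale", "desk")
    if scale not in SCALE_PRESETS:
        raise ConfigurationError(
            f"scale must be one of {sorted(SCALE_PRESETS)}, got {scale!r}"
        )
    preset = SCALE_PRESETS[scale]

    params = _build_params(raw.get("params", {}) or {})

    s = dict(raw.get("settings", {}) or {})
    _reject_unknown(
        s, {"n_initial", "n_runs", "horizon", "observation_interval", "seed"}, "settings"
    )
    s.setdefault("n_initial", preset["n_initial"])
    s.setdefault("n_runs", preset["n_runs"])
    settings = SimulationSettings(**s)

    e = dict(raw.get("ensemble", {}) or {})
    _reject_unknown(e, {"n_samples", "threshold", "bounds"}, "ensemble")
    n_samples = int(e.get("n_samples", preset["n_samples"]))
    threshold = float(e.get("threshold", 0.025))
    bounds = {k: (float(v[0]), float(v[1])) for k, v in (e.get("bounds", {}) or {}).items()}

    mechanism = raw.get("mechanism", "ME+/CX-/EU")
    get_mechanism(mechanism)  # validates the id eagerly

    return RunConfig(
        params=params,
        settings=settings,
        mechanism=mechanism,
        n_samples=n_samples,
        threshold=threshold,
        bounds=bounds,
        scale=scale,
        out_dir=str(raw.get("out_dir", "endosim-out")),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    try:
        return parse_config(raw)
    except ConfigurationError as exc:
        raise ConfigurationError(f"{path}: {exc}") from None


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: RunConfig | None = None,
    seed=None,
    started: float | None = None,
    extra: dict | None = None,
) -> Path:
    """Persist run provenance next to the outputs; returns the manifest path."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "version": __version__,
        "wall_clock_s": None if started is None else round(time.time() - started, 3),
        "scale": None if config is None else config.scale,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
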