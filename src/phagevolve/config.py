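"""YAML configuration loading, validation, and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, fields as _dc_fields
from pathlib import Path

import yaml

from .designs import BUNDLED_DESIGNS, bundled_design
from .dynamics import ExperimentDesign, TransferProtocol, Treatment
from .errors import ConfigError
from .model import ModelParams

__all__ = ["Config", "load_config", "dump_config", "write_manifest"]

_TOP_KEYS = {"profile", "params", "protocol", "design", "noise", "seed"}
_NOISE_KEYS = {"count_cv", "overdispersion", "n_clones"}
_PROFILES = {"paper_defaults": ModelParams.paper_defaults}


@dataclass
class Config:
    """Fully resolved run configuration."""

    params: ModelParams = field(default_factory=ModelParams.paper_defaults)
    protocol: TransferProtocol = field(default_factory=TransferProtocol)
    design: ExperimentDesign | None = None
    noise: dict = field(default_factory=lambda: {"count_cv": 0.2, "overdispersion": 0.0,
                                                 "n_clones": 24})
    seed: int = 0
    profile: str = "paper_defaults"


def _coerce(value):
    # pyyaml (YAML 1.1) reads '1.0e6' as a string; accept it as a number
    if isinstance(value, str):
        try:
            return float(value)
        except ValueError:
            return value
    return value


def _coerce_map(d: dict, skip=()) -> dict:
    return {k: (v if k in skip else _coerce(v)) for k, v in d.items()}


def _build_design(spec) -> ExperimentDesign:
    if isinstance(spec, str):
        return bundled_design(spec)
    if isinstance(spec, dict):
        if "name" in spec and set(spec) == {"name"}:
            return bundled_design(spec["name"])
        unknown = set(spec) - {"label", "treatments"}
        if unknown:
            raise ConfigError(f"unknown design keys: {sorted(unknown)}")
        treatments = []
        allowed = {f.name for f in _dc_fields(Treatment)}
        for td in spec.get("treatments", []):
            bad = set(td) - allowed
            if bad:
                raise ConfigError(f"unknown treatment keys: {sorted(bad)}")
            td = _coerce_map(td, skip=("label", "protocol", "sampling_days"))
            if "protocol" in td:
                td["protocol"] = TransferProtocol(**_coerce_map(td["protocol"]))
            if "sampling_days" in td:
                td["sampling_days"] = tuple(int(d) for d in td["sampling_days"])
            if "n_replicates" in td:
                td["n_replicates"] = int(td["n_replicates"])
            treatments.append(Treatment(**td))
        return ExperimentDesign(spec.get("label", "custom"), tuple(treatments))
    raise ConfigError(f"design must be a name or mapping, got {type(spec).__name__}")


def load_config(path) -> Config:
    """Load and validate a YAML config; unknown keys are rejected.

    An empty file (or just ``profile: paper_defaults``) resolves to the
    bundled default parameter profile.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    profile = raw.get("profile", "paper_defaults")
    if profile not in _PROFILES:
        raise ConfigError(f"unknown profile {profile!r}; available: {sorted(_PROFILES)}")
    params = _PROFILES[profile]()
    overrides = raw.get("params", {}) or {}
    if not isinstance(overrides, dict):
        raise ConfigError("'params' must be a mapping")
    overrides = _coerce_map(overrides, skip=('mutation_model',))
    params = ModelParams.from_dict({**params.to_dict(), **overrides})

    proto_raw = _coerce_map(raw.get("protocol", {}) or {})
    if "n_transfers" in proto_raw:
        proto_raw["n_transfers"] = int(proto_raw["n_transfers"])
    protocol = TransferProtocol(**proto_raw)
    design = _build_design(raw["design"]) if "design" in raw else None

    noise = {"count_cv": 0.2, "overdispersion": 0.0, "n_clones": 24}
    user_noise = raw.get("noise", {}) or {}
    bad = set(user_noise) - _NOISE_KEYS
    if bad:
        raise ConfigError(f"unknown noise keys: {sorted(bad)}")
    noise.update(_coerce_map(user_noise))
    noise["n_clones"] = int(noise["n_clones"])

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        raise ConfigError("seed must be a nonnegative integer")
    return Config(params=params, protocol=protocol, design=design,
                  noise=noise, seed=seed, profile=profile)


def dump_config(config: Config) -> dict:
    """Normalised plain-dict form of a config (YAML/JSON serialisable)."""
    out = {
        "profile": config.profile,
        "params": config.params.to_dict(),
        "protocol": {
            "n_transfers": config.protocol.n_transfers,
            "hours_per_transfer": config.protocol.hours_per_transfer,
            "dilution": config.protocol.dilution,
            "phage_dilution": config.protocol.phage_dilution,
        },
        "noise": dict(config.noise),
        "seed": config.seed,
    }
    if config.design is not None:
        if config.design.label in BUNDLED_DESIGNS:
            out["design"] = config.design.label
        else:
            out["design"] = {
                "label": config.design.label,
                "treatments": [
                    {"label": t.label, "V0": t.V0, "K": t.K,
                     "inoculum_fraction": t.inoculum_fraction,
                     "n_replicates": t.n_replicates,
                     "sampling_days": list(t.sampling_days)}
                    for t in config.design.treatments
                ],
            }
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, config: Config, outputs, extra=None) -> Path:
    """Write a JSON run manifest sufficient to reproduce the run."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "phagevolve",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "config": dump_config(config),
        "seed": config.seed,
        "outputs": {str(Path(p).name): _sha256(Path(p)) for p in outputs},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
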