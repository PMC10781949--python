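"""Run configuration, serialization, and manifests.

Configs are YAML or JSON mappings validated strictly: unknown keys are
errors (silent misconfiguration of coupling conventions is worse than a
loud one), defaults are filled in, and a resolved config round-trips
bit-identically.  Results are written as TSV tables (12 significant
digits; tabs avoid locale decimal ambiguity) plus a JSON manifest
recording the seed, a hash of the resolved config, and the package
version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .messages import ConfigurationError, MessageSpec
from .oscillators import SimTrajectory

__all__ = ["RunConfig", "load_config", "write_results", "read_trajectory", "config_schema"]


#: key -> (default, validator); the published schema of a run config.
_SCHEMA: dict[str, tuple] = {
    "omega0": (0.0, lambda v: isinstance(v, (int, float))),
    "gamma": (0.0, lambda v: isinstance(v, (int, float)) and v >= 0),
    "coupling": (1.0, lambda v: isinstance(v, (int, float)) and v >= 0),
    "coupling_function": ("attractive_sine", lambda v: isinstance(v, str)),
    "n": (100, lambda v: isinstance(v, int) and v >= 1),
    "fixture": (None, lambda v: v is None or isinstance(v, str)),
    "messages": ([], lambda v: isinstance(v, list)),
    "dt": (0.01, lambda v: isinstance(v, (int, float)) and v > 0),
    "horizon": (100.0, lambda v: isinstance(v, (int, float)) and v > 0),
    "burn_in_fraction": (0.5, lambda v: isinstance(v, (int, float)) and 0 <= v < 1),
    "integrator": ("rk4", lambda v: v in ("rk4", "euler")),
    "seed": (0, lambda v: isinstance(v, int)),
    "out_prefix": ("run", lambda v: isinstance(v, str)),
}

_MESSAGE_KEYS = {
    "id",
    "modality",
    "decay_rate",
    "secretion_rate",
    "activation_threshold",
    "ligand",
    "receptor",
    "weight",
}


def config_schema() -> dict:
    """The published config schema: key -> default."""
    return {k: default for k, (default, _) in _SCHEMA.items()}


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved, validated simulation configuration."""

    omega0: float = 0.0
    gamma: float = 0.0
    coupling: float = 1.0
    coupling_function: str = "attractive_sine"
    n: int = 100
    fixture: str | None = None
    messages: tuple[MessageSpec, ...] = ()
    dt: float = 0.01
    horizon: float = 100.0
    burn_in_fraction: float = 0.5
    integrator: str = "rk4"
    seed: int = 0
    out_prefix: str = "run"

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["messages"] = [
            {k: (v.value if hasattr(v, "value") else v) for k, v in asdict(m).items()}
            for m in self.messages
        ]
        return doc

    def write(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
            else:
                json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def content_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _parse_message_block(block: dict, index: int) -> MessageSpec:
    unknown = set(block) - _MESSAGE_KEYS
    if unknown:
        raise ConfigurationError(f"messages[{index}]: unknown keys {sorted(unknown)}")
    if "id" not in block:
        raise ConfigurationError(f"messages[{index}]: missing required key 'id'")
    try:
        return MessageSpec(**block)
    except ValueError as exc:
        raise ConfigurationError(f"messages[{index}]: {exc}") from exc


def resolve_config(doc: dict) -> RunConfig:
    """Validate a raw mapping against the schema and fill defaults."""
    if not isinstance(doc, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(doc).__name__}")
    unknown = set(doc) - set(_SCHEMA)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    resolved = {}
    for key, (default, valid) in _SCHEMA.items():
        if key in doc:
            value = doc[key]
            if not valid(value):
                raise ConfigurationError(f"invalid value for {key!r}: {value!r}")
        else:
            value = default
        resolved[key] = value
    resolved["messages"] = tuple(
        _parse_message_block(b, i) for i, b in enumerate(resolved["messages"])
    )
    resolved["omega0"] = float(resolved["omega0"])
    resolved["gamma"] = float(resolved["gamma"])
    resolved["coupling"] = float(resolved["coupling"])
    resolved["dt"] = float(resolved["dt"])
    resolved["horizon"] = float(resolved["horizon"])
    resolved["burn_in_fraction"] = float(resolved["burn_in_fraction"])
    return RunConfig(**resolved)


def load_config(path) -> RunConfig:
    """Load and strictly validate a YAML or JSON config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    return resolve_config(doc if doc is not None else {})


# --- results -----------------------------------------------------------------


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_results(result, prefix, seed: int | None = None, config: RunConfig | None = None) -> list[str]:
    """Write a trajectory (TSV) or a report (JSON) plus a run manifest.

    Returns the list of files written.  Two runs with the same seed and
    config produce byte-identical tables.
    """
    prefix = str(prefix)
    Path(prefix).parent.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    if isinstance(result, SimTrajectory):
        traj_path = f"{prefix}_trajectory.tsv"
        with open(traj_path, "w") as fh:
            fh.write("time\tR\tTheta\tsigma\n")
            for t, r, th, sg in zip(result.times, result.R, result.Theta, result.sigma):
                fh.write(f"{_fmt(t)}\t{_fmt(r)}\t{_fmt(th)}\t{_fmt(sg)}\n")
        written.append(traj_path)
        if result.theta_matrix is not None:
            phases_path = f"{prefix}_phases.tsv"
            n = result.theta_matrix.shape[1]
            with open(phases_path, "w") as fh:
                fh.write("time\t" + "\t".join(f"theta_{j}" for j in range(n)) + "\n")
                for t, row in zip(result.times, result.theta_matrix):
                    fh.write(_fmt(t) + "\t" + "\t".join(_fmt(x) for x in row) + "\n")
            written.append(phases_path)
    elif hasattr(result, "to_dict"):
        report_path = f"{prefix}_report.json"
        with open(report_path, "w") as fh:
            json.dump(result.to_dict(), fh, indent=1, sort_keys=True)
        written.append(report_path)
    else:
        raise TypeError(f"cannot write result of type {type(result).__name__}")

    manifest = {
        "seed": seed if seed is not None else (config.seed if config else None),
        "config_hash": config.content_hash() if config else None,
        "package_version": __version__,
        "files": [Path(p).name for p in written],
    }
    manifest_path = f"{prefix}_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    written.append(manifest_path)
    return written


def read_trajectory(path) -> SimTrajectory:
    """Read back a trajectory table written by write_results."""
    df = pd.read_csv(path, sep="\t")
    return SimTrajectory(
        times=df["time"].to_numpy(),
        R=df["R"].to_numpy(),
        Theta=df["Theta"].to_numpy(),
        sigma=df["sigma"].to_numpy(),
    )
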