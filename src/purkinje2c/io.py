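"""Configuration files, run manifests and report writers.

Configuration is YAML with three optional sections::

    dt_ms: 0.025
    duration_ms: 45000
    stride: 4
    protocol:            # omit for the unperturbed model
      name: alcohol
      y: 0.014
      m: 0.005
      onset_s: 50.0
    params:              # overrides on the published defaults
      gmax_soma: {bk: 0.0}
      gmax_dend: {bk: 0.0}
      pumps: {k_na: 12.0}
      g_erg: 3.08

Unknown keys are rejected by name; conductance densities must be >= 0.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cell_model import SimConfig
from .params import ModelParams, PumpExchangerSet
from .protocols import AlcoholProtocol

__all__ = [
    "ConfigError",
    "load_config",
    "dump_config",
    "RunManifest",
    "write_report",
]


class ConfigError(ValueError):
    pass


_TOP_KEYS = {"dt_ms", "duration_ms", "stride", "protocol", "params"}


def _check_keys(mapping, allowed, context):
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")


def _params_from_dict(overrides: dict) -> ModelParams:
    params = ModelParams()
    allowed = {f.name for f in dataclasses.fields(ModelParams)}
    _check_keys(overrides, allowed, "params")
    for key, value in overrides.items():
        if key in ("gmax_soma", "gmax_dend"):
            table = getattr(params, key)
            _check_keys(value, table, key)
            for cur, g in value.items():
                if g < 0:
                    raise ConfigError(f"{key}.{cur}: g_max must be >= 0")
                table[cur] = float(g)
        elif key == "pumps":
            allowed_p = {f.name for f in dataclasses.fields(PumpExchangerSet)}
            _check_keys(value, allowed_p, "pumps")
            for name, v in value.items():
                if v < 0:
                    raise ConfigError(f"pumps.{name}: density must be >= 0")
                setattr(params.pumps, name, float(v))
        else:
            if key.startswith("g_") and value < 0:
                raise ConfigError(f"{key}: conductance must be >= 0")
            setattr(params, key, value)
    return params


def load_config(path) -> SimConfig:
    """Load a SimConfig; defaults are the published parameter table."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    params = _params_from_dict(raw.get("params") or {})
    protocol = None
    if raw.get("protocol"):
        proto = dict(raw["protocol"])
        name = proto.pop("name", "alcohol")
        if name != "alcohol":
            raise ConfigError(f"unknown protocol {name!r}")
        _check_keys(proto, {"y", "m", "onset_s"}, "protocol")
        protocol = AlcoholProtocol(
            y_mA_cm2_s=float(proto.get("y", 0.014)),
            m_mA_cm2_s=float(proto.get("m", 0.005)),
            onset_s=float(proto.get("onset_s", 50.0)),
        )
    return SimConfig(
        params=params,
        duration_ms=float(raw.get("duration_ms", 1000.0)),
        dt_ms=float(raw.get("dt_ms", 0.025)),
        stride=int(raw.get("stride", 4)),
        protocol=protocol,
    )


def dump_config(config: SimConfig, path) -> None:
    """Write a config file that round-trips through :func:`load_config`.

    Only the fields that differ from the defaults are written for ``params``.
    """
    default = ModelParams()
    overrides: dict = {}
    for f in dataclasses.fields(ModelParams):
        val = getattr(config.params, f.name)
        ref = getattr(default, f.name)
        if f.name == "pumps":
            diff = {
                pf.name: getattr(val, pf.name)
                for pf in dataclasses.fields(PumpExchangerSet)
                if getattr(val, pf.name) != getattr(ref, pf.name)
            }
            if diff:
                overrides["pumps"] = diff
        elif val != ref:
            overrides[f.name] = val
    doc = {
        "dt_ms": config.dt_ms,
        "duration_ms": config.duration_ms,
        "stride": config.stride,
    }
    if overrides:
        doc["params"] = overrides
    if config.protocol is not None:
        doc["protocol"] = {
            "name": "alcohol",
            "y": config.protocol.y_mA_cm2_s,
            "m": config.protocol.m_mA_cm2_s,
            "onset_s": config.protocol.onset_s,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class RunManifest:
    """Written before a run starts and finalised when it completes."""

    path: Path
    config_hash: str
    dt_ms: float
    duration_ms: float
    protocol: str
    package_version: str = ""
    status: str = "running"
    outputs: list = field(default_factory=list)
    started: str = ""
    finished: str = ""

    @classmethod
    def start(cls, out_dir, config: SimConfig) -> "RunManifest":
        from . import __version__

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        blob = repr(
            (config.params, config.dt_ms, config.duration_ms, config.stride,
             config.protocol)
        ).encode()
        manifest = cls(
            path=out_dir / "manifest.json",
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            dt_ms=config.dt_ms,
            duration_ms=config.duration_ms,
            protocol="alcohol" if config.protocol else "none",
            package_version=__version__,
            started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )
        manifest.write()
        return manifest

    def finalize(self, outputs) -> None:
        self.outputs = [str(p) for p in outputs]
        self.status = "complete"
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.write()

    def write(self) -> None:
        doc = dataclasses.asdict(self)
        doc["path"] = str(self.path)
        with open(self.path, "w") as fh:
            json.dump(doc, fh, indent=2)


def write_report(path, title: str, lines) -> None:
    """Plain-text report with a header."""
    with open(path, "w") as fh:
        fh.write(title + "\n" + "=" * len(title) + "\n")
        for line in lines:
            fh.write(str(line) + "\n")
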