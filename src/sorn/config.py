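"""Run configuration: flat TOML files that round-trip losslessly.

A :class:`RunConfig` bundles the model parameters with run length,
recording flags and the ablation switches.  Files are flat key-value TOML
(arrays allowed for per-unit target rates); unknown keys are rejected so
typos fail loudly.  The configuration hash stamped into every output file
is the SHA-256 of the canonical JSON form.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, fields, replace

import numpy as np

from .params import NetworkParams, ParameterError
from .engine import Ablations, RecordSpec

__all__ = ["RunConfig"]

_RUN_KEYS = {
    "n_steps": 10_000,
    "snapshot_every": 200,
    "record_raster": True,
    "record_deltas": False,
    "record_events": True,
    "enable_stdp": True,
    "enable_normalization": True,
    "enable_intrinsic": True,
    "enable_istdp": True,
    "enable_structural": True,
}


@dataclass(frozen=True)
class RunConfig:
    params: NetworkParams
    n_steps: int = 10_000
    snapshot_every: int = 200
    record_raster: bool = True
    record_deltas: bool = False
    record_events: bool = True
    enable_stdp: bool = True
    enable_normalization: bool = True
    enable_intrinsic: bool = True
    enable_istdp: bool = True
    enable_structural: bool = True

    # -- derived views -----------------------------------------------------

    @property
    def seed(self) -> int:
        return self.params.seed

    def ablations(self) -> Ablations:
        return Ablations(stdp=self.enable_stdp,
                         normalization=self.enable_normalization,
                         intrinsic=self.enable_intrinsic,
                         istdp=self.enable_istdp,
                         structural=self.enable_structural)

    def record_spec(self) -> RecordSpec:
        return RecordSpec(raster=self.record_raster,
                          connection_fraction=True,
                          snapshot_every=self.snapshot_every or None,
                          events=self.record_events,
                          stdp_deltas=self.record_deltas)

    def replace(self, **changes) -> "RunConfig":
        param_fields = {f.name for f in fields(NetworkParams)}
        p_changes = {k: v for k, v in changes.items() if k in param_fields}
        r_changes = {k: v for k, v in changes.items() if k not in param_fields}
        params = self.params.replace(**p_changes) if p_changes else self.params
        return replace(self, params=params, **r_changes)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dict(self.params.to_dict())
        for k in _RUN_KEYS:
            d[k] = getattr(self, k)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        run = {}
        for k, default in _RUN_KEYS.items():
            run[k] = d.pop(k, default)
        params = NetworkParams.from_dict(d)  # rejects unknown keys
        return cls(params=params, **run)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_toml(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(_dumps_flat_toml(self.to_dict()))

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            try:
                d = tomllib.load(fh)
            except tomllib.TOMLDecodeError as e:
                raise ParameterError("<file>", f"invalid TOML: {e}") from e
        return cls.from_dict(d)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def _dumps_flat_toml(d: dict) -> str:
    # flat key-value dialect; sufficient for the configuration surface
    return "".join(f"{k} = {_toml_value(v)}\n" for k, v in d.items())
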