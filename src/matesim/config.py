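"""Configuration files, seed derivation, and run manifests.

YAML configs carry one key per :class:`SimulationParams` field. A sweep
config additionally allows lists per swept field (cross-product
semantics) plus ``replicates`` and ``base_seed``. Unknown keys are
rejected so typos cannot silently fall back to defaults.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .params import ConfigError, SimulationParams, SweepConfig

__all__ = ["load_config", "derive_seed", "RunManifest"]

_SWEEP_KEYS = {"replicates", "base_seed"}
_PARAM_KEYS = set(SimulationParams.__dataclass_fields__)


def derive_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    """Stable per-run seed from (base seed, sweep cell, replicate).

    Uses ``np.random.SeedSequence`` entropy mixing, which is platform-
    independent and collision-free in practice; seeds are reduced to
    [0, 2**31) so they remain portable small integers.
    """
    if base_seed < 0 or cell_index < 0 or replicate < 0:
        raise ValueError("seed components must be non-negative")
    ss = np.random.SeedSequence([base_seed, cell_index, replicate])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def load_config(path: Union[str, Path]) -> Union[SimulationParams, SweepConfig]:
    """Parse a YAML config into run parameters or a sweep grid.

    A config where any parameter value is a list (or that sets
    ``replicates``/``base_seed``) is a sweep; otherwise it is a single
    run. Missing fields take the reference-study defaults.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _PARAM_KEYS - _SWEEP_KEYS
    if unknown:
        raise ConfigError(
            f"{path}: unknown key(s) {sorted(unknown)!r}; valid keys are "
            f"{sorted(_PARAM_KEYS | _SWEEP_KEYS)}")
    is_sweep = (_SWEEP_KEYS & set(raw)) or any(
        isinstance(v, list) for v in raw.values())
    if not is_sweep:
        return SimulationParams(**raw)
    grid = {k: v for k, v in raw.items()
            if k in _PARAM_KEYS and isinstance(v, list)}
    scalars = {k: v for k, v in raw.items()
               if k in _PARAM_KEYS and not isinstance(v, list)}
    return SweepConfig(
        grid=grid,
        replicates=int(raw.get("replicates", 5)),
        base_seed=int(raw.get("base_seed", 0)),
        base_params=SimulationParams(**scalars),
    )


@dataclass
class RunManifest:
    """Everything needed to reproduce an output file bit-identically."""
    config: dict
    base_seed: int
    derived_seeds: list[int]
    version: str = ""
    created: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    def to_dict(self) -> dict:
        return {"config": self.config, "config_hash": self.config_hash,
                "base_seed": self.base_seed,
                "derived_seeds": self.derived_seeds,
                "version": self.version, "created": self.created}

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def read(cls, path: Union[str, Path]) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        m = cls(config=d["config"], base_seed=d["base_seed"],
                derived_seeds=d["derived_seeds"], version=d.get("version", ""),
                created=d.get("created", ""))
        if m.config_hash != d.get("config_hash"):
            raise ConfigError(f"{path}: config hash mismatch")
        return m
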