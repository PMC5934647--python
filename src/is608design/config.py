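"""Run configuration: defaults, YAML loading, validation.

A :class:`RunConfig` carries every tunable the pipeline commands use; loading
re-validates the cooperativity calibration constraints, so a user config
that would break the competition model's encoded outcomes fails at startup
with the offending field named.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .ssfold import FoldParams, FoldError
from .target_scan import CoopParams, CalibrationError, DEFAULT_PLUS1_WEIGHTS

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the field."""


@dataclass(frozen=True)
class RunConfig:
    ct: str = "TTAC"
    ext_len: int = 8
    linker_len: int = 3
    plus1_weights: dict = field(default_factory=lambda: dict(DEFAULT_PLUS1_WEIGHTS))
    coop: CoopParams = field(default_factory=CoopParams)
    fold: FoldParams = field(default_factory=FoldParams)
    seed: int = 1
    accessibility_threshold: float = 0.9

    def __post_init__(self):
        if len(self.ct) != 4 or set(self.ct.upper()) - set("ACGT"):
            raise ConfigError("ct: must be a 4-mer over ACGT")
        if not (0 <= self.ext_len <= 13):
            raise ConfigError("ext_len: must be in 0..13")
        if not (2 <= self.linker_len <= 5):
            raise ConfigError("linker_len: must be in 2..5")
        for b in "ACGT":
            w = self.plus1_weights.get(b)
            if w is None or not (0 < w <= 1):
                raise ConfigError(f"plus1_weights[{b}]: must be in (0, 1]")
        if max(self.plus1_weights, key=self.plus1_weights.get) != "C":
            raise ConfigError("plus1_weights: maximum must be at C")
        if not (0 < self.accessibility_threshold <= 1):
            raise ConfigError("accessibility_threshold: must be in (0, 1]")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["coop"] = asdict(self.coop)
        payload["fold"] = asdict(self.fold)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path: Optional[str] = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    The YAML mirrors the dataclass fields; ``coop`` and ``fold`` are nested
    mappings.  Any violated invariant (including the coop calibration
    constraints) raises :class:`ConfigError` naming the field.
    """
    data = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        if isinstance(data.get("coop"), dict):
            data["coop"] = CoopParams(**data["coop"])
        if isinstance(data.get("fold"), dict):
            data["fold"] = FoldParams(**data["fold"])
        return RunConfig(**data)
    except CalibrationError as exc:
        raise ConfigError(f"coop: {exc}") from exc
    except FoldError as exc:
        raise ConfigError(f"fold: {exc}") from exc
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
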