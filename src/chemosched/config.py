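"""Run configuration: validated parameter blocks with YAML loading.

A configuration file mirrors the nominal-value tables field for field; an
empty file (or missing block) means "all nominal defaults".  Unknown keys
are rejected loudly, and every field records whether it came from the file
or from a default, so a run manifest can state its exact provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ModelParams, TumorState
from .objective import ObjectiveWeights
from .ocp import TranscriptionSettings
from .survival import SurvivalSettings

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


_BLOCKS = {
    "model": ModelParams,
    "weights": ObjectiveWeights,
    "initial": TumorState,
    "survival": SurvivalSettings,
    "transcription": TranscriptionSettings,
}

_SCALARS = {"output_dir": str, "seed": int, "log_level": str}

#: defaults for blocks whose types have no field defaults of their own
_BLOCK_DEFAULTS = {"initial": {"n1": 280.0, "n2": 20.0, "k": 650.0}}


@dataclass(frozen=True)
class RunConfig:
    model: ModelParams = field(default_factory=ModelParams)
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    initial: TumorState = field(default_factory=lambda: TumorState(280.0, 20.0, 650.0))
    survival: SurvivalSettings = field(default_factory=SurvivalSettings)
    transcription: TranscriptionSettings = field(default_factory=TranscriptionSettings)
    output_dir: str = "chemosched-out"
    seed: int = 0
    log_level: str = "INFO"
    #: maps "block.field" -> "file" or "default"
    provenance: dict = field(default_factory=dict, compare=False)

    def as_dict(self) -> dict:
        out: dict = {}
        for name, cls in _BLOCKS.items():
            block = getattr(self, name)
            out[name] = {f.name: getattr(block, f.name)
                         for f in dataclasses.fields(block)
                         if f.name != "provenance"}
            # tuples/arrays -> plain lists for serialization
            out[name] = {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in out[name].items()}
        for name in _SCALARS:
            out[name] = getattr(self, name)
        return out


def _build_block(name: str, cls, data: dict, provenance: dict):
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - field_names
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in config block {name!r}; "
            f"known fields: {sorted(field_names)}")
    kwargs = dict(_BLOCK_DEFAULTS.get(name, {}))
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
        provenance[f"{name}.{key}"] = "file"
    for key in field_names - set(data):
        provenance[f"{name}.{key}"] = "default"
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"config block {name!r}: {exc}") from exc


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``None`` or an empty file yields the all-defaults configuration.  Raises
    :class:`ConfigError` naming the offending block/field on unknown keys,
    type mismatches, or invariant violations.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw = loaded
    unknown = set(raw) - set(_BLOCKS) - set(_SCALARS)
    if unknown:
        raise ConfigError(
            f"unknown top-level key(s) {sorted(unknown)}; known: "
            f"{sorted(set(_BLOCKS) | set(_SCALARS))}")
    provenance: dict = {}
    kwargs: dict = {}
    for name, cls in _BLOCKS.items():
        block_raw = raw.get(name, {})
        if not isinstance(block_raw, dict):
            raise ConfigError(f"config block {name!r} must be a mapping")
        kwargs[name] = _build_block(name, cls, block_raw, provenance)
    for name, typ in _SCALARS.items():
        if name in raw:
            try:
                kwargs[name] = typ(raw[name])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"config field {name!r}: {exc}") from exc
            provenance[name] = "file"
        else:
            provenance[name] = "default"
    return RunConfig(provenance=provenance, **kwargs)
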