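"""Run configuration: one serializable object covering every tunable.

A run configuration file (JSON or YAML) has up to three sections —
``scenario``/``paradigm``/``seed`` at the top level, a ``synthetic``
section mirroring :class:`~exodecode.synthetic.SyntheticConfig` and a
``pipeline`` section mirroring :class:`~exodecode.evaluate.PipelineConfig`.
Unknown keys raise :class:`~exodecode.errors.ConfigError` naming the field
path, so typos never silently fall back to defaults.  The resolved
configuration is echoed into every results directory for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

from .errors import ConfigError
from .evaluate import PipelineConfig
from .protocol import ProtocolSpec
from .synthetic import SyntheticConfig


@dataclass
class RunConfig:
    scenario: str = "experience"
    paradigm: str = "both"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    def __post_init__(self) -> None:
        if self.scenario not in ("experience", "slopes"):
            raise ConfigError(f"scenario: unknown value {self.scenario!r}")
        if self.paradigm not in ("mi", "att", "both"):
            raise ConfigError(f"paradigm: unknown value {self.paradigm!r}")

    @property
    def paradigms(self) -> list[str]:
        return ["mi", "att"] if self.paradigm == "both" else [self.paradigm]


def _build(cls, payload: dict, path: str):
    if not isinstance(payload, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(payload).__name__}")
    allowed = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in payload.items():
        if key not in allowed:
            raise ConfigError(f"{path}.{key}: unknown field")
        if key == "protocol":
            value = _build(ProtocolSpec, value, f"{path}.protocol")
        elif key in ("mi_bands", "att_bands", "sequence", "slopes_active_range"):
            value = tuple(tuple(item) if isinstance(item, (list, tuple)) else item for item in value)
        elif key == "label_codes":
            value = {str(k): {str(n): int(c) for n, c in v.items()} for k, v in value.items()}
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def run_config_from_dict(payload: dict) -> RunConfig:
    """Build a :class:`RunConfig` strictly from a plain mapping."""
    if not isinstance(payload, dict):
        raise ConfigError("configuration root must be a mapping")
    top = dict(payload)
    synthetic = _build(SyntheticConfig, top.pop("synthetic", {}), "synthetic")
    pipeline = _build(PipelineConfig, top.pop("pipeline", {}), "pipeline")
    allowed = {"scenario", "paradigm", "seed"}
    for key in top:
        if key not in allowed:
            raise ConfigError(f"{key}: unknown field")
    # keep the session scenario and seed consistent across sections unless
    # the synthetic section overrides them explicitly
    if "synthetic" not in payload or "scenario" not in payload.get("synthetic", {}):
        synthetic = dataclasses.replace(synthetic, scenario=top.get("scenario", "experience"))
    if "synthetic" not in payload or "seed" not in payload.get("synthetic", {}):
        synthetic = dataclasses.replace(synthetic, seed=int(top.get("seed", 0)))
    return RunConfig(
        scenario=top.get("scenario", "experience"),
        paradigm=top.get("paradigm", "both"),
        seed=int(top.get("seed", 0)),
        synthetic=synthetic,
        pipeline=pipeline,
    )


def load_config(path: str | Path) -> RunConfig:
    """Read a JSON (or YAML, if PyYAML is available) configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        try:
            import yaml
        except ImportError as exc:  # pragma: no cover
            raise ConfigError("YAML configuration requires PyYAML") from exc
        payload = yaml.safe_load(text) or {}
    else:
        payload = json.loads(text) if text.strip() else {}
    return run_config_from_dict(payload)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration as JSON (provenance record)."""
    Path(path).write_text(json.dumps(_to_jsonable(config), indent=2) + "\n", encoding="utf-8")
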