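"""Pipeline configuration: YAML/JSON sections mapped onto stage dataclasses.

Unknown keys are rejected up front so typos fail before any computation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

from .classifier import TrainConfig
from .feature_selection import DiscretizationScheme
from .features import FeatureParams
from .preprocessing import FilterSpec
from .synthetic import GeneratorConfig


class ConfigError(ValueError):
    pass


def _build(cls, section: str, data: dict[str, Any] | None):
    data = dict(data or {})
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown keys in [{section}]: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )
    if "split" in data and isinstance(data["split"], list):
        data["split"] = tuple(data["split"])
    if "sef_fractions" in data and isinstance(data["sef_fractions"], list):
        data["sef_fractions"] = tuple(data["sef_fractions"])
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{section}] config: {exc}") from exc


@dataclass
class SelectionConfig:
    k: int = 12
    method: str = "z-threshold"

    def scheme(self) -> DiscretizationScheme:
        return DiscretizationScheme(method=self.method)


@dataclass
class EvaluationConfig:
    k_folds: int = 10
    cv_mode: str = "trial"  # or "subject"
    fixed_selection: bool = False

    def __post_init__(self) -> None:
        if self.cv_mode not in ("trial", "subject"):
            raise ValueError("cv_mode must be 'trial' or 'subject'")


_SECTIONS = {
    "generator": GeneratorConfig,
    "filter": FilterSpec,
    "feature": FeatureParams,
    "selection": SelectionConfig,
    "train": TrainConfig,
    "evaluation": EvaluationConfig,
}


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    feature: FeatureParams = field(default_factory=FeatureParams)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0
    out_dir: str = "runs"

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data or {})
        top_allowed = set(_SECTIONS) | {"seed", "out_dir"}
        unknown = set(data) - top_allowed
        if unknown:
            raise ConfigError(
                f"unknown top-level keys: {sorted(unknown)}; "
                f"allowed: {sorted(top_allowed)}"
            )
        seed = int(data.get("seed", 0))
        sections = {
            name: _build(klass, name, data.get(name))
            for name, klass in _SECTIONS.items()
        }
        # the global seed flows into stages unless they override it
        if "generator" not in data or "seed" not in (data["generator"] or {}):
            sections["generator"].seed = seed
        if "train" not in data or "seed" not in (data["train"] or {}):
            sections["train"].seed = seed
        return cls(seed=seed, out_dir=str(data.get("out_dir", "runs")),
                   **sections)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            if path.endswith(".json"):
                data = json.load(fh)
            else:
                data = yaml.safe_load(fh)
        return cls.from_dict(data or {})
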