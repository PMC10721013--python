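"""YAML run configuration: validation, defaults, and a provenance echo.

A run is fully described by a model-parameters block plus a design block.
Unknown keys are rejected so a typo cannot silently fall back to a default;
out-of-range constants are reported with their valid range.  ``load_config``
applies the published defaults to anything omitted, and the fully resolved
configuration can be echoed next to the outputs so any result file plus its
echo regenerates the run bit-exactly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .experiments import Condition, ExperimentDesign
from .params import ModelParameters

SCHEMA_VERSION = 1


class AdaptationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    params: dict[str, float] | None = None


class ControlConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    adaptation: AdaptationConfig = AdaptationConfig()


class AttentionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    numerical: float = 1.0
    physical: float = 1.0


class ParametersConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tau: float = 0.25
    theta: float = 0.75
    w_inh: float = -0.5
    t_max: int = 200
    d_relevant: float = 1.0
    d_irrelevant: float = 0.15
    td_weight_init: float = 0.5
    learning_rate: float = 0.012
    numberline_sigma: float | None = None
    freq_table: list[float] | None = None
    n_train: int = 100_000
    seed: int = 2023


class ConditionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: str
    attention: dict[str, float] = {}
    checkpoint: int | None = None
    theta: float | None = None


class DesignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    task: str = "numerical"
    stimulus_set: str = "validation-144"
    n_participants: int = 30
    conditions: list[ConditionConfig] = [ConditionConfig(label="LMA")]


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    schema_version: int = SCHEMA_VERSION
    parameters: ParametersConfig = ParametersConfig()
    attention: AttentionConfig = AttentionConfig()
    control: ControlConfig = ControlConfig()
    design: DesignConfig = DesignConfig()
    output_dir: str = "results"
    log_level: str = "INFO"

    def model_parameters(self) -> ModelParameters:
        kwargs = self.parameters.model_dump()
        if kwargs.pop("numberline_sigma") is None:
            kwargs["numberline_sigma"] = ModelParameters().numberline_sigma
        freq = kwargs.pop("freq_table")
        if freq is not None:
            kwargs["freq_table"] = tuple(freq)
        return ModelParameters(
            attention_scale_numerical=self.attention.numerical,
            attention_scale_physical=self.attention.physical,
            **kwargs,
        )

    def experiment_design(self) -> ExperimentDesign:
        return ExperimentDesign(
            task=self.design.task,
            stimulus_set=self.design.stimulus_set,
            n_participants=self.design.n_participants,
            seed=self.parameters.seed,
            conditions=tuple(
                Condition(
                    label=c.label,
                    attention=tuple(sorted(c.attention.items())),
                    checkpoint=c.checkpoint,
                    theta=c.theta,
                )
                for c in self.design.conditions
            ),
        )


class ConfigError(ValueError):
    """A configuration file failed validation."""


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML configuration, applying defaults.

    An empty file yields the full default configuration.  Validation errors
    name the offending key; the adaptation rule may only be enabled together
    with its parameter block.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    try:
        config = RunConfig.model_validate(raw)
    except ValidationError as exc:
        keys = ", ".join(
            ".".join(str(loc) for loc in err["loc"]) or "<root>"
            for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration ({keys}): {exc}") from exc
    try:
        config.model_parameters()
        config.experiment_design()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    if config.control.adaptation.enabled and not config.control.adaptation.params:
        raise ConfigError(
            "control.adaptation.enabled requires control.adaptation.params"
        )
    return config


def dump_resolved(config: RunConfig, path: str | Path) -> None:
    """Echo the fully resolved configuration (YAML) alongside the outputs."""
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=False)
    )
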