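"""Run configuration: schema, validation, loading.

A run configuration is a small YAML document selecting the generator
settings, economic assumptions, coverage parameters, analysis options
and (optionally) probabilistic sensitivity analysis.  Validation is
all-or-nothing: every violation is reported with its field path in one
aggregated error, and nothing is partially accepted.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .errors import ConfigurationError

SCHEMA_ID = "cvdcea/run/v1"


class GeneratorConfig(BaseModel):
    n_per_cell: int = Field(250, gt=0,
                            description="survey respondents per age/sex cell")
    survey_path: str | None = None          # optional pre-generated survey
    epidemiology_path: str | None = None


class EconomicsConfig(BaseModel):
    discount_rate: float = Field(0.03, ge=0)
    threshold: float = Field(50_000.0, gt=0)
    metric: Literal["DALY", "QALY"] = "DALY"


class CoverageConfig(BaseModel):
    gp_attendance: float = Field(0.85, ge=0, le=1)
    assessment_participation: float = Field(0.60, ge=0, le=1)


class PSAConfig(BaseModel):
    enabled: bool = False
    n_draws: int = Field(200, ge=2)
    max_frontier_packages: int = Field(8, ge=1)


class AnalysisConfig(BaseModel):
    statin_price: Literal["australia", "nz"] = "australia"
    behaviour_effectiveness_scale: float = Field(0.01, ge=0, le=1)
    trend_enabled: bool = True
    unrelated_cost_per_life_year: float = Field(0.0, ge=0)
    frontier_max_threshold: float = Field(150_000.0, gt=0)
    frontier_step: float = Field(1000.0, gt=0)


class RunConfig(BaseModel):
    """Validated run configuration."""

    schema_id: str = Field(SCHEMA_ID, alias="schema")
    seed: int | None = None
    output_dir: str = "results"
    verbosity: int = Field(1, ge=0, le=2)
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    economics: EconomicsConfig = Field(default_factory=EconomicsConfig)
    coverage: CoverageConfig = Field(default_factory=CoverageConfig)
    psa: PSAConfig = Field(default_factory=PSAConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)

    model_config = {"populate_by_name": True, "extra": "forbid"}

    @model_validator(mode="after")
    def _cross_checks(self):
        if self.psa.enabled and self.seed is None:
            raise ValueError(
                "seed: required whenever probabilistic sensitivity "
                "analysis is enabled")
        if self.schema_id != SCHEMA_ID:
            raise ValueError(
                f"schema: expected {SCHEMA_ID!r}, got {self.schema_id!r}")
        return self


def validate_config(source) -> RunConfig:
    """Validate a config mapping, YAML text, or file path.

    Raises :class:`ConfigurationError` listing every violation with its
    field path; referenced files must exist.
    """
    origin = "<mapping>"
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        path = Path(source)
        origin = str(path)
        if not path.exists():
            raise ConfigurationError(f"{origin}: config file does not exist")
        data = yaml.safe_load(path.read_text())
        base_dir = path.parent
    elif isinstance(source, str):
        data = yaml.safe_load(source)
        base_dir = Path(".")
    else:
        data = source
        base_dir = Path(".")
    if not isinstance(data, dict):
        raise ConfigurationError(f"{origin}: config root must be a mapping")
    try:
        cfg = RunConfig.model_validate(data)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"  {loc}: {err['msg']}")
        raise ConfigurationError(
            f"{origin}: invalid configuration\n" + "\n".join(lines)
        ) from exc
    problems = []
    for field in ("survey_path", "epidemiology_path"):
        ref = getattr(cfg.generator, field)
        if ref is not None and not (base_dir / ref).exists():
            problems.append(f"  generator.{field}: file {ref!r} not found")
    if problems:
        raise ConfigurationError(
            f"{origin}: invalid configuration\n" + "\n".join(problems))
    return cfg


def builtin_config_path(name: str) -> Path:
    """Path of a shipped demo configuration ("toy" or "full")."""
    p = Path(__file__).parent / "configs" / f"{name}.yaml"
    if not p.exists():
        raise ConfigurationError(f"no built-in config named {name!r}")
    return p
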