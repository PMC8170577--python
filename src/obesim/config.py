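"""Run configuration: cohort profiles, treatment, and file-backed settings.

Configs are YAML or JSON.  Validation is schema-based (pydantic) so
errors name the offending field; glycemic shares must sum to one, the
horizon is capped at the model's 40-year lifetime horizon, and any
referenced paths must exist at load time.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .riskfactors import RiskFactorVector, TrajectoryPolicy, TreatmentEffect

logger = logging.getLogger(__name__)

__all__ = ["CohortProfile", "RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for invalid configuration files, naming the field at fault."""


class CohortProfile(BaseModel):
    """Baseline cohort: risk-factor vector plus stratum shares.

    Shares are proportions in [0, 1]; the three glycemic shares
    (no dysglycemia / prediabetes / T2D) must sum to 1 within 1e-9.
    """

    n: float = Field(gt=0, default=100.0)
    age: float = Field(ge=0)
    bmi: float = Field(gt=0)
    sex_share_women: float = Field(ge=0, le=1)
    height_cm: float = 168.0
    sbp: float = 130.0
    total_chol: float = 200.0
    hdl_chol: float = 55.0
    hba1c_pct: float = 7.0
    t2d_duration: float = 0.0
    triglycerides: float = 130.0
    share_tg_ge_150: float = Field(ge=0, le=1, default=0.3)
    share_smokers: float = Field(ge=0, le=1, default=0.4)
    share_antihypertensive: float = Field(ge=0, le=1, default=0.15)
    share_lipid_lowering: float = Field(ge=0, le=1, default=0.10)
    menopause_age: float = 51.0
    share_no_dysglycemia: float = Field(ge=0, le=1)
    share_prediabetes: float = Field(ge=0, le=1)
    share_t2d: float = Field(ge=0, le=1)
    sleep_apnea_share: float = Field(ge=0, le=1, default=0.0)

    @model_validator(mode="after")
    def _glycemic_shares_sum_to_one(self) -> "CohortProfile":
        total = self.share_no_dysglycemia + self.share_prediabetes + self.share_t2d
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                "share_no_dysglycemia + share_prediabetes + share_t2d = "
                f"{total:.6f}, must sum to 1"
            )
        return self

    @property
    def glycemic_split(self) -> tuple[float, float, float]:
        return (self.share_no_dysglycemia, self.share_prediabetes, self.share_t2d)

    def to_risk_factors(self) -> RiskFactorVector:
        return RiskFactorVector(
            age=self.age,
            sex_share_women=self.sex_share_women,
            bmi=self.bmi,
            height=self.height_cm,
            sbp=self.sbp,
            total_chol=self.total_chol,
            hdl_chol=self.hdl_chol,
            hba1c_pct=self.hba1c_pct,
            t2d_duration=self.t2d_duration,
            triglycerides=self.triglycerides,
            share_tg_ge_150=self.share_tg_ge_150,
            share_smokers=self.share_smokers,
            share_antihypertensive=self.share_antihypertensive,
            share_lipid_lowering=self.share_lipid_lowering,
            menopause_age=self.menopause_age,
        )


class TreatmentEffectConfig(BaseModel):
    bmi_pct_change: float = 0.0
    sbp_abs_change: float = 0.0
    hdl_abs_change: float = 0.0
    tc_abs_change: float = 0.0
    hba1c_point_change: float = 0.0
    antihypertensive_share_change: float = 0.0
    duration: float = Field(ge=0, default=0.0)
    catchup_years: float = Field(ge=0, default=0.0)

    def to_effect(self) -> TreatmentEffect:
        return TreatmentEffect(**self.model_dump())


class TrajectoryPolicyConfig(BaseModel):
    bmi_drift_per_year: float = 0.0
    bmi_drift_stop_age: float = 200.0
    hba1c_drift_per_year: float = 0.0

    def to_policy(self) -> TrajectoryPolicy:
        return TrajectoryPolicy(**self.model_dump())


class RunConfig(BaseModel):
    """Top-level simulation configuration."""

    horizon_years: int = Field(ge=1, le=40, default=40)
    cohort: CohortProfile
    treatment: Optional[TreatmentEffectConfig] = None
    trajectory: TrajectoryPolicyConfig = TrajectoryPolicyConfig()
    risk_registry: Literal["toy"] | dict[str, str] = "toy"
    life_table_path: Optional[str] = None
    acs_share: float = Field(ge=0, le=1, default=3.4 / 7.8)
    seed: int = 0
    output_dir: str = "."

    @field_validator("life_table_path")
    @classmethod
    def _path_exists(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and not Path(v).exists():
            raise ValueError(f"life table path does not exist: {v}")
        return v

    @model_validator(mode="after")
    def _registry_paths_exist(self) -> "RunConfig":
        if isinstance(self.risk_registry, dict):
            for slot, path in self.risk_registry.items():
                if not Path(path).exists():
                    raise ValueError(f"risk model path for slot '{slot}' missing: {path}")
        return self


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        cfg = RunConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    logger.info(
        "loaded config %s (horizon %d y, cohort n=%g, registry=%s)",
        path,
        cfg.horizon_years,
        cfg.cohort.n,
        cfg.risk_registry if isinstance(cfg.risk_registry, str) else "custom",
    )
    return cfg
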