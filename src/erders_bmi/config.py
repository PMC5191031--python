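"""Schema-validated pipeline configuration and provenance records."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__


class SynthSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    classes: tuple[str, str] = ("left_hand", "both_feet")
    n_trials_per_class: int = Field(60, ge=1)
    erd_depth: float = Field(0.5, ge=0.0, le=1.0)
    ers_gain: float = Field(0.4, ge=0.0)
    mixing_spread: float = Field(0.5, ge=0.0, le=1.0)
    noise_rms_uv: float = Field(3.0, gt=0.0)
    artifact_rate: float = Field(0.0, ge=0.0)
    passive_arm_contamination: float = Field(0.0, ge=0.0, le=1.0)


class PreprocessSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    band: tuple[float, float] = (8.0, 30.0)
    notch: float = 50.0
    window: tuple[float, float] = (-3.0, 5.0)
    amplitude_threshold_uv: float = 100.0
    variance_z_threshold: float = 10.0


class TrainSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    classifier: str = "LDA"
    train_fraction: float = 0.8
    cv_folds: int = Field(10, ge=2)
    m: int = Field(2, ge=1)
    feature_window: tuple[float, float] = (4.0, 7.0)


class OnlineSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_actions: int = Field(60, ge=1)
    scenario: str = "without_exo"
    motor_mode: str = "MI"
    step_deg: float = 10.0


class RunConfig(BaseModel):
    """Top-level pipeline configuration (schema version 1, unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    out_dir: str = "pipeline_out"
    seed: int = 0
    log_level: str = "INFO"
    synth: SynthSection = Field(default_factory=SynthSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    train: TrainSection = Field(default_factory=TrainSection)
    online: OnlineSection = Field(default_factory=OnlineSection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_provenance(out_dir: str | Path, stage: str, config: RunConfig) -> Path:
    """One provenance record per stage: config hash, seed, package version."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "config": config.model_dump(),
    }
    path = out_dir / f"provenance_{stage}.json"
    path.write_text(json.dumps(record, indent=1, sort_keys=True))
    return path
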