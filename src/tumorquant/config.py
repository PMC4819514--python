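"""Schema-validated pipeline configuration (YAML in, YAML out).

Every tunable the pipeline exposes lives here: acquisition constants, the
population AIF, positivity/viability/ROI thresholds, the erosion
structuring element, the significance level and the RNG seed. Unknown keys
are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .acquisition import AcquisitionParams, AIFModel
from .errors import InvalidInputError
from .pk_model import RELAXIVITY_R1_DEFAULT

__all__ = ["PipelineConfig", "Thresholds", "load_config", "save_config"]


class Thresholds(BaseModel):
    model_config = ConfigDict(extra="forbid")

    #: per-channel fixed positivity thresholds; channels absent here use Otsu
    positivity: dict[str, float] = Field(
        default_factory=lambda: {
            "ef5": 100.0,
            "ki67": 100.0,
            "tunel": 100.0,
            "cd31": 100.0,
            "hoechst_perfusion": 100.0,
        }
    )
    #: 'viable' voxel: peak enhancement above this multiple of baseline noise SD
    viability_noise_multiple: float = 3.0
    #: PET avid-ROI threshold as a fraction of the volume maximum
    roi_fraction: float = 0.4

    @field_validator("viability_noise_multiple")
    @classmethod
    def _vnm(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("viability_noise_multiple must be strictly positive")
        return v

    @field_validator("roi_fraction")
    @classmethod
    def _roi(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError("roi_fraction must lie in (0, 1)")
        return v


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    acquisition: AcquisitionParams = Field(default_factory=AcquisitionParams)
    #: bolus arrival defaults to the start of the post-contrast block
    #: (n_pre * frame_interval = 312 s for the default acquisition); keep it
    #: consistent with `acquisition` when overriding either
    aif: AIFModel = Field(default_factory=lambda: AIFModel(onset_time=312.0))
    thresholds: Thresholds = Field(default_factory=Thresholds)
    relaxivity_r1: float = RELAXIVITY_R1_DEFAULT
    shell_connectivity: int = 6
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "results"

    @field_validator("alpha")
    @classmethod
    def _alpha(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        return v

    @field_validator("shell_connectivity")
    @classmethod
    def _conn(cls, v: int) -> int:
        if v not in (6, 18, 26):
            raise ValueError("shell_connectivity must be 6, 18 or 26")
        return v

    @field_validator("relaxivity_r1")
    @classmethod
    def _r1(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("relaxivity_r1 must be strictly positive")
        return v


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; an empty file yields all defaults."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        keys = sorted({str(e["loc"][0]) for e in exc.errors() if e["loc"]})
        raise InvalidInputError(
            f"invalid config {path}: offending keys {keys}\n{exc}"
        ) from exc


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True))
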